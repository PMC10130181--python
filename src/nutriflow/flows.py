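"""Route-level nutrient flow accounting and network aggregates.

The central quantity is the nutrient flow of a trade route,
``F = C x T``: content C (kg nutrient per tonne, physical or virtual)
times traded mass T (tonnes), giving kg of N or P embedded in the
shipment.  On the virtual basis the *exporter's* (producer's) content
is used, since virtual nutrients are inputs spent where the product was
grown.  Everything else in this module is descriptive aggregation of
those flows: country gross/net budgets, route counts, top-k sender
concentration, virtual:physical ratio censuses, and adjacency/distance
stratification of route volumes.

Internal units: kg for nutrient amounts; report layers convert to
Gg (1e6 kg) and Tg (1e9 kg).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .countries import CountrySet
from .errors import ConfigurationError, ValidationError
from .nutrients import ContentResolver

logger = logging.getLogger(__name__)

FLOW_COLUMNS = ["year", "product", "exporter", "importer",
                "element", "basis", "amount"]

KG_PER_TG = 1e9
KG_PER_GG = 1e6


def compute_flows(trade: pd.DataFrame, contents: ContentResolver,
                  basis: str, element: str) -> pd.DataFrame:
    """Nutrient flow of every trade record: amount = content x mass, kg.

    Physical content is per-product; virtual content is the exporter's
    country-specific value (falling back per the resolver's rule).
    """
    if trade.empty:
        return pd.DataFrame(columns=FLOW_COLUMNS)
    content = contents.contents_for(trade["exporter"], trade["product"],
                                    basis, element)
    out = trade[["year", "product", "exporter", "importer"]].copy()
    out["element"] = element
    out["basis"] = basis
    out["amount"] = content.to_numpy() * trade["mass"].to_numpy()
    return out.reset_index(drop=True)


def compute_all_flows(trade: pd.DataFrame, contents: ContentResolver,
                      bases=("physical", "virtual"),
                      elements=("N", "P")) -> pd.DataFrame:
    parts = [compute_flows(trade, contents, b, e)
             for b in bases for e in elements]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=FLOW_COLUMNS)


def country_budgets(flows: pd.DataFrame) -> pd.DataFrame:
    """Gross export/import and net budget per (year, country, element, basis).

    Net = gross import - gross export; positive marks a net receiving
    system.  Nets sum to zero globally per (year, element, basis).
    """
    if flows.empty:
        return pd.DataFrame(columns=["year", "country", "element", "basis",
                                     "gross_export", "gross_import", "net"])
    exp = (flows.groupby(["year", "exporter", "element", "basis"])
           ["amount"].sum().rename("gross_export"))
    exp.index = exp.index.set_names("country", level="exporter")
    imp = (flows.groupby(["year", "importer", "element", "basis"])
           ["amount"].sum().rename("gross_import"))
    imp.index = imp.index.set_names("country", level="importer")
    out = pd.concat([exp, imp], axis=1).fillna(0.0).reset_index()
    out["net"] = out["gross_import"] - out["gross_export"]
    return out.sort_values(["year", "element", "basis", "country"],
                           ignore_index=True)


def network_summary(flows: pd.DataFrame, budgets: pd.DataFrame,
                    ks=(10, 20)) -> pd.DataFrame:
    """Per-(year, element, basis) network aggregates.

    A *route* is a distinct (exporter, importer) pair with positive
    summed flow in the year.  ``top{k}_share`` is the share of all
    positive net exports contributed by the k largest net senders
    (value-descending, country-code ascending tie-break); k beyond the
    sender count is capped, so the share reaches 1 at k = n_net_senders.
    """
    rows = []
    for (yr, el, ba), f in flows.groupby(["year", "element", "basis"]):
        routes = (f.groupby(["exporter", "importer"])["amount"].sum() > 0)
        b = budgets[(budgets["year"] == yr) & (budgets["element"] == el)
                    & (budgets["basis"] == ba)]
        senders = b[b["net"] < 0].copy()
        senders["net_export"] = -senders["net"]
        senders = senders.sort_values(["net_export", "country"],
                                      ascending=[False, True],
                                      kind="stable")
        total_net_export = senders["net_export"].sum()
        row = {
            "year": yr, "element": el, "basis": ba,
            "total_flow": f["amount"].sum(),
            "n_routes": int(routes.sum()),
            "n_net_senders": int((b["net"] < 0).sum()),
            "n_net_receivers": int((b["net"] > 0).sum()),
        }
        for k in ks:
            if total_net_export > 0:
                share = senders["net_export"].head(k).sum() / total_net_export
            else:
                share = np.nan
            row[f"top{k}_share"] = share
        rows.append(row)
    return pd.DataFrame(rows)


def ratio_census(physical_flows: pd.DataFrame, virtual_flows: pd.DataFrame,
                 thresholds=(100.0, 1000.0)
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count routes whose virtual flow exceeds the physical by each cutoff.

    Routes are (year, exporter, importer) pairs with flows summed over
    products, per element.  Returns ``(counts, zero_physical)``:
    ``counts`` has one row per (year, element, cutoff) with the number
    of routes whose virtual/physical ratio exceeds the cutoff;
    ``zero_physical`` reports routes excluded because their physical
    flow is zero.
    """
    key = ["year", "exporter", "importer", "element"]
    p = (physical_flows.groupby(key)["amount"].sum().rename("physical"))
    v = (virtual_flows.groupby(key)["amount"].sum().rename("virtual"))
    m = pd.concat([p, v], axis=1).fillna(0.0).reset_index()

    zero = m[m["physical"] == 0]
    zero_physical = (zero.groupby(["year", "element"]).size()
                     .rename("n_zero_physical").reset_index())
    pos = m[m["physical"] > 0].copy()
    pos["ratio"] = pos["virtual"] / pos["physical"]
    rows = []
    for (yr, el), g in pos.groupby(["year", "element"]):
        for cut in thresholds:
            rows.append({"year": yr, "element": el, "cutoff": cut,
                         "count": int((g["ratio"] > cut).sum())})
    counts = pd.DataFrame(rows, columns=["year", "element", "cutoff",
                                         "count"])
    return counts, zero_physical


def distance_stratify(flows: pd.DataFrame, countries: CountrySet,
                      bins=(2000.0, 5000.0, 10000.0)) -> pd.DataFrame:
    """Mean route flow per adjacency/distance stratum.

    Route volume is the flow summed over products per (year, exporter,
    importer).  Pairs within ``countries.adjacent_km`` form the
    ``adjacent`` stratum; other pairs fall into half-open distance bins
    with the given upper edges (a final open-ended bin is added).
    Routes without a distance entry are excluded and logged; empty
    strata are simply absent from the result.
    """
    if not countries.adjacency:
        raise ConfigurationError("distance stratification requires an "
                                 "adjacency/distance table")
    routes = (flows.groupby(["year", "exporter", "importer"],
                            as_index=False)["amount"].sum())
    dist = [countries.distance(a, b) for a, b in
            zip(routes["exporter"], routes["importer"])]
    routes["distance"] = dist
    missing = routes["distance"].isna()
    if missing.any():
        logger.warning("%d route pair(s) lack a distance entry; excluded",
                       int(missing.sum()))
        routes = routes[~missing]

    inner = [e for e in sorted(bins) if e > countries.adjacent_km]
    edges = [-np.inf, countries.adjacent_km, *inner, np.inf]
    labels = ["adjacent"] + [
        f"{lo:g}-{hi:g} km" if np.isfinite(hi) else f">{lo:g} km"
        for lo, hi in zip(edges[1:-1], edges[2:])
    ]
    routes["stratum"] = pd.cut(routes["distance"], edges, labels=labels,
                               right=True, ordered=False)
    out = (routes.groupby("stratum", observed=True)["amount"]
           .agg(mean_flow="mean", n_routes="size").reset_index())
    return out


def affected_area(net_outflow: float, consumption_per_area: float) -> float:
    """Cropland area, km^2, whose nutrient cycle a net outflow affects.

    Net nutrient outflow (kg) divided by nutrient consumption per unit
    area (kg/km^2); net importers (outflow <= 0) return 0.
    """
    if consumption_per_area <= 0:
        raise ValidationError("consumption_per_area must be positive")
    if net_outflow <= 0:
        return 0.0
    return net_outflow / consumption_per_area
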