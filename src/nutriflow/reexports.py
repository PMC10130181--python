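"""Re-export identification and origin attribution.

An importing country B can act as a transit station: part of what it
imports of a product it ships onward to final destinations C_k rather
than consuming it.  To trace nutrient flows to the real producer and
consumer, each re-export B -> C_k is attributed back to origin
countries A in proportion to B's import-origin shares, giving
single-hop chains A -> B -> C_k.  Netting those chains out of the
bilateral flow A -> B leaves the mass B actually retains.

Two modes are supported: *declared*, where explicit re-export records
are supplied; and *inferred*, where the re-exported share of each of
B's exports is taken as B's import share of apparent supply,
imports / (production + imports), per product-year.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import InconsistencyError

logger = logging.getLogger(__name__)

ATTRIBUTION_COLUMNS = ["year", "product", "origin", "intermediate",
                       "destination", "mass"]


def _empty_attribution() -> pd.DataFrame:
    return pd.DataFrame(columns=ATTRIBUTION_COLUMNS).astype(
        {"year": int, "mass": float}, errors="ignore")


def infer_reexports(trade: pd.DataFrame, production: pd.DataFrame,
                    year: int | None = None,
                    product: str | None = None) -> pd.DataFrame:
    """Infer re-export records from trade and domestic production.

    For each exporter B and product-year, the re-exported share of every
    export B -> C equals B's import share of apparent supply,
    ``imports / (production + imports)``; the remainder is
    domestic-origin export.  Optional ``year``/``product`` restrict the
    scope.  Exports with zero apparent supply raise
    :class:`InconsistencyError`.
    """
    t = trade
    if year is not None:
        t = t[t["year"] == year]
    if product is not None:
        t = t[t["product"] == product]
    if t.empty:
        return pd.DataFrame(columns=["year", "intermediate", "destination",
                                     "product", "mass"])

    imports = (t.groupby(["year", "importer", "product"])["mass"].sum()
                .rename("imports"))
    prod = (production.set_index(["year", "country", "product"])
            ["production"].astype(float))

    exports = t.rename(columns={"exporter": "intermediate",
                                "importer": "destination"}).copy()
    key = pd.MultiIndex.from_frame(
        exports[["year", "intermediate", "product"]])
    exports["imports"] = imports.reindex(key).fillna(0.0).to_numpy()
    exports["production"] = prod.reindex(key).fillna(0.0).to_numpy()

    supply = exports["imports"] + exports["production"]
    bad = exports[(supply <= 0) & (exports["mass"] > 0)]
    if len(bad):
        r = bad.iloc[0]
        raise InconsistencyError(
            f"{r.intermediate!r} exports {r['mass']} t of {r['product']!r} "
            f"in {r.year} with zero production and zero imports"
        )
    share = (exports["imports"] / supply).where(supply > 0, 0.0)
    exports["mass"] = exports["mass"] * share
    out = exports[exports["mass"] > 0][
        ["year", "intermediate", "destination", "product", "mass"]]
    return out.reset_index(drop=True)


def attribute_origins(reexports: pd.DataFrame, trade: pd.DataFrame,
                      strict: bool = False) -> pd.DataFrame:
    """Split each re-export B -> C_k across origin countries A.

    Attribution is proportional to B's import-origin shares for the
    product-year, so the totals over (A, C_k) reproduce B's re-export
    mass exactly.  Re-exports exceeding imports are capped at the import
    total with a warning (``strict=True`` raises instead); re-exports by
    a country with no recorded imports are dropped the same way.
    """
    if reexports is None or reexports.empty:
        return _empty_attribution()

    origin_mass = (trade.groupby(["year", "importer", "product", "exporter"])
                   ["mass"].sum())
    import_total = origin_mass.groupby(level=[0, 1, 2]).sum()

    chunks = []
    for (yr, b, prod), grp in reexports.groupby(
            ["year", "intermediate", "product"]):
        total_re = grp["mass"].sum()
        try:
            m_total = float(import_total.loc[(yr, b, prod)])
        except KeyError:
            m_total = 0.0
        if m_total <= 0:
            msg = (f"{b!r} re-exports {total_re} t of {prod!r} in {yr} "
                   f"but imported none")
            if strict:
                raise InconsistencyError(msg)
            logger.warning("%s; dropping", msg)
            continue
        scale = 1.0
        if total_re > m_total:
            msg = (f"{b!r} re-exports {total_re} t of {prod!r} in {yr} "
                   f"exceeding imports {m_total} t")
            if strict:
                raise InconsistencyError(msg)
            logger.warning("%s; capping at imports", msg)
            scale = m_total / total_re
        shares = origin_mass.loc[(yr, b, prod)] / m_total  # index: origin A
        for row in grp.itertuples(index=False):
            for origin, s in shares.items():
                chunks.append((yr, prod, origin, b, row.destination,
                               row.mass * scale * s))
    if not chunks:
        return _empty_attribution()
    return pd.DataFrame(chunks, columns=ATTRIBUTION_COLUMNS)


def netted_trade(trade: pd.DataFrame,
                 attribution: pd.DataFrame | None) -> pd.DataFrame:
    """Bilateral trade with attributed re-exports removed.

    Returns one row per (year, product, exporter, importer) with
    ``mass`` (gross), ``reexported`` (mass attributed onward through the
    importer) and ``mass_net`` = mass - reexported, floored at zero with
    a warning when mirror inconsistencies would drive it negative.
    """
    key = ["year", "product", "exporter", "importer"]
    out = trade.groupby(key, as_index=False)["mass"].sum()
    if attribution is None or attribution.empty:
        out["reexported"] = 0.0
    else:
        att = (attribution.groupby(["year", "product", "origin",
                                    "intermediate"])["mass"].sum()
               .rename("reexported").reset_index()
               .rename(columns={"origin": "exporter",
                                "intermediate": "importer"}))
        out = out.merge(att, on=key, how="left")
        out["reexported"] = out["reexported"].fillna(0.0)
    net = out["mass"] - out["reexported"]
    negative = net < 0
    if negative.any():
        logger.warning("%d netted flow(s) negative; flooring at 0",
                       int(negative.sum()))
    out["mass_net"] = net.clip(lower=0.0)
    return out


def net_bilateral(trade: pd.DataFrame, attribution: pd.DataFrame | None,
                  exporter: str, importer: str, product: str,
                  year: int) -> float:
    """Netted bilateral mass for one route, tonnes (scalar convenience)."""
    nt = netted_trade(trade, attribution)
    sel = nt[(nt["exporter"] == exporter) & (nt["importer"] == importer)
             & (nt["product"] == product) & (nt["year"] == year)]
    return float(sel["mass_net"].sum())
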