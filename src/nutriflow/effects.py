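"""Sending-receiving, spillover and telecoupling effects.

For each trade route A -> B of product i, the mass B actually retains
(gross mass net of attributed re-exports) carries a *sending-receiving
effect*:

* physical: content_i x netted mass — the nutrient mass actually
  transferred from sender to receiver (always >= 0);
* virtual: (content_i,B - content_i,A) x netted mass — signed; positive
  means the importer would have spent more nutrient input producing the
  product itself, so trade *saved* nutrients (an efficient flow);
  negative means nutrients were wasted (inefficient flow).

The re-exported portion travels on a chain A -> B -> C_k and carries a
*spillover effect*: physical content x re-exported mass, and on the
virtual basis (content_i,C_k - content_i,A) x re-exported mass — the
origin producer's content against the final consumer's, since B is only
a transit station.  The *telecoupling effect* per element and basis is
the sum of all sending-receiving and spillover effects.

A compatibility flag reproduces the variant in which the physical P
spillover is summed into the virtual P telecoupling total; the default
keeps all four totals basis-consistent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nutrients import ContentResolver
from .reexports import netted_trade

logger = logging.getLogger(__name__)

ROUTE_EFFECT_COLUMNS = ["year", "product", "exporter", "importer",
                        "mass", "reexported", "mass_net",
                        "nsre_p", "psre_p", "nsre_v", "psre_v"]
SPILLOVER_COLUMNS = ["year", "product", "origin", "intermediate",
                     "destination", "mass",
                     "nse_p", "pse_p", "nse_v", "pse_v"]


@dataclass
class EffectsResult:
    """Route-level effect tables plus summary accessors.

    ``route_effects``: one row per (year, product, exporter, importer)
    with netted mass and the four sending-receiving effects (kg).
    ``spillover_effects``: one row per attributed re-export chain
    (year, product, origin, intermediate, destination) with the four
    spillover effects (kg).
    """

    route_effects: pd.DataFrame
    spillover_effects: pd.DataFrame

    def product_summary(self, cumulative: bool = False) -> pd.DataFrame:
        """Per-product effect totals, annually or cumulated over years."""
        key = ["product"] if cumulative else ["year", "product"]
        sre = self.route_effects.groupby(key)[
            ["nsre_p", "psre_p", "nsre_v", "psre_v"]].sum()
        spill = self.spillover_effects.groupby(key)[
            ["nse_p", "pse_p", "nse_v", "pse_v"]].sum()
        return (sre.join(spill, how="outer").fillna(0.0).reset_index())

    def telecoupling_summary(self, eq13_printed: bool = False
                             ) -> pd.DataFrame:
        """Annual telecoupling totals: TE = sum SRE + sum SE, per element
        and basis (columns ``nte_p``, ``pte_p``, ``nte_v``, ``pte_v``
        plus their SRE/SE addends, kg)."""
        sre = self.route_effects.groupby("year")[
            ["nsre_p", "psre_p", "nsre_v", "psre_v"]].sum()
        spill = self.spillover_effects.groupby("year")[
            ["nse_p", "pse_p", "nse_v", "pse_v"]].sum().astype(float)
        out = sre.join(spill, how="outer").fillna(0.0)
        out["nte_p"] = out["nsre_p"] + out["nse_p"]
        out["pte_p"] = out["psre_p"] + out["pse_p"]
        out["nte_v"] = out["nsre_v"] + out["nse_v"]
        if eq13_printed:
            out["pte_v"] = out["psre_v"] + out["pse_p"]
        else:
            out["pte_v"] = out["psre_v"] + out["pse_v"]
        return out.reset_index()


def compute_effects(trade: pd.DataFrame, contents: ContentResolver,
                    attribution: pd.DataFrame | None) -> EffectsResult:
    """Compute all route-level sending-receiving and spillover effects."""
    nt = netted_trade(trade, attribution)
    if nt.empty:
        return EffectsResult(pd.DataFrame(columns=ROUTE_EFFECT_COLUMNS),
                             pd.DataFrame(columns=SPILLOVER_COLUMNS))

    re = nt.copy()
    for el, p_col, v_col in (("N", "nsre_p", "nsre_v"),
                             ("P", "psre_p", "psre_v")):
        phys = contents.contents_for(re["exporter"], re["product"],
                                     "physical", el)
        v_a = contents.contents_for(re["exporter"], re["product"],
                                    "virtual", el)
        v_b = contents.contents_for(re["importer"], re["product"],
                                    "virtual", el)
        re[p_col] = phys.to_numpy() * re["mass_net"].to_numpy()
        re[v_col] = (v_b.to_numpy() - v_a.to_numpy()) * \
            re["mass_net"].to_numpy()
    route_effects = re[ROUTE_EFFECT_COLUMNS]

    if attribution is None or attribution.empty:
        spill = pd.DataFrame(columns=SPILLOVER_COLUMNS)
    else:
        sp = attribution.copy()
        for el, p_col, v_col in (("N", "nse_p", "nse_v"),
                                 ("P", "pse_p", "pse_v")):
            phys = contents.contents_for(sp["origin"], sp["product"],
                                         "physical", el)
            v_a = contents.contents_for(sp["origin"], sp["product"],
                                        "virtual", el)
            v_c = contents.contents_for(sp["destination"], sp["product"],
                                        "virtual", el)
            sp[p_col] = phys.to_numpy() * sp["mass"].to_numpy()
            sp[v_col] = (v_c.to_numpy() - v_a.to_numpy()) * \
                sp["mass"].to_numpy()
        spill = sp[SPILLOVER_COLUMNS]
    return EffectsResult(route_effects, spill)


# -- per-product convenience wrappers ---------------------------------------

def sre_physical(trade, contents, attribution, product: str,
                 element: str) -> float:
    """Physical sending-receiving effect of one product, kg (>= 0)."""
    res = compute_effects(trade[trade["product"] == product], contents,
                          _filter_attr(attribution, product))
    col = "nsre_p" if element == "N" else "psre_p"
    return float(res.route_effects[col].sum())


def sre_virtual(trade, contents, attribution, product: str,
                element: str) -> float:
    """Virtual sending-receiving effect of one product, kg (signed)."""
    res = compute_effects(trade[trade["product"] == product], contents,
                          _filter_attr(attribution, product))
    col = "nsre_v" if element == "N" else "psre_v"
    return float(res.route_effects[col].sum())


def spillover_physical(attribution, contents, product: str,
                       element: str) -> float:
    """Physical spillover effect of one product's re-export chains, kg."""
    res = _spill_only(attribution, contents, product)
    col = "nse_p" if element == "N" else "pse_p"
    return float(res[col].sum()) if len(res) else 0.0


def spillover_virtual(attribution, contents, product: str,
                      element: str) -> float:
    """Virtual spillover effect of one product's re-export chains, kg."""
    res = _spill_only(attribution, contents, product)
    col = "nse_v" if element == "N" else "pse_v"
    return float(res[col].sum()) if len(res) else 0.0


def _filter_attr(attribution, product):
    if attribution is None or attribution.empty:
        return attribution
    return attribution[attribution["product"] == product]


def _spill_only(attribution, contents, product):
    att = _filter_attr(attribution, product)
    if att is None or att.empty:
        return pd.DataFrame(columns=SPILLOVER_COLUMNS)
    sp = att.copy()
    for el, p_col, v_col in (("N", "nse_p", "nse_v"),
                             ("P", "pse_p", "pse_v")):
        phys = contents.contents_for(sp["origin"], sp["product"],
                                     "physical", el)
        v_a = contents.contents_for(sp["origin"], sp["product"],
                                    "virtual", el)
        v_c = contents.contents_for(sp["destination"], sp["product"],
                                    "virtual", el)
        sp[p_col] = phys.to_numpy() * sp["mass"].to_numpy()
        sp[v_col] = (v_c.to_numpy() - v_a.to_numpy()) * sp["mass"].to_numpy()
    return sp


def telecoupling_total(result: EffectsResult,
                       eq13_printed: bool = False) -> pd.DataFrame:
    """Annual telecoupling totals (delegates to the result object)."""
    return result.telecoupling_summary(eq13_printed=eq13_printed)


# -- efficiency classification and grading ----------------------------------

def classify_routes(route_effects: pd.DataFrame,
                    element: str) -> pd.DataFrame:
    """Label each route efficient / inefficient / neutral.

    The label is the sign of the route's virtual sending-receiving
    effect: saving nutrients (> 0) is efficient, wasting (< 0) is
    inefficient, an exact zero is neutral.
    """
    col = "nsre_v" if element == "N" else "psre_v"
    out = route_effects[["year", "product", "exporter", "importer",
                         col]].copy()
    out["element"] = element
    out["label"] = "neutral"
    out.loc[out[col] > 0, "label"] = "efficient"
    out.loc[out[col] < 0, "label"] = "inefficient"
    return out.rename(columns={col: "sre_v"})


def grade_producers(virtual: pd.DataFrame, element: str) -> pd.DataFrame:
    """Three-grade production-efficiency ranking per product.

    Per product, producing countries are ranked by ascending virtual
    content (lower input per tonne = more efficient) and cut into
    rank-based tertiles of ceil(n/3): ``high``, ``medium``, ``low``.
    Ties break by country code; products with fewer than 3 producers
    grade every producer ``high`` (logged).
    """
    col = element.lower()
    rows = []
    for product, g in virtual.groupby("product"):
        g = g.sort_values([col, "country"], kind="stable")
        n = len(g)
        if n < 3:
            logger.warning("product %r has %d producer(s); grading all "
                           "'high'", product, n)
            grades = ["high"] * n
        else:
            size = math.ceil(n / 3)
            grades = ["high"] * size + ["medium"] * size
            grades += ["low"] * (n - len(grades))
            grades = grades[:n]
        for (_, r), grade in zip(g.iterrows(), grades):
            rows.append({"product": product, "country": r["country"],
                         "element": element, "grade": grade})
    return pd.DataFrame(rows, columns=["product", "country", "element",
                                       "grade"])


def classify_and_grade(route_effects: pd.DataFrame, virtual: pd.DataFrame,
                       element: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Route efficiency labels plus producer grades (see the two parts)."""
    return (classify_routes(route_effects, element),
            grade_producers(virtual, element))


def top_inefficient_routes(route_effects: pd.DataFrame,
                           virtual: pd.DataFrame, element: str, k: int,
                           year: int | None = None) -> pd.DataFrame:
    """The k routes with the most-negative virtual SRE.

    Stable sort (ascending SRE, then year/product/exporter/importer);
    sender and receiver producer grades are attached.  Fewer than k
    inefficient routes returns them all (logged).
    """
    labelled = classify_routes(route_effects, element)
    if year is not None:
        labelled = labelled[labelled["year"] == year]
    bad = labelled[labelled["label"] == "inefficient"]
    bad = bad.sort_values(["sre_v", "year", "product", "exporter",
                           "importer"], kind="stable")
    if len(bad) < k:
        logger.warning("only %d inefficient route(s) for k=%d",
                       len(bad), k)
    bad = bad.head(k).copy()
    grades = grade_producers(virtual, element).set_index(
        ["country", "product"])["grade"]
    idx_s = pd.MultiIndex.from_frame(bad[["exporter", "product"]])
    idx_r = pd.MultiIndex.from_frame(bad[["importer", "product"]])
    bad["sender_grade"] = grades.reindex(idx_s).to_numpy()
    bad["receiver_grade"] = grades.reindex(idx_r).to_numpy()
    return bad.reset_index(drop=True)


def country_efficiency(virtual: pd.DataFrame, trade: pd.DataFrame,
                       element: str) -> pd.DataFrame:
    """Overall nutrient conversion efficiency score per country.

    Trade-weighted mean of the country's per-product efficiency rank
    quantiles (0 = most efficient producer of the product, 1 = least),
    weighted by the country's export mass per product.  Products the
    country produces but never exports enter with equal weight.
    """
    col = element.lower()
    ranks = []
    for product, g in virtual.groupby("product"):
        g = g.sort_values([col, "country"], kind="stable").reset_index()
        q = (pd.Series(range(len(g)), dtype=float) /
             max(len(g) - 1, 1))
        ranks.append(pd.DataFrame({"country": g["country"],
                                   "product": product, "rank_q": q}))
    rank_df = pd.concat(ranks, ignore_index=True)
    w = (trade.groupby(["exporter", "product"], as_index=False)["mass"]
         .sum().rename(columns={"exporter": "country"}))
    merged = rank_df.merge(w, on=["country", "product"], how="left")
    merged["mass"] = merged["mass"].fillna(0.0)

    def _score(g):
        weights = g["mass"].to_numpy()
        if weights.sum() <= 0:
            weights = None
        return float(np.average(g["rank_q"], weights=weights))

    out = (merged.groupby("country")[["rank_q", "mass"]]
           .apply(_score).rename("efficiency_rank").reset_index())
    out["element"] = element
    return out
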