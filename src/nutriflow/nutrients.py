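"""Physical and virtual nutrient contents.

Physical content is the N or P mass literally contained in a tonne of
product; it is a per-product constant (country-invariant).  Virtual
content is the total nutrient *input* required to produce a tonne —
inorganic and organic fertiliser, seed, irrigation water, atmospheric
deposition and (for N) biological fixation — whether or not the crop
absorbed it.  Because nutrient-use efficiency differs between
countries, virtual content is country-specific: the same tonne of wheat
embodies more virtual N when grown by an inefficient producer.

The primary input path is a directly supplied virtual-content table;
:func:`crop_virtual_content` and :func:`animal_virtual_content` derive
one from production input budgets when no table is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContentLookupError, ValidationError

logger = logging.getLogger(__name__)

ELEMENTS = ("N", "P")
BASES = ("physical", "virtual")


@dataclass(frozen=True)
class InputBudget:
    """Per-hectare nutrient inputs and yield for one (country, product).

    All input terms are kg nutrient per hectare per season; ``yield_``
    is tonnes of product per hectare.  ``bnf`` (biological N fixation)
    applies to N only and is ignored for P.
    """

    country: str
    product: str
    inorganic_fert: float = 0.0
    organic_fert: float = 0.0
    seed: float = 0.0
    irrigation: float = 0.0
    deposition: float = 0.0
    bnf: float = 0.0
    yield_: float = 1.0

    def __post_init__(self):
        terms = (self.inorganic_fert, self.organic_fert, self.seed,
                 self.irrigation, self.deposition, self.bnf)
        if any(t < 0 for t in terms):
            raise ValidationError(f"negative input term in budget for "
                                  f"({self.country}, {self.product})")


def crop_virtual_content(budget: InputBudget, element: str) -> float:
    """Virtual content of a crop, kg nutrient per tonne of product.

    Total per-hectare nutrient input divided by yield.  The biological
    fixation term contributes to N only — there is no biological P
    fixation.
    """
    if budget.yield_ <= 0:
        raise ValidationError(
            f"yield must be positive, got {budget.yield_} for "
            f"({budget.country}, {budget.product})"
        )
    total = (budget.inorganic_fert + budget.organic_fert + budget.seed
             + budget.irrigation + budget.deposition)
    if element == "N":
        total += budget.bnf
    elif element != "P":
        raise ValueError(f"element must be 'N' or 'P', got {element!r}")
    return total / budget.yield_


def animal_virtual_content(product: str, country: str,
                           feeds: list[tuple[str, float]],
                           feed_contents: pd.DataFrame,
                           element: str,
                           non_feed_input: float = 0.0) -> float:
    """Virtual content of an animal product via its feed cascade, kg/t.

    ``feeds`` lists (feed_product, tonnes of feed per tonne of animal
    product); each feed's virtual content is looked up for the producing
    country in the canonical virtual table.  ``non_feed_input`` adds any
    further inputs per tonne of animal product (bedding, direct water
    nutrients); it defaults to zero.
    """
    col = element.lower()
    if col not in ("n", "p"):
        raise ValueError(f"element must be 'N' or 'P', got {element!r}")
    total = float(non_feed_input)
    for feed_product, factor in feeds:
        if factor < 0:
            raise ValidationError(
                f"negative feed conversion factor for {product}")
        sel = feed_contents[(feed_contents["country"] == country)
                            & (feed_contents["product"] == feed_product)]
        if sel.empty:
            raise ContentLookupError(
                f"no virtual {element} content for feed "
                f"({country}, {feed_product}) needed by {product}"
            )
        total += factor * float(sel[col].iloc[0])
    return total


def feed_conversion_table(conv: pd.DataFrame) -> dict[str, list[tuple[str, float]]]:
    """Index a feed-conversion table (animal_product, feed_product, factor)."""
    out: dict[str, list[tuple[str, float]]] = {}
    for row in conv.itertuples(index=False):
        out.setdefault(str(row.animal_product), []).append(
            (str(row.feed_product), float(row.factor)))
    return out


class ContentResolver:
    """Resolve nutrient content, kg/t, by (country, product, basis, element).

    Physical lookups ignore the country.  Virtual lookups return the
    country-specific value; when a (country, product) pair is missing
    from the virtual table the trade-weighted global mean content of the
    product is substituted (unweighted mean if no trade weights were
    given) and the fallback is logged.
    """

    def __init__(self, physical: pd.DataFrame,
                 virtual: pd.DataFrame | None = None,
                 trade: pd.DataFrame | None = None):
        self._physical = physical.set_index("product")[["n", "p"]]
        if self._physical.index.has_duplicates:
            raise ValidationError("duplicate product in physical table")
        if ((self._physical < 0) | (self._physical > 1000)).any().any():
            raise ValidationError(
                "physical contents must lie in [0, 1000] kg/t")
        if virtual is not None and len(virtual):
            self._virtual = virtual.set_index(["country", "product"])[["n", "p"]]
            if self._virtual.index.has_duplicates:
                raise ValidationError("duplicate (country, product) in "
                                      "virtual table")
        else:
            self._virtual = None
        self._fallback = self._product_means(virtual, trade)
        self.fallbacks_used: list[tuple[str, str]] = []

    @staticmethod
    def _product_means(virtual, trade) -> pd.DataFrame | None:
        """Per-product mean virtual content, trade-weighted if possible."""
        if virtual is None or not len(virtual):
            return None
        if trade is None or not len(trade):
            return virtual.groupby("product")[["n", "p"]].mean()
        weights = (trade.groupby(["exporter", "product"], as_index=False)
                        ["mass"].sum()
                        .rename(columns={"exporter": "country"}))
        merged = virtual.merge(weights, on=["country", "product"], how="left")
        merged["mass"] = merged["mass"].fillna(0.0)

        def _wmean(g: pd.DataFrame) -> pd.Series:
            w = g["mass"].to_numpy()
            if w.sum() <= 0:
                w = np.ones(len(g))
            return pd.Series({
                "n": float(np.average(g["n"], weights=w)),
                "p": float(np.average(g["p"], weights=w)),
            })

        return merged.groupby("product")[["n", "p", "mass"]].apply(_wmean)

    @property
    def products(self) -> set[str]:
        return set(self._physical.index)

    def resolve(self, country: str, product: str, basis: str,
                element: str) -> float:
        col = element.lower()
        if col not in ("n", "p"):
            raise ValueError(f"element must be 'N' or 'P', got {element!r}")
        if basis == "physical":
            try:
                return float(self._physical.at[product, col])
            except KeyError:
                raise ContentLookupError(
                    f"product {product!r} not in physical content table")
        if basis != "virtual":
            raise ValueError(f"basis must be 'physical' or 'virtual', "
                             f"got {basis!r}")
        if self._virtual is not None:
            try:
                return float(self._virtual.at[(country, product), col])
            except KeyError:
                pass
        if self._fallback is not None and product in self._fallback.index:
            logger.warning("virtual content fallback: (%s, %s) -> "
                           "trade-weighted product mean", country, product)
            self.fallbacks_used.append((country, product))
            return float(self._fallback.at[product, col])
        raise ContentLookupError(
            f"no virtual content for ({country!r}, {product!r}) and no "
            f"fallback mean available"
        )

    def contents_for(self, countries: pd.Series, products: pd.Series,
                     basis: str, element: str) -> pd.Series:
        """Vectorised :meth:`resolve` over aligned country/product Series."""
        pairs = pd.DataFrame({"country": countries.to_numpy(),
                              "product": products.to_numpy()})
        uniq = pairs.drop_duplicates()
        lut = {
            (r.country, r.product): self.resolve(r.country, r.product,
                                                 basis, element)
            for r in uniq.itertuples(index=False)
        }
        vals = [lut[(c, p)] for c, p in
                zip(pairs["country"], pairs["product"])]
        return pd.Series(vals, index=countries.index, dtype=float)
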