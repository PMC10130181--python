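"""Reading and writing the tabular formats the pipeline touches.

All tables travel as :class:`pandas.DataFrame` with canonical columns
and units:

==============  =========================================================
table           columns (canonical units)
==============  =========================================================
trade           year, exporter, importer, product, mass  [tonnes]
re-exports      year, intermediate, destination, product, mass  [tonnes]
production      year, country, product, production  [tonnes]
physical        product, n, p  [kg nutrient / tonne product]
virtual         country, product, n, p  [kg / tonne]
flows           year, product, exporter, importer, element, basis,
                amount  [kg nutrient]
==============  =========================================================

Two trade dialects are accepted: ``simple_long`` (the canonical columns
above) and ``long_faostat`` (the FAOSTAT detailed-trade-matrix layout
with Reporter/Partner country names and an Element column separating
export-reported from import-reported quantities).  Mirror double-reports
are reconciled with exporter priority: the importer's figure is used
only when no exporter report exists for the route.
"""

from __future__ import annotations

import logging

import pandas as pd

from .countries import CountrySet, to_iso3
from .errors import SchemaError, UnitError, ValidationError

logger = logging.getLogger(__name__)

TRADE_COLUMNS = ["year", "exporter", "importer", "product", "mass"]
REEXPORT_COLUMNS = ["year", "intermediate", "destination", "product", "mass"]
PRODUCTION_COLUMNS = ["year", "country", "product", "production"]

_FAOSTAT_REQUIRED = [
    "Reporter Countries", "Partner Countries", "Item", "Element",
    "Year", "Unit", "Value",
]
_FAOSTAT_MASS_UNITS = {"tonnes", "t", "tonne"}

#: content units accepted by :func:`read_content_table`, with the factor
#: converting to the canonical kg per tonne.  1 % of product mass is
#: 10 kg per tonne.
CONTENT_UNIT_FACTORS = {"percent": 10.0, "kg_per_tonne": 1.0}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_nonnegative(series: pd.Series, what: str, path) -> None:
    bad = series.index[series < 0]
    if len(bad):
        raise ValidationError(
            f"{path}: negative {what} at row index {bad[0]} "
            f"(value {series.loc[bad[0]]!r})"
        )


def reconcile_mirror_reports(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse exporter- and importer-reported rows to one record per route.

    ``df`` carries the canonical trade columns plus ``reported_by`` in
    ``{"exporter", "importer"}``.  Exporter reports win; importer reports
    fill routes the exporter never declared.  A table without the
    ``reported_by`` column is treated as already reconciled (duplicate
    keys are summed), which makes the operation idempotent.
    """
    key = ["year", "exporter", "importer", "product"]
    if "reported_by" not in df.columns:
        return (df.groupby(key, as_index=False)["mass"].sum()
                  .sort_values(key, ignore_index=True))
    exp = df[df["reported_by"] == "exporter"]
    imp = df[df["reported_by"] == "importer"]
    exp = exp.groupby(key, as_index=False)["mass"].sum()
    imp = imp.groupby(key, as_index=False)["mass"].sum()
    exp_keys = set(map(tuple, exp[key].itertuples(index=False)))
    imp_only = imp[[tuple(r) not in exp_keys
                    for r in imp[key].itertuples(index=False)]]
    if len(imp_only):
        logger.info("reconciliation: %d route(s) only importer-reported",
                    len(imp_only))
    out = pd.concat([exp, imp_only], ignore_index=True)
    return out.sort_values(key, ignore_index=True)


def read_trade_matrix(path, dialect: str = "simple_long",
                      aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a bilateral trade matrix CSV into the canonical trade table.

    Zero-mass rows are dropped; mirror double-reports are reconciled
    with exporter priority; country names are mapped to ISO3.
    """
    if dialect == "simple_long":
        df = pd.read_csv(path)
        _require_columns(df, TRADE_COLUMNS, path)
        df = df[TRADE_COLUMNS].copy()
    elif dialect == "long_faostat":
        raw = pd.read_csv(path)
        _require_columns(raw, _FAOSTAT_REQUIRED, path)
        bad_unit = set(raw["Unit"].str.strip().str.lower()) - _FAOSTAT_MASS_UNITS
        if bad_unit:
            raise UnitError(
                f"{path}: unsupported trade unit(s) {sorted(bad_unit)}; "
                f"expected one of {sorted(_FAOSTAT_MASS_UNITS)}"
            )
        elem = raw["Element"].str.strip()
        known = elem.isin(["Export Quantity", "Import Quantity"])
        if not known.all():
            raise SchemaError(
                f"{path}: unknown Element value(s) "
                f"{sorted(set(elem[~known]))}"
            )
        is_export = elem == "Export Quantity"
        reporter = raw["Reporter Countries"].map(lambda s: to_iso3(s, aliases))
        partner = raw["Partner Countries"].map(lambda s: to_iso3(s, aliases))
        df = pd.DataFrame({
            "year": raw["Year"].astype(int),
            "exporter": reporter.where(is_export, partner),
            "importer": partner.where(is_export, reporter),
            "product": raw["Item"].astype(str),
            "mass": raw["Value"].astype(float),
            "reported_by": is_export.map({True: "exporter",
                                          False: "importer"}),
        })
    else:
        raise ValueError(f"unknown trade dialect {dialect!r}")

    df["year"] = df["year"].astype(int)
    df["mass"] = df["mass"].astype(float)
    _check_nonnegative(df["mass"], "mass", path)
    self_trade = df.index[df["exporter"] == df["importer"]]
    if len(self_trade):
        raise ValidationError(
            f"{path}: exporter equals importer at row index {self_trade[0]}"
        )
    df = df[df["mass"] > 0]
    return reconcile_mirror_reports(df)


def read_content_table(path) -> pd.DataFrame:
    """Read a physical-content table (product, n_content, p_content, unit).

    Returns the canonical physical table (product, n, p) in kg per tonne.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["product", "n_content", "p_content", "unit"], path)
    if df.empty:
        return pd.DataFrame(columns=["product", "n", "p"])
    bad = set(df["unit"]) - set(CONTENT_UNIT_FACTORS)
    if bad:
        raise UnitError(
            f"{path}: unknown content unit(s) {sorted(bad)}; "
            f"expected one of {sorted(CONTENT_UNIT_FACTORS)}"
        )
    factor = df["unit"].map(CONTENT_UNIT_FACTORS)
    out = pd.DataFrame({
        "product": df["product"].astype(str),
        "n": df["n_content"].astype(float) * factor,
        "p": df["p_content"].astype(float) * factor,
    })
    _check_nonnegative(out["n"], "N content", path)
    _check_nonnegative(out["p"], "P content", path)
    return out


def read_content_long(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the long content layout: product, element, basis, country, value, unit.

    ``country`` is blank for the physical basis.  Returns
    ``(physical, virtual)`` canonical tables in kg per tonne.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    _require_columns(df, ["product", "element", "basis", "country",
                          "value", "unit"], path)
    bad = set(df["unit"]) - set(CONTENT_UNIT_FACTORS)
    if bad:
        raise UnitError(f"{path}: unknown content unit(s) {sorted(bad)}")
    df = df.copy()
    df["value"] = df["value"].astype(float) * df["unit"].map(CONTENT_UNIT_FACTORS)
    _check_nonnegative(df["value"], "content", path)
    df["element"] = df["element"].str.upper()
    if not set(df["element"]) <= {"N", "P"}:
        raise ValidationError(f"{path}: element must be N or P")

    def _pivot(sub: pd.DataFrame, index: list[str]) -> pd.DataFrame:
        if sub.empty:
            return pd.DataFrame(columns=index + ["n", "p"])
        wide = (sub.pivot_table(index=index, columns="element",
                                values="value", aggfunc="last")
                   .reset_index())
        wide.columns.name = None
        out = wide.rename(columns={"N": "n", "P": "p"})
        for col in ("n", "p"):
            if col not in out.columns:
                out[col] = float("nan")
        return out[index + ["n", "p"]]

    physical = _pivot(df[df["basis"] == "physical"], ["product"])
    virtual = _pivot(df[df["basis"] == "virtual"], ["country", "product"])
    return physical, virtual


def read_reexports(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, REEXPORT_COLUMNS, path)
    df = df[REEXPORT_COLUMNS].copy()
    df["mass"] = df["mass"].astype(float)
    _check_nonnegative(df["mass"], "re-export mass", path)
    return df[df["mass"] > 0].reset_index(drop=True)


def read_production(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PRODUCTION_COLUMNS, path)
    df = df[PRODUCTION_COLUMNS].copy()
    df["production"] = df["production"].astype(float)
    _check_nonnegative(df["production"], "production", path)
    return df


def read_adjacency(path, adjacent_km: float = 500.0) -> CountrySet:
    """Read a pairwise distance table (country_a, country_b, distance_km)."""
    df = pd.read_csv(path)
    _require_columns(df, ["country_a", "country_b", "distance_km"], path)
    cs = CountrySet(codes=set(df["country_a"]) | set(df["country_b"]),
                    adjacent_km=adjacent_km)
    for row in df.itertuples(index=False):
        cs.adjacency[cs._key(row.country_a, row.country_b)] = float(
            row.distance_km)
    return cs


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as UTF-8 CSV with full float precision.

    Column order is preserved; reading the file back with
    :func:`pandas.read_csv` reproduces the values to at least 10
    significant digits (floats are written with shortest-roundtrip repr).
    """
    if records is None:
        raise ValidationError("records must not be None")
    records.to_csv(path, index=False)
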