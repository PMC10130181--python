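"""Synthetic trade-world generator with ground-truth bookkeeping.

Generates worlds that mimic the statistical structure of a multi-year
FAOSTAT-style bilateral trade matrix: heavy-tailed (log-normal) route
volumes, a geometric multi-year growth trend, re-export hub countries
that pass a fraction of their imports onward, country-specific virtual
nutrient contents spread log-normally around product means, and animal
products whose virtual content cascades from their feed crops.

Every world carries a :class:`GroundTruth` — totals, budgets,
telecoupling effects and route efficiency labels evaluated at
generation time by direct, loop-based application of the defining
formulas, written independently of the pandas pipeline so that the
pipeline can be tested against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .countries import CountrySet, synthetic_codes
from .errors import ConfigurationError

_CROP_NAMES = ["wheat", "maize", "rice", "soybeans", "barley", "rapeseed",
               "potatoes", "sugar_cane", "coffee", "seed_cotton",
               "sunflower_seed", "lentils", "hazelnuts", "coconuts",
               "cassava", "sorghum"]
_ANIMAL_NAMES = ["beef", "pork", "poultry", "mutton", "goat_meat"]


@dataclass(frozen=True)
class WorldConfig:
    """Generator parameters; defaults are the study-scale surrogate.

    ``volume_lognormal`` is (mu, sigma) of log route tonnage in the
    first year; ``year_noise_sigma`` adds mean-one log-normal
    year-to-year noise on top of the persistent route volume, so the
    realised growth ratio is a stochastic estimate of
    ``growth_factor``.  ``nue_sigma`` is the log-normal spread of
    country virtual contents around each product's mean (nutrient-use
    efficiency heterogeneity); ``hub_passthrough`` is the fraction of a
    hub's imports re-exported onward.
    """

    n_countries: int = 30
    n_products: int = 10
    years: tuple[int, int] = (1997, 2001)
    route_density: float = 0.06
    volume_lognormal: tuple[float, float] = (6.0, 1.0)
    year_noise_sigma: float = 0.3
    growth_factor: float = 2.8
    n_content_range: tuple[float, float] = (5.0, 40.0)
    p_content_range: tuple[float, float] = (1.0, 8.0)
    virtual_uplift_range: tuple[float, float] = (1.5, 6.0)
    nue_sigma: float = 0.5
    n_hubs: int = 3
    hub_passthrough: float = 0.3
    hub_destinations: int = 2
    animal_fraction: float = 0.2
    feed_factor_range: tuple[float, float] = (2.0, 8.0)
    gravity_decay: float = 0.0
    map_size_km: float = 12000.0
    adjacent_km: float = 1500.0
    mirror_noise: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_countries < 2 or self.n_products < 1:
            raise ConfigurationError("need >= 2 countries and >= 1 product")
        for name in ("route_density", "hub_passthrough", "animal_fraction",
                     "mirror_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.growth_factor <= 0:
            raise ConfigurationError("growth_factor must be positive")
        if self.volume_lognormal[1] < 0 or self.nue_sigma < 0 \
                or self.year_noise_sigma < 0:
            raise ConfigurationError("sigmas must be non-negative")
        if self.years[1] < self.years[0]:
            raise ConfigurationError("year range must be increasing")
        if not 0 <= self.n_hubs <= self.n_countries:
            raise ConfigurationError("n_hubs must be <= n_countries")


@dataclass
class GroundTruth:
    """Quantities recorded at generation time by direct formula evaluation.

    Keys are tuples; nutrient amounts are kg.  ``total_flow`` is the
    gross Eq.-style sum content x mass over all trade records;
    ``net_budget`` is gross import minus gross export;
    ``telecoupling`` maps (year, element, basis) to dicts with ``sre``,
    ``spill`` and ``te``; ``route_label`` holds the efficiency label of
    every (year, product, exporter, importer, element) route.
    """

    total_flow: dict = field(default_factory=dict)
    net_budget: dict = field(default_factory=dict)
    telecoupling: dict = field(default_factory=dict)
    route_label: dict = field(default_factory=dict)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    countries: CountrySet
    trade: pd.DataFrame
    physical: pd.DataFrame
    virtual: pd.DataFrame
    production: pd.DataFrame
    reexports: pd.DataFrame
    feed_conversion: pd.DataFrame
    truth: GroundTruth | None


def _product_names(n: int, animal_fraction: float) -> tuple[list, list]:
    n_animal = int(round(n * animal_fraction))
    n_animal = min(n_animal, n - 1) if n > 1 else 0
    n_crop = n - n_animal
    crops = [_CROP_NAMES[i] if i < len(_CROP_NAMES) else f"crop_{i:03d}"
             for i in range(n_crop)]
    animals = [_ANIMAL_NAMES[i] if i < len(_ANIMAL_NAMES)
               else f"animal_{i:03d}" for i in range(n_animal)]
    return crops, animals


def generate(config: WorldConfig, compute_truth: bool = True
             ) -> SyntheticWorld:
    """Generate a world; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    codes = synthetic_codes(config.n_countries)
    crops, animals = _product_names(config.n_products,
                                    config.animal_fraction)
    products = crops + animals

    # --- geography: points in a square, Euclidean distances -------------
    xy = rng.uniform(0, config.map_size_km, size=(config.n_countries, 2))
    cs = CountrySet(codes=set(codes), adjacent_km=config.adjacent_km)
    for i in range(config.n_countries):
        cs.region_map[codes[i]] = (
            f"R{int(xy[i, 0] > config.map_size_km / 2)}"
            f"{int(xy[i, 1] > config.map_size_km / 2)}")
        for j in range(i + 1, config.n_countries):
            d = float(np.hypot(*(xy[i] - xy[j])))
            cs.adjacency[cs._key(codes[i], codes[j])] = d

    # --- nutrient contents ----------------------------------------------
    phys_n = rng.uniform(*config.n_content_range, size=len(products))
    phys_p = rng.uniform(*config.p_content_range, size=len(products))
    physical = pd.DataFrame({"product": products, "n": phys_n,
                             "p": phys_p})

    uplift = rng.uniform(*config.virtual_uplift_range, size=len(products))
    country_mult = np.exp(config.nue_sigma
                          * rng.standard_normal((config.n_countries,
                                                 len(products))))
    virt = {}
    for pi, prod in enumerate(products):
        if prod in animals:
            continue
        for ci, c in enumerate(codes):
            virt[(c, prod)] = (phys_n[pi] * uplift[pi] * country_mult[ci, pi],
                               phys_p[pi] * uplift[pi] * country_mult[ci, pi])
    # animal products: feed cascade over crop virtual contents
    feed_rows = []
    for pi, prod in enumerate(products):
        if prod not in animals:
            continue
        n_feeds = min(2, len(crops))
        if n_feeds == 0:  # no crops: fall back to direct draw
            for ci, c in enumerate(codes):
                virt[(c, prod)] = (
                    phys_n[pi] * uplift[pi] * country_mult[ci, pi],
                    phys_p[pi] * uplift[pi] * country_mult[ci, pi])
            continue
        feed_idx = rng.choice(len(crops), size=n_feeds, replace=False)
        factors = rng.uniform(*config.feed_factor_range, size=n_feeds)
        for fi, fac in zip(feed_idx, factors):
            feed_rows.append({"animal_product": prod,
                              "feed_product": crops[fi],
                              "factor": float(fac)})
        for c in codes:
            vn = sum(fac * virt[(c, crops[fi])][0]
                     for fi, fac in zip(feed_idx, factors))
            vp = sum(fac * virt[(c, crops[fi])][1]
                     for fi, fac in zip(feed_idx, factors))
            virt[(c, prod)] = (vn, vp)
    virtual = pd.DataFrame(
        [{"country": c, "product": p, "n": v[0], "p": v[1]}
         for (c, p), v in virt.items()])
    feed_conversion = pd.DataFrame(
        feed_rows, columns=["animal_product", "feed_product", "factor"])

    # --- routes and volumes ---------------------------------------------
    nc, npr = config.n_countries, len(products)
    pair_i, pair_j = np.where(~np.eye(nc, dtype=bool))
    n_pairs = len(pair_i)
    active = rng.random((n_pairs, npr)) < config.route_density
    ridx, pidx = np.where(active)
    mu, sigma = config.volume_lognormal
    base = np.exp(mu + sigma * rng.standard_normal(len(ridx)))
    if config.gravity_decay > 0:
        d = np.array([cs.adjacency[cs._key(codes[pair_i[r]],
                                           codes[pair_j[r]])]
                      for r in ridx])
        base = base * (config.adjacent_km / np.maximum(d,
                       config.adjacent_km)) ** config.gravity_decay

    y0, y1 = config.years
    years = list(range(y0, y1 + 1))
    t_span = max(len(years) - 1, 1)
    parts = []
    sy = config.year_noise_sigma
    for t, yr in enumerate(years):
        gfac = config.growth_factor ** (t / t_span) \
            if len(years) > 1 else 1.0
        noise = np.exp(-0.5 * sy ** 2
                       + sy * rng.standard_normal(len(ridx))) \
            if sy > 0 else 1.0
        parts.append(pd.DataFrame({
            "year": yr,
            "exporter": np.array(codes)[pair_i[ridx]],
            "importer": np.array(codes)[pair_j[ridx]],
            "product": np.array(products)[pidx],
            "mass": base * gfac * noise,
        }))
    trade = pd.concat(parts, ignore_index=True)

    # --- re-export hubs ---------------------------------------------------
    hub_reexports = []
    extra_flows = []
    if config.n_hubs > 0 and config.hub_passthrough > 0:
        imports_total = trade.groupby("importer")["mass"].sum()
        hubs = list(imports_total.sort_values(ascending=False)
                    .head(config.n_hubs).index)
        imp = trade[trade["importer"].isin(hubs)].groupby(
            ["year", "importer", "product"])["mass"].sum()
        for (yr, b, prod), m in imp.items():
            if m <= 0:
                continue
            total_re = config.hub_passthrough * m
            ndest = min(config.hub_destinations, nc - 1)
            others = [c for c in codes if c != b]
            dest = rng.choice(len(others), size=ndest, replace=False)
            split = rng.dirichlet(np.ones(ndest)) if ndest > 1 else [1.0]
            for di, s in zip(dest, split):
                mass = total_re * float(s)
                if mass <= 0:
                    continue
                hub_reexports.append({"year": yr, "intermediate": b,
                                      "destination": others[di],
                                      "product": prod, "mass": mass})
                extra_flows.append({"year": yr, "exporter": b,
                                    "importer": others[di],
                                    "product": prod, "mass": mass})
    reexports = pd.DataFrame(hub_reexports,
                             columns=["year", "intermediate", "destination",
                                      "product", "mass"])
    if extra_flows:
        trade = pd.concat([trade, pd.DataFrame(extra_flows)],
                          ignore_index=True)
    trade = (trade.groupby(["year", "exporter", "importer", "product"],
                           as_index=False)["mass"].sum())

    # --- production backing the exports ---------------------------------
    exports = (trade.groupby(["year", "exporter", "product"],
                             as_index=False)["mass"].sum()
               .rename(columns={"exporter": "country"}))
    if len(reexports):
        re_by_exp = (reexports.groupby(["year", "intermediate", "product"],
                                       as_index=False)["mass"].sum()
                     .rename(columns={"intermediate": "country",
                                      "mass": "reexported"}))
        exports = exports.merge(re_by_exp, on=["year", "country", "product"],
                                how="left")
        exports["reexported"] = exports["reexported"].fillna(0.0)
    else:
        exports["reexported"] = 0.0
    domestic = (exports["mass"] - exports["reexported"]).clip(lower=0.0)
    production = exports[["year", "country", "product"]].copy()
    production["production"] = domestic * rng.uniform(1.2, 3.0,
                                                      size=len(exports))

    truth = _compute_truth(trade, physical, virtual, reexports) \
        if compute_truth else None
    return SyntheticWorld(config, cs, trade, physical, virtual, production,
                          reexports, feed_conversion, truth)


def _compute_truth(trade: pd.DataFrame, physical: pd.DataFrame,
                   virtual: pd.DataFrame,
                   reexports: pd.DataFrame) -> GroundTruth:
    """Direct loop-based evaluation of the defining formulas.

    Deliberately plain-Python (dicts and loops, no groupbys) so it is an
    independent re-derivation rather than a re-run of the pipeline.
    """
    phys = {r.product: {"N": r.n, "P": r.p}
            for r in physical.itertuples(index=False)}
    virt = {(r.country, r.product): {"N": r.n, "P": r.p}
            for r in virtual.itertuples(index=False)}
    records = [(int(r.year), r.product, r.exporter, r.importer,
                float(r.mass)) for r in trade.itertuples(index=False)]
    re_records = [(int(r.year), r.intermediate, r.destination, r.product,
                   float(r.mass)) for r in reexports.itertuples(index=False)]

    gt = GroundTruth()

    def content(basis, element, country, product):
        if basis == "physical":
            return phys[product][element]
        return virt[(country, product)][element]

    # gross totals and budgets
    for basis in ("physical", "virtual"):
        for element in ("N", "P"):
            for yr, prod, a, b, mass in records:
                amt = content(basis, element, a, prod) * mass
                key = (yr, element, basis)
                gt.total_flow[key] = gt.total_flow.get(key, 0.0) + amt
                ka = (yr, a, element, basis)
                kb = (yr, b, element, basis)
                gt.net_budget[ka] = gt.net_budget.get(ka, 0.0) - amt
                gt.net_budget[kb] = gt.net_budget.get(kb, 0.0) + amt

    # proportional origin attribution of re-exports
    imports = {}
    for yr, prod, a, b, mass in records:
        imports.setdefault((yr, b, prod), {})
        imports[(yr, b, prod)][a] = imports[(yr, b, prod)].get(a, 0.0) + mass
    attribution = []  # (year, product, origin, intermediate, dest, mass)
    for yr, b, c, prod, mass in re_records:
        origin_masses = imports.get((yr, b, prod), {})
        total = sum(origin_masses.values())
        if total <= 0:
            continue
        for a, m in origin_masses.items():
            attribution.append((yr, prod, a, b, c, mass * m / total))

    netted = {(yr, prod, a, b): mass for yr, prod, a, b, mass in records}
    for yr, prod, a, b, c, mass in attribution:
        netted[(yr, prod, a, b)] -= mass
    for key, m in netted.items():
        if m < 0:
            netted[key] = 0.0

    # sending-receiving, spillover, telecoupling, labels
    for element in ("N", "P"):
        sre_p, sre_v = {}, {}
        for (yr, prod, a, b), m in netted.items():
            sre_p[yr] = sre_p.get(yr, 0.0) + phys[prod][element] * m
            dv = virt[(b, prod)][element] - virt[(a, prod)][element]
            sre_v[yr] = sre_v.get(yr, 0.0) + dv * m
            lab = "efficient" if dv * m > 0 else (
                "inefficient" if dv * m < 0 else "neutral")
            gt.route_label[(yr, prod, a, b, element)] = lab
        sp_p, sp_v = {}, {}
        for yr, prod, a, b, c, m in attribution:
            sp_p[yr] = sp_p.get(yr, 0.0) + phys[prod][element] * m
            dv = virt[(c, prod)][element] - virt[(a, prod)][element]
            sp_v[yr] = sp_v.get(yr, 0.0) + dv * m
        for yr in {r[0] for r in records}:
            gt.telecoupling[(yr, element, "physical")] = {
                "sre": sre_p.get(yr, 0.0), "spill": sp_p.get(yr, 0.0),
                "te": sre_p.get(yr, 0.0) + sp_p.get(yr, 0.0)}
            gt.telecoupling[(yr, element, "virtual")] = {
                "sre": sre_v.get(yr, 0.0), "spill": sp_v.get(yr, 0.0),
                "te": sre_v.get(yr, 0.0) + sp_v.get(yr, 0.0)}
    return gt


# -- presets and fixtures -----------------------------------------------------

_PRESETS = {
    "tiny": dict(n_countries=5, n_products=3, years=(1997, 1998),
                 route_density=0.5, n_hubs=1, animal_fraction=0.34),
    "small": dict(n_countries=30, n_products=10, years=(1997, 2001),
                  route_density=0.06, n_hubs=3),
    "paper_shape": dict(n_countries=221, n_products=320,
                        years=(1997, 2016), route_density=0.0023,
                        n_hubs=8),
}


def scale_down_preset(name: str, **overrides) -> WorldConfig:
    """A named scale preset: ``tiny`` (exhaustive-oracle scale),
    ``small`` (default desk scale) or ``paper_shape`` (full network
    shape at low density)."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return WorldConfig(**{**_PRESETS[name], **overrides})


def faostat_fixture(world: SyntheticWorld, path,
                    mirror_noise: float | None = None) -> None:
    """Write the world's trade as a FAOSTAT detailed-trade-matrix CSV.

    Every route is emitted as an exporter-reported row plus a mirrored
    importer-reported row whose quantity is perturbed by a uniform
    relative ``mirror_noise`` (default from the world config), so
    parsing exercises the exporter-priority reconciliation and
    reproduces the generator's masses exactly.
    """
    noise = world.config.mirror_noise if mirror_noise is None else mirror_noise
    rng = np.random.default_rng(world.config.seed + 1)
    t = world.trade
    perturb = 1.0 + noise * rng.uniform(-1, 1, size=len(t))
    exp_rows = pd.DataFrame({
        "Reporter Countries": t["exporter"],
        "Partner Countries": t["importer"],
        "Item": t["product"],
        "Element": "Export Quantity",
        "Year": t["year"],
        "Unit": "tonnes",
        "Value": t["mass"],
    })
    imp_rows = pd.DataFrame({
        "Reporter Countries": t["importer"],
        "Partner Countries": t["exporter"],
        "Item": t["product"],
        "Element": "Import Quantity",
        "Year": t["year"],
        "Unit": "tonnes",
        "Value": t["mass"] * perturb,
    })
    pd.concat([exp_rows, imp_rows], ignore_index=True).to_csv(path,
                                                              index=False)


def write_world(world: SyntheticWorld, outdir) -> dict:
    """Write all world tables (CSV) plus the ground truth (JSON).

    Returns the mapping of table name to file path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "trade": world.trade,
        "production": world.production,
        "reexports": world.reexports,
        "feed_conversion": world.feed_conversion,
    }
    for name, df in tables.items():
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False)

    # long content layout shared by physical and virtual entries
    long_rows = []
    for r in world.physical.itertuples(index=False):
        for el, v in (("N", r.n), ("P", r.p)):
            long_rows.append({"product": r.product, "element": el,
                              "basis": "physical", "country": "",
                              "value": v, "unit": "kg_per_tonne"})
    for r in world.virtual.itertuples(index=False):
        for el, v in (("N", r.n), ("P", r.p)):
            long_rows.append({"product": r.product, "element": el,
                              "basis": "virtual", "country": r.country,
                              "value": v, "unit": "kg_per_tonne"})
    paths["contents"] = outdir / "contents.csv"
    pd.DataFrame(long_rows).to_csv(paths["contents"], index=False)

    adj_rows = [{"country_a": a, "country_b": b, "distance_km": d}
                for (a, b), d in world.countries.adjacency.items()]
    paths["adjacency"] = outdir / "adjacency.csv"
    pd.DataFrame(adj_rows).to_csv(paths["adjacency"], index=False)
    paths["regions"] = outdir / "regions.csv"
    pd.DataFrame([{"country": c, "region": r}
                  for c, r in world.countries.region_map.items()]
                 ).to_csv(paths["regions"], index=False)

    if world.truth is not None:
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump({
                "total_flow": {"|".join(map(str, k)): v
                               for k, v in world.truth.total_flow.items()},
                "net_budget": {"|".join(map(str, k)): v
                               for k, v in world.truth.net_budget.items()},
                "telecoupling": {"|".join(map(str, k)): v
                                 for k, v in
                                 world.truth.telecoupling.items()},
            }, fh, indent=1)
    paths["config"] = outdir / "world_config.json"
    with open(paths["config"], "w") as fh:
        json.dump(asdict(world.config), fh, indent=1)
    return paths
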