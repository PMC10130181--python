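# Methods

This note records the accounting model implemented by `nutriflow`, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the package's numerical
conventions.

## Flow accounting

A trade route is a (year, exporter, importer, product) record with mass
in tonnes. Its nutrient flow is content × mass, in kg. Physical
contents (kg nutrient per tonne of product) are per-product constants;
virtual contents are per-(country, product) because nutrient-use
efficiency differs between producers. On the virtual basis the
*exporter's* content is used at the route level: virtual nutrients are
inputs spent where the product was grown.

Virtual content of a crop, when derived from an input budget rather
than supplied directly, is the total per-hectare input —
inorganic fertiliser + organic fertiliser (which includes manure; there
is no internal manure-cycling model) + seed + irrigation water +
atmospheric deposition + biological N fixation (N only) — divided by
yield (t/ha). It is therefore homogeneous of degree 0 under joint
scaling of inputs and yield and degree 1 in inputs alone. Animal
products cascade from feed: Σ (feed conversion factor × feed virtual
content in the producing country), plus a configurable additive
non-feed term defaulting to 0, since published budgets rarely separate
bedding/water inputs. A directly supplied virtual-content table is the
primary input path and overrides both derivations.

When a (country, product) virtual content is missing, the resolver
substitutes the product's trade-weighted global mean (unweighted if no
trade weights are available) and logs the fallback; dropping routes
silently would bias totals downward.

## Double-report reconciliation

FAOSTAT-style matrices report many routes twice (exporter- and
importer-reported). The package keeps the exporter-reported quantity
and uses importer reports only for routes the exporter never declared.
A priority rule is deterministic and preserves mass through re-export
netting, which symmetric averaging would not; the choice is this
package's convention, documented rather than inferred from any
statistical agency's practice.

## Re-exports

Two modes:

* **declared** — explicit (year, intermediate, destination, product,
  mass) records are used verbatim;
* **inferred** — the re-exported share of each export B → C equals B's
  import share of apparent supply, imports / (production + imports),
  per product-year. This is the standard physical-trade apportionment
  assumption; it makes re-export mass weakly decreasing in domestic
  production.

Each re-export B → C_k is attributed to origins A proportionally to
B's import-origin shares for that product-year, so attribution sums to
the re-export mass exactly. Attribution is single-hop (chains
A → B → C_k); multi-hop fixed-point tracing is deliberately out of
scope because the effect equations are written over single chains.
Products are netted independently — no tracing across processing
stages (soybeans → soybean oil). Re-exports exceeding imports are
capped at imports with a warning (strict mode raises); netted bilateral
masses are floored at zero with a warning, since mirror-inconsistent
statistics occur in real data but negative consumption is unphysical.

## Effects

Per route, with netted mass `m = T(A,B) − Σ attributed re-exports`:

* physical SRE = physical content × m (≥ 0);
* virtual SRE = (importer content − exporter content) × m, signed;
  positive = nutrient saving (efficient flow), negative = wasting
  (inefficient); exactly zero = neutral, counted in neither tally;
* physical SE (per chain) = physical content × re-exported mass;
* virtual SE = (final-destination content − origin content) ×
  re-exported mass;
* TE = Σ SRE + Σ SE per element and basis, an exact identity in the
  output tables.

Note the onward leg B → C_k usually also exists as a trade record; its
own SRE is computed on its (netted) mass with B's contents. Netting is
applied on the inbound route A → B, so per product the physical SRE
plus physical spillover equals the gross flow total exactly (the
closure identity tested in the suite).

One published variant of the virtual P telecoupling total sums the
*physical* P spillover into it; the package treats that as a
transcription slip and keeps all four totals basis-consistent, but
exposes the variant behind `telecoupling_summary(eq13_printed=True)`
rather than ignoring it.

Producer grading per product ranks countries by ascending virtual
content and cuts rank tertiles of ⌈n/3⌉ (high, then medium, remainder
low; ties broken by country code). With fewer than 3 producers all are
graded high and a warning is logged. The per-country "overall
conversion efficiency" score is the export-mass-weighted mean of the
country's per-product rank quantiles; no standard formula exists for
this summary, so it is isolated in `country_efficiency` and used only
for reporting.

## Synthetic worlds

The generator emulates the structure a multi-year global
bilateral-trade extract actually has, at configurable scale:

* route incidence: each ordered country pair trades each product with
  probability `route_density`, fixed across years (routes persist);
* volumes: log-normal base volume per route (`volume_lognormal`,
  default mu 6, sigma 1 — median ≈ 400 t with a heavy tail), times a
  deterministic geometric year factor reaching `growth_factor`
  (default 2.8) across the year range, times mean-one log-normal
  year noise (`year_noise_sigma`, default 0.3). The noise makes the
  realised last/first-year ratio a stochastic estimate of the growth
  factor, so recovery tests are statistically meaningful rather than
  tautological;
* contents: physical N ~ U(5, 40) kg/t and P ~ U(1, 8) kg/t per
  product; virtual product means are physical × U(1.5, 6); country
  values multiply the mean by exp(nue_sigma · z), z ~ N(0,1)
  (default nue_sigma 0.5). Animal products (default 20% of products)
  get feed-cascade contents from two crop feeds with conversion
  factors U(2, 8) t/t;
* re-export hubs: the `n_hubs` largest importers re-export
  `hub_passthrough` (default 0.3) of their imports per product-year to
  uniformly drawn destinations; the onward flows are added to the
  trade table so re-exports never exceed imports or exports;
* production backs exports: each exporter's domestic production is
  (exports − declared re-exports) × U(1.2, 3), so inferred-mode
  preconditions always hold;
* geography: countries are uniform points in a square
  (`map_size_km`, default 12 000 km); pairs within `adjacent_km`
  (default 1 500 km) are adjacent; regions are map quadrants. Optional
  `gravity_decay` applies distance decay to volumes (off by default —
  plain log-normal volumes already reproduce the heavy tail).

Presets: `tiny` (5 countries × 3 products × 2 years, exhaustive-oracle
scale), `small` (30 × 10 × 5, the default desk scale used by the test
suite and the acceptance script), `paper_shape` (221 × 320 × 20 years
at density 0.0023, ≈ 26 000 final-year pair routes — smoke-tested for
shape, not asserted numerically).

`GroundTruth` (totals, net budgets, telecoupling components, route
labels) is computed at generation time by plain-loop evaluation of the
defining formulas, independent of the pandas pipeline, so
pipeline-vs-truth comparisons are genuine cross-checks. For
`paper_shape`-scale worlds truth computation can be skipped
(`compute_truth=False`).

What the generator does **not** emulate: FAOSTAT's country-specific
reporting gaps and unit quirks, price-driven route formation,
processing chains between product codes, and any calibration to real
marginals. Passing tests therefore demonstrate that the accounting is
exact and the statistical machinery recovers known structure — not
that real-data estimates are unbiased; with real inputs the dominant
uncertainties are the content tables and mirror-statistic quality.

## Numerical conventions

Canonical units: tonnes (mass), kg/t (content), kg (nutrient amounts);
reports convert to Gg (10⁶ kg) and Tg (10⁹ kg). Percent contents
convert at 1% = 10 kg/t. Zero-mass trade rows are dropped at read
time. Top-k rankings sort by (value descending, country code
ascending) for determinism; k beyond the sender count is capped so the
share reaches 1. Ratio censuses exclude zero-physical routes and
report them separately. Distance strata with no routes are absent from
output, not zero. All randomness is scoped to per-world
`numpy.random.Generator` instances seeded from the config — no global
state, so parallel test runs are reproducible.

Problem sizes used by the test suite and acceptance script — `tiny`
for exact oracle comparisons, 50 `small` worlds for identity checks,
20 seeds for statistical recovery — are the package's chosen desk
scale: large enough for ≥ 500 routes per world (where ratio estimators
concentrate), small enough to keep the full suite interactive.

## Known limitations

* Single-hop re-export attribution; chains deeper than one transit are
  attributed only proportionally at each independent step.
* Virtual contents for livestock ignore enteric/excretion recycling
  credits; the additive non-feed term is a placeholder for such
  refinements.
* The affected-cropland estimate is a straight quotient of net outflow
  by consumption per unit area; it ignores crop mix and within-country
  heterogeneity.
* Mirror reconciliation cannot recover from routes that *both* parties
  misreport; strict mode only surfaces, not fixes, such data.
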