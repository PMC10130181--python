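# nutriflow

Accounting for the nitrogen (N) and phosphorus (P) that international
agricultural trade moves around the planet — both the **physical**
nutrients literally contained in shipped products and the **virtual**
nutrients that were spent producing them (fertiliser, manure, seed,
irrigation water, atmospheric deposition and biological N fixation,
whether or not the crop absorbed them).

`nutriflow` is for agro-environmental researchers who work with
bilateral trade matrices in the FAOSTAT "detailed trade matrix" layout
and want reproducible, testable answers to questions like: which
countries are net nutrient senders and receivers; how concentrated are
exports among top senders; how much of a flow is really a re-export
passing through a transit hub; and does a given trade route *save* or
*waste* nutrients globally, given that nutrient-use efficiency differs
between producers.

## The accounting model

For product *i* traded from exporter *A* to importer *B*, the embedded
nutrient flow is

```
F_{i,A,B} = C_{i,A,B} × T_{i,A,B}
```

with `T` the traded mass (tonnes) and `C` the nutrient content
(kg/tonne) — a per-product constant on the physical basis, the
*producer's* country-specific value on the virtual basis.

Because importers also act as re-export transit stations, each
re-export `B → C_k` is attributed back to origin countries `A` in
proportion to `B`'s import-origin shares, giving single-hop chains
`A → B → C_k`. Effects are then decomposed per route:

* **sending–receiving effect (SRE)** — on the mass `B` actually
  retains, `T_{A,B} − T_{B,C_k}`: physically the transferred nutrient
  mass `N_{p,i} × (T_{A,B} − T_{B,C_k})`; virtually the signed
  `(N_{v,i,B} − N_{v,i,A}) × (T_{A,B} − T_{B,C_k})`, positive when
  trade saved nutrients (an *efficient* flow), negative when it wasted
  them (*inefficient*);
* **spillover effect (SE)** — on the re-exported mass:
  `N_{p,i} × T_{B,C_k}` physically, and virtually
  `(N_{v,i,C_k} − N_{v,i,A}) × T_{B,C_k}`, origin content against
  final-destination content;
* **telecoupling effect (TE)** — per element and basis,
  `TE = Σ SRE + Σ SE`.

Producers are additionally graded `high`/`medium`/`low` per product by
rank tertiles of ascending virtual content, and inefficient routes can
be ranked by most-negative virtual SRE.

Because real multi-country content tables are large external datasets,
the package ships a seeded synthetic world generator
(`nutriflow.synthetic`) reproducing the statistical structure of such
data — heavy-tailed lognormal route volumes, multi-year geometric
growth, re-export hubs, lognormal cross-country efficiency spread,
feed-cascade animal products — together with generation-time ground
truth that the pipeline is tested against.

## Worked example

```python
import nutriflow as nf

world = nf.generate(nf.scale_down_preset("tiny", seed=11))
resolver = nf.ContentResolver(world.physical, world.virtual, world.trade)
attribution = nf.attribute_origins(world.reexports, world.trade)

flows = nf.compute_all_flows(world.trade, resolver)
budgets = nf.country_budgets(flows)
summary = nf.network_summary(flows, budgets, ks=(3,))
print(summary[summary.basis == "physical"]
      [["year", "element", "total_flow", "n_routes", "top3_share"]]
      .to_string(index=False))
```

```
 year element   total_flow  n_routes  top3_share
 1997       N 6.489136e+05        20         1.0
 1997       P 1.220687e+05        20         1.0
 1998       N 1.738159e+06        20         1.0
 1998       P 3.265822e+05        20         1.0
```

In 1997 this 5-country world traded 6.49 × 10⁵ kg of physical N over 20
bilateral routes, and its top 3 net-sending countries account for all
net exports (`top3_share = 1.0`). Continuing with the effect
decomposition:

```python
result = nf.compute_effects(world.trade, resolver, attribution)
print(result.telecoupling_summary()[["year", "nsre_v", "nse_v", "nte_v"]]
      .to_string(index=False))
print(nf.classify_routes(result.route_effects, "N")["label"]
      .value_counts().to_dict())
```

```
 year        nsre_v          nse_v          nte_v
 1997 -58836.295921 -293215.821160 -352052.117081
 1998  56832.020976 -800297.888304 -743465.867328
{'inefficient': 45, 'efficient': 38}
```

The virtual N telecoupling effect is negative in both years (−3.5 × 10⁵
and −7.4 × 10⁵ kg): in this particular world, trade routed products
from less efficient to more efficient producers on balance, wasting
virtual N — 45 product-routes are inefficient against 38 efficient.

The same pipeline is available from the shell:

```
nutriflow simulate --preset small --seed 42 --out world/
nutriflow run --trade world/trade.csv --contents world/contents.csv \
    --reexport-mode declared --reexports world/reexports.csv --out run/
nutriflow report --rundir run/
```

`run/` then holds `flows.csv`, `budgets.csv`, `network_summary.csv`,
route and spillover effect tables, a telecoupling summary, a
`manifest.json` with input checksums and per-stage totals, and a
markdown report in Tg (10⁹ kg).

### Trade fixture format

The `simple_long` dialect is plain CSV (masses in tonnes):

```
year,exporter,importer,product,mass
2016,USA,CHN,soybeans,1200000
2016,BRA,CHN,soybeans,900000
2016,ARG,CHN,soybean_cake,300000
2016,USA,MEX,maize,800000
2016,FRA,DEU,wheat,400000
2016,DEU,NLD,wheat,120000
2016,NLD,GBR,wheat,60000
2016,IND,SGP,rice,250000
2016,SGP,AUS,rice,40000
2016,AUS,IDN,beef,50000
```

The `long_faostat` dialect accepts the FAOSTAT detailed-trade-matrix
columns (`Reporter Countries`, `Partner Countries`, `Item`, `Element`,
`Year`, `Unit`, `Value`); exporter-reported quantities take priority
over importer-reported mirrors of the same route.

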