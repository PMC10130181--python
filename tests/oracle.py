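"""Brute-force reference implementation used to cross-check the pipeline.

Written independently of the package internals: plain Python dicts and
loops over record tuples, no pandas groupbys, evaluating the defining
formulas one route at a time.  Deliberately slow and only suitable for
worlds of a few countries and products.
"""

from __future__ import annotations


def records(trade_df):
    """Trade DataFrame -> list of (year, product, exporter, importer, mass)."""
    return [(int(r.year), r.product, r.exporter, r.importer, float(r.mass))
            for r in trade_df.itertuples(index=False)]


def content_tables(physical_df, virtual_df):
    phys = {r.product: {"N": float(r.n), "P": float(r.p)}
            for r in physical_df.itertuples(index=False)}
    virt = {(r.country, r.product): {"N": float(r.n), "P": float(r.p)}
            for r in virtual_df.itertuples(index=False)}
    return phys, virt


def flows(recs, phys, virt, basis, element):
    """Route flow amounts: {(year, product, A, B): kg}."""
    out = {}
    for yr, prod, a, b, mass in recs:
        c = phys[prod][element] if basis == "physical" \
            else virt[(a, prod)][element]
        out[(yr, prod, a, b)] = out.get((yr, prod, a, b), 0.0) + c * mass
    return out

def budgets(flow_map):
    """{(year, country): (gross_export, gross_import, net)}."""
    out = {}
    for (yr, _prod, a, b), amt in flow_map.items():
        ea, ia, _ = out.get((yr, a), (0.0, 0.0, 0.0))
        out[(yr, a)] = (ea + amt, ia, ia - (ea + amt))
        eb, ib, _ = out.get((yr, b), (0.0, 0.0, 0.0))
        out[(yr, b)] = (eb, ib + amt, (ib + amt) - eb)
    return out


def top_k_share(budget_map, year, k):
    senders = sorted(
        [(-net, c) for (yr, c), (_, _, net) in budget_map.items()
         if yr == year and net < 0],
        key=lambda t: (-t[0], t[1]))
    total = sum(v for v, _ in senders)
    if total <= 0:
        return float("nan")
    return sum(v for v, _ in senders[:k]) / total


def attribute(recs, reexp_recs):
    """Proportional origin attribution.

    ``reexp_recs``: list of (year, intermediate, destination, product,
    mass).  Returns list of (year, product, origin, intermediate,
    destination, mass).
    """
    imports = {}
    for yr, prod, a, b, mass in recs:
        imports.setdefault((yr, b, prod), {}).setdefault(a, 0.0)
        imports[(yr, b, prod)][a] += mass
    out = []
    for yr, b, c, prod, mass in reexp_recs:
        shares = imports.get((yr, b, prod), {})
        total = sum(shares.values())
        if total <= 0:
            continue
        for a, m in shares.items():
            out.append((yr, prod, a, b, c, mass * m / total))
    return out


def netted(recs, attribution):
    out = {}
    for yr, prod, a, b, mass in recs:
        out[(yr, prod, a, b)] = out.get((yr, prod, a, b), 0.0) + mass
    for yr, prod, a, b, _c, mass in attribution:
        out[(yr, prod, a, b)] -= mass
    return {k: max(v, 0.0) for k, v in out.items()}


def effects(recs, reexp_recs, phys, virt, element):
    """Per-year SRE/spillover/telecoupling sums for both bases.

    Returns {(year, basis): {"sre": kg, "spill": kg, "te": kg}}.
    """
    attribution = attribute(recs, reexp_recs)
    net_map = netted(recs, attribution)
    out = {}
    years = {r[0] for r in recs}
    for yr in years:
        sre_p = sre_v = sp_p = sp_v = 0.0
        for (y, prod, a, b), m in net_map.items():
            if y != yr:
                continue
            sre_p += phys[prod][element] * m
            sre_v += (virt[(b, prod)][element]
                      - virt[(a, prod)][element]) * m
        for (y, prod, a, _b, c, m) in attribution:
            if y != yr:
                continue
            sp_p += phys[prod][element] * m
            sp_v += (virt[(c, prod)][element]
                     - virt[(a, prod)][element]) * m
        out[(yr, "physical")] = {"sre": sre_p, "spill": sp_p,
                                 "te": sre_p + sp_p}
        out[(yr, "virtual")] = {"sre": sre_v, "spill": sp_v,
                                "te": sre_v + sp_v}
    return out


def route_sre_virtual(recs, reexp_recs, phys, virt, element):
    """Signed virtual SRE per route: {(year, product, A, B): kg}."""
    attribution = attribute(recs, reexp_recs)
    net_map = netted(recs, attribution)
    return {
        (yr, prod, a, b):
        (virt[(b, prod)][element] - virt[(a, prod)][element]) * m
        for (yr, prod, a, b), m in net_map.items()
    }
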