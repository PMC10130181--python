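"""Sending-receiving, spillover and telecoupling effect computation."""

import pandas as pd
import pytest

import nutriflow as nf
from nutriflow import effects as fx
from conftest import make_physical, make_trade, make_virtual
import oracle


@pytest.fixture()
def wheat_setup(wheat_world):
    trade, reexp, physical, virtual = wheat_world
    resolver = nf.ContentResolver(physical, virtual)
    attribution = nf.attribute_origins(reexp, trade)
    return trade, reexp, physical, virtual, resolver, attribution


class TestSendingReceiving:
    def test_no_reexports_equals_total_physical_flow(self):
        trade = make_trade([(2000, "AAA", "BBB", "wheat", 100.0)])
        r = nf.ContentResolver(make_physical([("wheat", 20.0, 4.0)]),
                               make_virtual([("AAA", "wheat", 30, 6),
                                             ("BBB", "wheat", 50, 10)]))
        assert fx.sre_physical(trade, r, None, "wheat", "N") == \
            pytest.approx(2000.0)

    def test_reexported_mass_removed_from_physical_sre(self, wheat_setup):
        trade, _, _, _, resolver, att = wheat_setup
        # A->B 100 t at 20 kg N/t with 20 t re-exported: 20 x 80 = 1600,
        # plus the B->C leg netted to zero (fully re-exported).
        got = fx.sre_physical(trade, resolver, att, "wheat", "N")
        assert got == pytest.approx(1600.0)

    def test_virtual_sre_signed_content_difference(self, wheat_setup):
        trade, _, _, _, resolver, att = wheat_setup
        # (50-30) x 80 on A->B; B->C netted to 0 -> +1600 kg saved
        got = fx.sre_virtual(trade, resolver, att, "wheat", "N")
        assert got == pytest.approx(1600.0)

    def test_identical_contents_give_zero_virtual_sre(self):
        trade = make_trade([(2000, "AAA", "BBB", "wheat", 10.0)])
        r = nf.ContentResolver(make_physical([("wheat", 20, 4)]),
                               make_virtual([("AAA", "wheat", 30, 6),
                                             ("BBB", "wheat", 30, 6)]))
        assert fx.sre_virtual(trade, r, None, "wheat", "N") == 0.0

    def test_swapping_contents_flips_sign_exactly(self):
        phys = make_physical([("wheat", 20, 4)])
        trade = make_trade([(2000, "AAA", "BBB", "wheat", 10.0)])
        r1 = nf.ContentResolver(phys, make_virtual(
            [("AAA", "wheat", 30, 6), ("BBB", "wheat", 50, 10)]))
        r2 = nf.ContentResolver(phys, make_virtual(
            [("AAA", "wheat", 50, 10), ("BBB", "wheat", 30, 6)]))
        a = fx.sre_virtual(trade, r1, None, "wheat", "N")
        b = fx.sre_virtual(trade, r2, None, "wheat", "N")
        assert a == pytest.approx(200.0)
        assert b == -a


class TestSpillover:
    def test_zero_reexport_means_zero_spillover(self, wheat_setup):
        trade, _, _, _, resolver, _ = wheat_setup
        assert fx.spillover_physical(None, resolver, "wheat", "N") == 0.0
        assert fx.spillover_virtual(None, resolver, "wheat", "N") == 0.0

    def test_physical_spillover_is_content_times_reexport(self, wheat_setup):
        _, _, _, _, resolver, att = wheat_setup
        assert fx.spillover_physical(att, resolver, "wheat", "N") == \
            pytest.approx(400.0)  # 20 kg/t x 20 t

    def test_virtual_spillover_uses_origin_vs_final_destination(
            self, wheat_setup):
        _, _, _, _, resolver, att = wheat_setup
        # (45 - 30) x 20 = 300 kg: origin A content vs destination C
        assert fx.spillover_virtual(att, resolver, "wheat", "N") == \
            pytest.approx(300.0)

    def test_physical_closure_per_product(self, wheat_setup):
        trade, _, _, _, resolver, att = wheat_setup
        total = nf.compute_flows(trade, resolver, "physical", "N")[
            "amount"].sum()
        sre = fx.sre_physical(trade, resolver, att, "wheat", "N")
        spill = fx.spillover_physical(att, resolver, "wheat", "N")
        assert sre + spill == pytest.approx(total, rel=1e-12)


class TestTelecoupling:
    def test_empty_network_all_totals_zero(self):
        r = nf.ContentResolver(make_physical([("wheat", 20, 4)]),
                               make_virtual([("AAA", "wheat", 30, 6)]))
        res = nf.compute_effects(make_trade([]), r, None)
        assert res.route_effects.empty
        assert res.telecoupling_summary().empty

    def test_totals_match_bruteforce_on_tiny_world(self, tiny_world,
                                                   resolver):
        att = nf.attribute_origins(tiny_world.reexports, tiny_world.trade)
        res = nf.compute_effects(tiny_world.trade, resolver, att)
        tele = res.telecoupling_summary().set_index("year")
        recs = oracle.records(tiny_world.trade)
        re_recs = [(int(r.year), r.intermediate, r.destination, r.product,
                    float(r.mass))
                   for r in tiny_world.reexports.itertuples(index=False)]
        phys, virt = oracle.content_tables(tiny_world.physical,
                                           tiny_world.virtual)
        for el, c in (("N", "n"), ("P", "p")):
            want = oracle.effects(recs, re_recs, phys, virt, el)
            for (yr, basis), d in want.items():
                suffix = "p" if basis == "physical" else "v"
                assert tele.loc[yr, f"{c}te_{suffix}"] == pytest.approx(
                    d["te"], rel=1e-12)

    def test_decomposition_identity_exact(self, small_world):
        r = nf.ContentResolver(small_world.physical, small_world.virtual)
        att = nf.attribute_origins(small_world.reexports, small_world.trade)
        tele = nf.compute_effects(small_world.trade, r,
                                  att).telecoupling_summary()
        assert (tele["nte_p"] == tele["nsre_p"] + tele["nse_p"]).all()
        assert (tele["pte_p"] == tele["psre_p"] + tele["pse_p"]).all()
        assert (tele["nte_v"] == tele["nsre_v"] + tele["nse_v"]).all()
        assert (tele["pte_v"] == tele["psre_v"] + tele["pse_v"]).all()

    def test_printed_eq13_variant_behind_flag(self, small_world):
        r = nf.ContentResolver(small_world.physical, small_world.virtual)
        att = nf.attribute_origins(small_world.reexports, small_world.trade)
        res = nf.compute_effects(small_world.trade, r, att)
        printed = res.telecoupling_summary(eq13_printed=True)
        assert (printed["pte_v"] == printed["psre_v"]
                + printed["pse_p"]).all()

    def test_removing_reexports_leaves_only_sre(self, small_world):
        r = nf.ContentResolver(small_world.physical, small_world.virtual)
        res = nf.compute_effects(small_world.trade, r, None)
        tele = res.telecoupling_summary()
        assert res.spillover_effects.empty
        assert (tele["nte_v"] == tele["nsre_v"]).all()
        assert (tele["nse_p"] == 0).all()


class TestClassificationAndGrading:
    def test_sign_rule_labels(self, wheat_setup):
        trade, _, _, virtual, resolver, att = wheat_setup
        res = nf.compute_effects(trade, resolver, att)
        labels = nf.classify_routes(res.route_effects, "N").set_index(
            ["exporter", "importer"])
        # importer content (50) exceeds exporter content (30): saving
        assert labels.loc[("AAA", "BBB"), "label"] == "efficient"
        # a fully re-exported route has zero netted mass -> neutral
        zero = nf.compute_effects(
            make_trade([(2000, "AAA", "BBB", "wheat", 100.0)]), resolver,
            pd.DataFrame([(2000, "wheat", "AAA", "BBB", "CCC", 100.0)],
                         columns=["year", "product", "origin",
                                  "intermediate", "destination", "mass"]))
        lab0 = nf.classify_routes(zero.route_effects, "N")
        assert (lab0["label"] == "neutral").all()

    def test_equal_contents_everywhere_all_neutral(self):
        trade = make_trade([(2000, "AAA", "BBB", "wheat", 10.0),
                            (2000, "BBB", "CCC", "wheat", 5.0)])
        r = nf.ContentResolver(make_physical([("wheat", 20, 4)]),
                               make_virtual([("AAA", "wheat", 30, 6),
                                             ("BBB", "wheat", 30, 6),
                                             ("CCC", "wheat", 30, 6)]))
        res = nf.compute_effects(trade, r, None)
        labels = nf.classify_routes(res.route_effects, "N")
        assert (labels["label"] == "neutral").all()

    def test_nine_countries_cut_into_three_tertiles(self):
        virtual = make_virtual([(f"C{i:02d}", "wheat", 10.0 + i, 2.0 + i)
                                for i in range(9)])
        grades = nf.grade_producers(virtual, "N").set_index("country")
        assert (grades["grade"].value_counts() == 3).all()
        assert grades.loc["C00", "grade"] == "high"
        assert grades.loc["C04", "grade"] == "medium"
        assert grades.loc["C08", "grade"] == "low"

    def test_fewer_than_three_producers_all_high(self):
        virtual = make_virtual([("AAA", "wheat", 10, 2),
                                ("BBB", "wheat", 20, 4)])
        grades = nf.grade_producers(virtual, "N")
        assert (grades["grade"] == "high").all()

    def test_labels_match_truth_on_tiny_world(self, tiny_world, resolver):
        att = nf.attribute_origins(tiny_world.reexports, tiny_world.trade)
        res = nf.compute_effects(tiny_world.trade, resolver, att)
        for el in ("N", "P"):
            labels = nf.classify_routes(res.route_effects, el)
            for r in labels.itertuples(index=False):
                want = tiny_world.truth.route_label[
                    (r.year, r.product, r.exporter, r.importer, el)]
                assert r.label == want


class TestTopInefficientRoutes:
    def _setup(self):
        virtual = make_virtual([("AAA", "wheat", 50, 10),
                                ("BBB", "wheat", 45, 9),
                                ("CCC", "wheat", 30, 6),
                                ("DDD", "wheat", 20, 4)])
        trade = make_trade([
            (2016, "AAA", "CCC", "wheat", 1.0),   # (30-50)x1 = -20
            (2016, "BBB", "CCC", "wheat", 0.5),   # (30-45)x0.5 = -7.5
            (2016, "DDD", "AAA", "wheat", 1.0),   # (50-20)x1 = +30
        ])
        r = nf.ContentResolver(make_physical([("wheat", 20, 4)]), virtual)
        res = nf.compute_effects(trade, r, None)
        return res, virtual

    def test_most_negative_first_and_length_capped(self):
        res, virtual = self._setup()
        top = nf.top_inefficient_routes(res.route_effects, virtual, "N", 2)
        assert len(top) == 2
        assert list(top["exporter"]) == ["AAA", "BBB"]
        assert top.loc[0, "sre_v"] == pytest.approx(-20.0)

    def test_grades_attached_to_routes(self):
        res, virtual = self._setup()
        # ascending content: DDD, CCC | BBB, AAA (ceil(4/3)=2 per tertile)
        top = nf.top_inefficient_routes(res.route_effects, virtual, "N", 1)
        assert top.loc[0, "sender_grade"] == "medium"  # AAA least efficient
        assert top.loc[0, "receiver_grade"] == "high"

    def test_no_inefficient_routes_empty_list(self):
        virtual = make_virtual([("AAA", "wheat", 10, 2),
                                ("BBB", "wheat", 20, 4),
                                ("CCC", "wheat", 30, 6)])
        trade = make_trade([(2016, "AAA", "BBB", "wheat", 1.0)])
        r = nf.ContentResolver(make_physical([("wheat", 20, 4)]), virtual)
        res = nf.compute_effects(trade, r, None)
        assert nf.top_inefficient_routes(res.route_effects, virtual,
                                         "N", 5).empty


class TestCountryEfficiency:
    def test_rank_quantiles_weighted_by_exports(self):
        virtual = make_virtual([("AAA", "wheat", 10, 2),
                                ("BBB", "wheat", 20, 4),
                                ("CCC", "wheat", 30, 6)])
        trade = make_trade([(2016, "AAA", "BBB", "wheat", 5.0)])
        out = nf.country_efficiency(virtual, trade, "N").set_index("country")
        assert out.loc["AAA", "efficiency_rank"] == 0.0
        assert out.loc["BBB", "efficiency_rank"] == pytest.approx(0.5)
        assert out.loc["CCC", "efficiency_rank"] == 1.0
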