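"""Relative intrinsic activity, bias factors, rankings and group tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from opbias.bias import (
    compare_groups,
    compute_bias_factor,
    compute_RAi,
    compute_RAi_table,
    format_ranking,
    rank_constructs,
)
from opbias.datasets import load_ga16_panel, load_m2_m5_variants
from opbias.models import HillFit, OperationalFit


def op(tau, pka, emax=30.7, **kw):
    return OperationalFit(system_Emax=emax, tau=tau, pKA=pka, **kw)


class TestComputeRAi:
    def test_self_reference_is_unity(self):
        f = HillFit(pEC50=6.99, EmaxPrime=18.0, nH=1.0)
        assert compute_RAi(f, f).RAi == pytest.approx(1.0, abs=1e-12)

    def test_oxotremorine_vs_carbachol_published_m2_row(self):
        """E'MAX/EC50 route reproduces the published M2-fusion value."""
        t3 = load_m2_m5_variants()
        rows = t3[(t3.receptor == "M2") & (t3.variant == "fused")]
        cbc = rows[rows.ligand == "carbachol"].iloc[0]
        oxo = rows[rows.ligand == "oxotremorine"].iloc[0]
        r = compute_RAi(
            HillFit(pEC50=oxo.pEC50_neg_log10_M,
                    EmaxPrime=oxo.EmaxPrime_fold_over_basal, nH=1.0),
            HillFit(pEC50=cbc.pEC50_neg_log10_M,
                    EmaxPrime=cbc.EmaxPrime_fold_over_basal, nH=1.0))
        assert r.RAi == pytest.approx(21.13, abs=0.05)  # own arithmetic
        assert r.RAi == pytest.approx(float(oxo.RAi), rel=0.05)  # printed 21.4

    def test_iperoxo_vs_carbachol_published_wt_m5_row(self):
        """tau/K_A route reproduces the published wild-type M5 value."""
        t3 = load_m2_m5_variants()
        rows = t3[(t3.receptor == "M5") & (t3.variant == "wt")]
        cbc = rows[rows.ligand == "carbachol"].iloc[0]
        ipx = rows[rows.ligand == "iperoxo"].iloc[0]
        r = compute_RAi(op(ipx.tau, ipx.pKA_neg_log10_M),
                        op(cbc.tau, cbc.pKA_neg_log10_M))
        assert r.RAi == pytest.approx(893.1, abs=1.0)  # own arithmetic
        assert r.RAi == pytest.approx(float(ipx.RAi), rel=0.05)  # printed 912

    def test_non_responder_gets_zero(self):
        r = compute_RAi(op(0.0, None), op(1.41, 6.6))
        assert r.RAi == 0.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            compute_RAi_table({"a": op(1.0, 7.0)}, "carbachol")

    def test_nonunit_slope_rejected_for_hill_route(self):
        with pytest.raises(ValueError, match="unit Hill slope"):
            compute_RAi(HillFit(pEC50=7.0, EmaxPrime=10.0, nH=1.6),
                        HillFit(pEC50=7.0, EmaxPrime=10.0, nH=1.0))

    @given(tau_a=st.floats(0.1, 10.0), pka_a=st.floats(5.0, 9.0),
           tau_r=st.floats(0.1, 10.0), pka_r=st.floats(5.0, 9.0))
    def test_orientation_consistency(self, tau_a, pka_a, tau_r, pka_r):
        """RA_i > 1 exactly when log(tau/K_A) exceeds the reference's."""
        r = compute_RAi(op(tau_a, pka_a), op(tau_r, pka_r))
        lhs = math.log10(tau_a) + pka_a
        rhs = math.log10(tau_r) + pka_r
        assert (r.RAi > 1.0) == (lhs > rhs) or math.isclose(lhs, rhs)


class TestBiasFactor:
    def test_self_comparison_is_unity(self):
        fits = {"oxo": op(2.8, 7.64), "cbc": op(1.41, 6.6)}
        r = compute_bias_factor(fits, fits, "oxo", "cbc")
        assert r.bias_factor == pytest.approx(1.0, abs=1e-12)

    def test_published_m2_vs_m4_oxotremorine(self):
        """Direct arithmetic oracle on the published panel parameters."""
        panel = load_ga16_panel().set_index(["receptor", "ligand"])

        def fits(rec):
            return {lig: op(panel.loc[(rec, lig)].tau,
                            panel.loc[(rec, lig)].pKA_neg_log10_M)
                    for lig in ("carbachol", "oxotremorine")}

        r = compute_bias_factor(fits("M2"), fits("M4"), "oxotremorine",
                                "carbachol", "M2", "M4")
        # oracle: (log 2.799 + 7.64 - log 1.41 - 6.6)
        #       - (log 0.994 + 7.95 - log 0.897 - 7.1) = 0.4432
        assert r.ddlog_tau_over_KA == pytest.approx(0.4432, abs=0.001)
        assert r.bias_factor == pytest.approx(2.774, abs=0.01)

    @given(ta=st.floats(0.1, 10), pa=st.floats(5, 9), tb=st.floats(0.1, 10),
           pb=st.floats(5, 9), tr=st.floats(0.1, 10), pr=st.floats(5, 9),
           ts=st.floats(0.1, 10), ps=st.floats(5, 9))
    def test_antisymmetry(self, ta, pa, tb, pb, tr, pr, ts, ps):
        a = {"x": op(ta, pa), "ref": op(tr, pr)}
        b = {"x": op(tb, pb), "ref": op(ts, ps)}
        fwd = compute_bias_factor(a, b, "x", "ref").bias_factor
        rev = compute_bias_factor(b, a, "x", "ref").bias_factor
        assert fwd * rev == pytest.approx(1.0, rel=1e-9)

    def test_reference_shift_invariance(self):
        """Adding a constant to all log(tau/K_A) at one construct cancels."""
        a = {"x": op(2.0, 7.0), "ref": op(1.0, 6.0)}
        a_shift = {"x": op(20.0, 7.0), "ref": op(10.0, 6.0)}  # +1 log unit each
        b = {"x": op(1.5, 6.5), "ref": op(0.8, 6.2)}
        r1 = compute_bias_factor(a, b, "x", "ref").ddlog_tau_over_KA
        r2 = compute_bias_factor(a_shift, b, "x", "ref").ddlog_tau_over_KA
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_tau_zero_is_undefined(self):
        a = {"x": op(0.0, None), "ref": op(1.0, 6.0)}
        b = {"x": op(1.0, 6.0), "ref": op(1.0, 6.0)}
        r = compute_bias_factor(a, b, "x", "ref")
        assert not r.defined


class TestEq7Eq8Identity:
    def test_routes_agree_under_plain_ceiling_convention(self):
        """tau/K_A and E'MAX/EC50 give identical RA_i for unit slopes."""
        from opbias.models import hill_to_operational

        emax = 30.7
        hills = {"cbc": HillFit(pEC50=6.99, EmaxPrime=18.0, nH=1.0),
                 "oxo": HillFit(pEC50=8.22, EmaxPrime=22.4, nH=1.0)}
        ops = {k: hill_to_operational(h, emax, baseline="plain")
               for k, h in hills.items()}
        via_hill = compute_RAi(hills["oxo"], hills["cbc"]).RAi
        via_op = compute_RAi(ops["oxo"], ops["cbc"]).RAi
        assert via_op == pytest.approx(via_hill, rel=1e-9)


class TestRankConstructs:
    @pytest.mark.parametrize("ligand, expected", [
        ("arecoline", "M2 > M4 ~ M3 > M5 > M1"),
        ("furmethide", "M2 > M5 ~ M4 > M1 > M3"),
        ("McN-A-343", "M2 > M4 > M5 > M1 > M3"),
        ("pilocarpine", "M2 > M5 > M3 ~ M1 > M4"),
        ("xanomeline", "M2 > M5 > M4 > M1 > M3"),
        ("oxotremorine", "M2 > M5 > M1 ~ M3 > M4"),
    ])
    def test_published_orderings_reproduced(self, ligand, expected):
        panel = load_ga16_panel()
        sub = panel[panel.ligand == ligand]
        vals = dict(zip(sub.receptor, sub.RAi))
        sds = dict(zip(sub.receptor, sub.RAi_sd.fillna(0.0)))
        assert format_ranking(rank_constructs(vals, sds)) == expected

    def test_all_equal_is_single_tie_group(self):
        groups = rank_constructs({"A": 2.0, "B": 2.0, "C": 2.0},
                                 {"A": 0.1, "B": 0.1, "C": 0.1})
        assert len(groups) == 1 and set(groups[0]) == {"A", "B", "C"}

    def test_relative_difference_fallback_without_sds(self):
        groups = rank_constructs({"A": 1.0, "B": 0.95, "C": 0.5})
        assert groups == [["A", "B"], ["C"]]


class TestCompareGroups:
    def test_identical_groups_not_flagged(self):
        rng = np.random.default_rng(0)
        g = {k: 5.0 + 0.1 * rng.standard_normal(3) for k in "abc"}
        out = compare_groups(g)
        assert not out["flags_withheld"]
        assert not out["tukey"]["reject"].any() or out["anova_p"] >= 0.05

    def test_small_groups_withhold_flags(self):
        with pytest.warns(UserWarning, match="withheld"):
            out = compare_groups({"a": [1.0, 2.0], "b": [1.5, 2.5]})
        assert out["flags_withheld"]

    def test_published_pka_contrast_flagged(self):
        """Fusion vs cotransfection pKA difference (oxotremorine at M2)."""
        rng = np.random.default_rng(42)
        groups = {"M2_coexpr": 6.26 + 0.10 * rng.standard_normal(3),
                  "M2_fusion": 7.64 + 0.08 * rng.standard_normal(3)}
        out = compare_groups(groups)
        assert out["anova_p"] < 0.05
        assert out["tukey"]["reject"].all()

    def test_power_for_twofold_tau_difference(self):
        """tau 2.8 vs 1.41 at 3% CV, n=3, separates in >= 95% of runs."""
        n_sim = 500
        hits = 0
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            a = 2.8 * (1.0 + 0.03 * rng.standard_normal(3))
            b = 1.41 * (1.0 + 0.03 * rng.standard_normal(3))
            out = compare_groups({"a": a, "b": b}, log_scale=True)
            hits += bool(out["anova_p"] < 0.05
                         and out["tukey"]["reject"].all())
        assert hits / n_sim >= 0.95
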