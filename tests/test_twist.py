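"""TWIST estimators: identities, IVW algebra, recovery, assumption checks."""
from __future__ import annotations

import numpy as np
import pytest

from pgxtwist import (
    EstimateWithSE,
    FitError,
    TwistGMTE,
    assumption_checks,
    cat_estimate,
    combine_ivw,
    fit_additive_hazards,
    gmte_components,
    mr_estimate,
    run_twist,
    ryr3_hf_config,
    simulate_cohort,
    truth_analysis_table,
)
from pgxtwist.twist import _select_combination, cochran_q


class TestIVWAlgebra:
    def test_equal_pair_closed_form(self):
        v, s = 0.4, 0.1
        res = combine_ivw([EstimateWithSE("A", v, s), EstimateWithSE("B", v, s)])
        assert res.combined.estimate == pytest.approx(v)
        assert res.combined.se == pytest.approx(s / np.sqrt(2))

    def test_hand_computed_example(self):
        # weights 100 and 25: mean (50 + 22.5)/125 = 0.58, se = 1/sqrt(125),
        # Q = 100*(0.08)^2 + 25*(0.32)^2 = 3.2 on 1 dof (p ~ 0.074)
        a = EstimateWithSE("RGMTE", 0.5, 0.1)
        b = EstimateWithSE("MR", 0.9, 0.2)
        q, dof, p = cochran_q([a, b])
        assert q == pytest.approx(3.2, abs=1e-9)
        assert dof == 1
        assert 0.07 < p < 0.08
        res = combine_ivw([a, b])
        assert res.combined.estimate == pytest.approx(0.58, abs=1e-12)
        assert res.combined.se == pytest.approx(0.0894427, abs=1e-6)
        assert res.selected == ("RGMTE", "MR")

    def test_heterogeneous_pair_not_combined(self):
        a = EstimateWithSE("RGMTE", 0.0, 0.05)
        b = EstimateWithSE("MR", 1.0, 0.05)
        res = combine_ivw([a, b])
        assert res.selected == ("RGMTE",)
        assert "heterogeneous" in res.note

    def test_single_estimate_passthrough(self):
        a = EstimateWithSE("RGMTE", 0.3, 0.1)
        res = combine_ivw([a])
        assert res.combined.estimate == a.estimate
        assert "passthrough" in res.note

    def test_combined_variance_never_exceeds_components(self):
        ests = [EstimateWithSE(l, e, s) for l, e, s in
                [("RGMTE", 0.5, 0.1), ("MR", 0.55, 0.2), ("CAT", 0.45, 0.15)]]
        res = combine_ivw(ests)
        assert res.combined.variance <= min(e.variance for e in ests)

    def test_selection_prefers_largest_consistent_set(self):
        r = EstimateWithSE("RGMTE", 0.5, 0.1)
        m = EstimateWithSE("MR", 0.52, 0.1)
        c = EstimateWithSE("CAT", 5.0, 0.1)  # wildly heterogeneous
        res = _select_combination(r, m, c)
        assert res.selected == ("RGMTE", "MR")

    def test_empty_input_rejected(self):
        with pytest.raises(FitError):
            combine_ivw([])


@pytest.fixture(scope="module")
def small_suite(ryr3_small_table):
    return run_twist(ryr3_small_table, "rs877087", "hf")


class TestComponents:
    def test_rgmte_identity_machine_precision(self, small_suite):
        s = small_suite
        assert s.rgmte.estimate == pytest.approx(
            s.gmte1.estimate - s.gmte0.estimate, abs=1e-18
        )
        assert s.rgmte.variance == pytest.approx(
            s.gmte1.variance + s.gmte0.variance, rel=1e-12
        )

    def test_mr_equals_gmte1_when_everyone_treated(self):
        cfg = ryr3_hf_config(n_treated=6_000, n_untreated=0, seed=23)
        tab = truth_analysis_table(simulate_cohort(cfg))
        mr, _ = mr_estimate(tab, "rs877087", "hf", covariates=())
        df = tab.assign(carrier=(tab["g_rs877087"] > 0).astype(float))
        g1 = fit_additive_hazards(df, ["carrier"], "hf_time", "hf_event")
        assert mr.estimate == pytest.approx(g1.estimate("carrier")[0], rel=1e-9)

    def test_component_recovery_with_direct_genotype_effect(self):
        # bG = 0.0002, bGT = 0.0007: GMTE1 targets their sum, RGMTE the
        # interaction alone; averaged over seeds both recover within MC error
        g1s, rgs, g0s = [], [], []
        for s in range(6):
            cfg = ryr3_hf_config(
                n_treated=25_000, n_untreated=120_000, seed=300 + s,
                beta_geno=0.0002, beta_interact=0.0007,
            )
            tab = truth_analysis_table(simulate_cohort(cfg))
            g1, g0, rg, _ = gmte_components(tab, "rs877087", "hf", covariates=())
            g1s.append(g1.estimate)
            g0s.append(g0.estimate)
            rgs.append(rg.estimate)
        mc = lambda xs: np.std(xs) / np.sqrt(len(xs))
        assert abs(np.mean(g1s) - 0.0009) < 3 * mc(g1s) + 1e-5
        assert abs(np.mean(g0s) - 0.0002) < 3 * mc(g0s) + 1e-5
        assert abs(np.mean(rgs) - 0.0007) < 3 * mc(rgs) + 1e-5

    def test_cat_recovers_interaction(self):
        cfg = ryr3_hf_config(n_treated=25_000, n_untreated=120_000, seed=31)
        tab = truth_analysis_table(simulate_cohort(cfg))
        cat, _ = cat_estimate(tab, "rs877087", "hf", covariates=())
        assert abs(cat.estimate - 0.00069) < 2.5 * cat.se

    def test_confounded_treatment_biases_as_treated_not_rgmte(self):
        # frailty raises both treatment odds and the hazard: the naive
        # as-treated treatment coefficient is biased upward, while RGMTE
        # (and CAT, whose strata biases cancel) still target the interaction
        cfg = ryr3_hf_config(
            n_treated=25_000, n_untreated=120_000, seed=37, confounding=0.004
        )
        tab_truth = simulate_cohort(cfg)
        tab = truth_analysis_table(tab_truth)
        df = tab.assign(treated=tab["treated"].astype(float))
        naive = fit_additive_hazards(df, ["treated"], "hf_time", "hf_event")
        bias = naive.estimate("treated")[0] - cfg.beta_treat - 0.708 * cfg.beta_interact
        assert bias > 3 * naive.estimate("treated")[1]  # clearly confounded
        _, _, rg, _ = gmte_components(tab, "rs877087", "hf", covariates=())
        assert abs(rg.estimate - cfg.beta_interact) < 2.5 * rg.se
        cat, _ = cat_estimate(tab, "rs877087", "hf", covariates=())
        assert abs(cat.estimate - cfg.beta_interact) < 2.5 * cat.se

    def test_missing_subset_is_error(self, ryr3_small_table):
        treated_only = ryr3_small_table[ryr3_small_table["treated"] == 1]
        with pytest.raises(FitError):
            gmte_components(treated_only, "rs877087", "hf")


class TestAssumptionChecks:
    def test_default_generator_passes(self, ryr3_small_table):
        rep = assumption_checks(ryr3_small_table, "rs877087")
        treatment = rep[rep["check"] == "genotype_independent_of_treatment"]
        assert len(treatment) == 1
        assert bool(treatment["passed"].iloc[0])

    def test_violation_mode_detected(self):
        cfg = ryr3_hf_config(
            n_treated=7_000, n_untreated=43_000, seed=41, treat_geno_or=1.5
        )
        tab = truth_analysis_table(simulate_cohort(cfg))
        rep = assumption_checks(tab, "rs877087")
        treatment = rep[rep["check"] == "genotype_independent_of_treatment"]
        assert not bool(treatment["passed"].iloc[0])

    def test_constant_covariate_skipped_with_note(self, ryr3_small_table):
        tab = ryr3_small_table.assign(pc1=0.0)
        rep = assumption_checks(tab, "rs877087")
        row = rep[rep["check"] == "genotype_vs_pc1"]
        assert "skipped" in row["note"].iloc[0]
        assert bool(row["passed"].iloc[0])


class TestRunTwist:
    def test_suite_structure_and_report(self, small_suite):
        est = small_suite.estimates()
        assert est["label"].tolist()[:5] == ["GMTE1", "GMTE0", "RGMTE", "MR", "CAT"]
        assert (est["se"] > 0).all()
        report = small_suite.report()
        for section in ("RGMTE", "Heterogeneity", "Assumption checks", "GMTE0"):
            assert section in report

    def test_combined_variance_bounded_by_selected_components(self, small_suite):
        sel = small_suite.combination.selected
        comp = {
            "RGMTE": small_suite.rgmte,
            "MR": small_suite.mr,
            "CAT": small_suite.cat,
        }
        if len(sel) > 1:
            assert small_suite.combined.variance <= min(
                comp[l].variance for l in sel if l in comp
            )

    def test_gmte0_nonnull_marks_mr_suspect(self):
        cfg = ryr3_hf_config(
            n_treated=10_000, n_untreated=100_000, seed=43, beta_geno=0.001
        )
        tab = truth_analysis_table(simulate_cohort(cfg))
        suite = run_twist(tab, "rs877087", "hf", covariates=())
        assert suite.gmte0.p <= 0.05
        assert "suspect" in suite.combination.note

    def test_estimator_interface(self, ryr3_small_table):
        tw = TwistGMTE(variant="rs877087", outcome="hf").fit(ryr3_small_table)
        assert tw.combined_.se > 0
        assert tw.rgmte_.estimate == pytest.approx(
            tw.gmte1_.estimate - tw.gmte0_.estimate
        )
        assert tw.get_params()["variant"] == "rs877087"
        assert "TWIST" in tw.report()
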