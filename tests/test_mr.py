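"""Harmonization, Wald/IVW/Egger/median/mode estimators, MR-PRESSO,
one-sample 2SLS, multivariable MR and cross-cohort heterogeneity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mrphewas as mp
from mrphewas.errors import EstimationError, InputError, MethodError
from mrphewas.mr import _weighted_median


def _stats_frame(rows, role="exposure"):
    beta_col = "beta_exposure" if role == "exposure" else "beta_outcome"
    se_col = "se_exposure" if role == "exposure" else "se_outcome"
    return pd.DataFrame([{
        "rsid": r[0], "effect_allele": r[1], "other_allele": r[2],
        "eaf": r[3], beta_col: r[4], se_col: r[5],
    } for r in rows])


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = _stats_frame([("rs1", "A", "G", 0.3, -0.1, 0.01)])
        out = _stats_frame([("rs1", "G", "A", 0.7, 0.5, 0.05)], role="outcome")
        mri = mp.harmonize(exp, out)
        assert mri["flipped"].iloc[0]
        assert mri["beta_out"].iloc[0] == pytest.approx(-0.5)

    def test_ambiguous_palindrome_dropped(self):
        exp = _stats_frame([("rs1", "A", "T", 0.5, -0.1, 0.01)])
        out = _stats_frame([("rs1", "A", "T", 0.5, 0.5, 0.05)], role="outcome")
        mri = mp.harmonize(exp, out)
        assert mri.empty
        assert mri.attrs["dropped"]["reason"].iloc[0] == "ambiguous palindrome"

    def test_strand_complement_resolved(self):
        exp = _stats_frame([("rs1", "A", "G", 0.3, -0.1, 0.01)])
        out = _stats_frame([("rs1", "T", "C", 0.3, 0.5, 0.05)], role="outcome")
        mri = mp.harmonize(exp, out)
        assert len(mri) == 1 and not mri["flipped"].iloc[0]
        assert mri["beta_out"].iloc[0] == pytest.approx(0.5)

    def test_toy_panel_matches_hand_alignment(self):
        exp = _stats_frame([
            ("rs1", "A", "G", 0.2, -0.10, 0.01),   # aligned
            ("rs2", "C", "T", 0.3, 0.08, 0.01),    # swapped in outcome
            ("rs3", "G", "A", 0.4, -0.05, 0.01),   # swapped in outcome
            ("rs4", "A", "T", 0.50, -0.07, 0.01),  # ambiguous palindrome
            ("rs5", "C", "G", 0.10, 0.04, 0.01),   # palindrome, clear freq
            ("rs6", "A", "C", 0.6, -0.02, 0.01),   # strand complement
            ("rs7", "T", "G", 0.7, 0.03, 0.01),    # swapped complement
            ("rs8", "A", "G", 0.2, -0.01, 0.01),   # mismatched alleles
            ("rs9", "A", "G", 0.2, -0.02, 0.01),   # aligned
            ("rs10", "C", "T", 0.9, 0.06, 0.01),   # aligned
        ])
        out = _stats_frame([
            ("rs1", "A", "G", 0.2, 0.10, 0.02),
            ("rs2", "T", "C", 0.7, 0.20, 0.02),
            ("rs3", "A", "G", 0.6, 0.30, 0.02),
            ("rs4", "A", "T", 0.5, 0.40, 0.02),
            ("rs5", "C", "G", 0.1, 0.50, 0.02),
            ("rs6", "T", "G", 0.6, 0.60, 0.02),
            ("rs7", "C", "A", 0.3, 0.70, 0.02),
            ("rs8", "A", "C", 0.2, 0.80, 0.02),
            ("rs9", "A", "G", 0.2, 0.90, 0.02),
            ("rs10", "C", "T", 0.9, 1.00, 0.02),
        ], role="outcome")
        mri = mp.harmonize(exp, out).set_index("rsid")
        assert list(mri.index) == ["rs1", "rs2", "rs3", "rs5", "rs6", "rs7",
                                   "rs9", "rs10"]
        np.testing.assert_allclose(
            mri["beta_out"], [0.10, -0.20, -0.30, 0.50, 0.60, -0.70, 0.90, 1.00])
        dropped = set(mp.harmonize(exp, out).attrs["dropped"]["rsid"])
        assert dropped == {"rs4", "rs8"}

    def test_no_shared_rsids_is_error(self):
        exp = _stats_frame([("rs1", "A", "G", 0.2, -0.1, 0.01)])
        out = _stats_frame([("rs2", "A", "G", 0.2, 0.1, 0.01)], role="outcome")
        with pytest.raises(InputError):
            mp.harmonize(exp, out)


class TestWaldRatios:
    def test_simple_ratio(self):
        mri = mp.mr_input_from_arrays([0.25], [0.01], [0.5], [0.1])
        w = mp.wald_ratios(mri)
        assert w["ratio"].iloc[0] == pytest.approx(2.0)
        assert w["se"].iloc[0] == pytest.approx(0.4)

    def test_zero_outcome_effect(self):
        mri = mp.mr_input_from_arrays([0.2], [0.01], [0.0], [0.05])
        w = mp.wald_ratios(mri)
        assert w["ratio"].iloc[0] == 0.0
        assert w["se"].iloc[0] == pytest.approx(0.25)

    def test_zero_exposure_effect_excluded_with_warning(self):
        mri = mp.mr_input_from_arrays([0.0, 0.2], [0.01, 0.01],
                                      [0.1, 0.1], [0.05, 0.05])
        with pytest.warns(UserWarning):
            w = mp.wald_ratios(mri)
        assert len(w) == 1

    def test_first_order_se_close_to_second_order_for_strong_instruments(self):
        # |beta_exp / se_exp| > 10 keeps the two delta expansions within 5%
        mri = mp.mr_input_from_arrays([0.2, 0.3, 0.25], [0.015, 0.02, 0.02],
                                      [0.1, 0.12, 0.11], [0.05, 0.04, 0.06])
        first = mp.wald_ratios(mri)["se"].to_numpy()
        second = mp.wald_ratios(mri, second_order=True)["se"].to_numpy()
        assert np.all(np.abs(second - first) / second < 0.05)


class TestIvw:
    def test_identical_ratios_have_no_heterogeneity(self):
        mri = mp.mr_input_from_arrays([1.0] * 3, [0.01] * 3, [0.3] * 3, [0.1] * 3)
        est = mp.ivw(mri, "random")
        assert est.beta == pytest.approx(0.3)
        assert est.extras["Q"] == pytest.approx(0.0, abs=1e-20)
        assert est.extras["I2"] == 0.0 and est.extras["tau2"] == 0.0

    def test_hand_computed_weighted_mean(self):
        mri = mp.mr_input_from_arrays([1.0, 1.0], [0.01, 0.01],
                                      [0.2, 0.4], [0.1, 0.2])
        est = mp.ivw(mri, "fixed")
        assert est.beta == pytest.approx(0.24)
        assert est.se == pytest.approx(1.0 / np.sqrt(125.0))

    def test_random_equals_fixed_when_tau2_zero(self):
        mri = mp.mr_input_from_arrays([1.0] * 4, [0.01] * 4,
                                      [0.301, 0.299, 0.3, 0.3], [0.1] * 4)
        fixed = mp.ivw(mri, "fixed")
        rand = mp.ivw(mri, "random")
        assert rand.extras["tau2"] == 0.0
        assert rand.beta == pytest.approx(fixed.beta)
        assert rand.se == pytest.approx(fixed.se)

    def test_single_variant_random_falls_back_to_fixed(self):
        mri = mp.mr_input_from_arrays([0.2], [0.01], [0.1], [0.05])
        with pytest.warns(UserWarning, match="single variant"):
            est = mp.ivw(mri, "random")
        assert est.method == "ivw_fixed"


class TestEgger:
    def test_minimum_variant_guard(self):
        mri = mp.mr_input_from_arrays([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(MethodError):
            mp.mr_egger(mri)

    def test_collinear_points_recover_exact_line(self):
        mri = mp.mr_input_from_arrays([0.1, 0.2, 0.3], [0.01] * 3,
                                      [0.05, 0.15, 0.25], [0.05] * 3)
        est = mp.mr_egger(mri)
        assert est.beta == pytest.approx(1.0, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(-0.05, abs=1e-10)

    def test_intercept_zero_constraint_reproduces_fixed_ivw(self):
        """Egger with the intercept forced to zero is exactly the
        weighted-through-origin regression, i.e. a beta_exp^2/se^2-weighted
        estimate identical to IVW on the Wald ratios."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            m = rng.integers(3, 12)
            be = rng.uniform(0.05, 0.4, m) * rng.choice([-1, 1], m)
            bo = rng.normal(0, 0.1, m)
            so = rng.uniform(0.01, 0.1, m)
            mri = mp.mr_input_from_arrays(be, np.full(m, 0.01), bo, so)
            w = 1.0 / so**2
            slope0 = np.sum(w * be * bo) / np.sum(w * be**2)
            fixed = mp.ivw(mri, "fixed")
            assert slope0 == pytest.approx(fixed.beta, rel=1e-10)

    def test_directional_pleiotropy_lands_in_intercept(self):
        rng = np.random.default_rng(23)
        m, truth, pleio = 50, -0.1, 0.02
        be = rng.uniform(0.05, 0.35, m)
        so = np.full(m, 0.01)
        bo = truth * be + pleio + rng.normal(0, 0.01, m)
        mri = mp.mr_input_from_arrays(be, np.full(m, 0.005), bo, so)
        est = mp.mr_egger(mri)
        assert est.extras["intercept"] == pytest.approx(pleio, abs=0.01)
        assert est.beta == pytest.approx(truth, abs=0.05)


class TestWeightedMedian:
    def test_equal_weights_reduce_to_plain_median(self):
        mri = mp.mr_input_from_arrays([1.0] * 3, [0.01] * 3,
                                      [1.0, 2.0, 3.0], [0.5] * 3)
        est = mp.weighted_median(mri, bootstrap_reps=50, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_dominant_weight_returns_its_ratio(self):
        assert _weighted_median(np.array([1.0, 2.0, 3.0]),
                                np.array([0.6, 0.2, 0.2])) == 1.0

    def test_breakdown_resistance_to_forty_percent_invalid(self):
        rng = np.random.default_rng(29)
        truth, wins = -0.1, 0
        reps = 60
        for _ in range(reps):
            m = 30
            be = rng.uniform(0.1, 0.4, m)
            so = np.full(m, 0.02)
            bo = truth * be + rng.normal(0, 0.02, m)
            bad = rng.choice(m, 12, replace=False)
            # large balanced outlier ratios: the median resists, IVW does not
            bo[bad] += rng.uniform(0.2, 0.5, 12) * rng.choice([-1, 1], 12)
            mri = mp.mr_input_from_arrays(be, np.full(m, 0.005), bo, so)
            wm = mp.weighted_median(mri, bootstrap_reps=100, seed=int(rng.integers(2**31)))
            ivw_est = mp.ivw(mri, "fixed")
            wm_ok = wm.ci_low <= truth <= wm.ci_high
            ivw_ok = ivw_est.ci_low <= truth <= ivw_est.ci_high
            wins += int(wm_ok and not ivw_ok)
        assert wins > reps / 2

    def test_all_zero_weights_error(self):
        mri = mp.mr_input_from_arrays([1.0] * 3, [0.01] * 3, [1.0] * 3, [0.5] * 3)
        mri["se_out"] = np.inf
        with pytest.raises(MethodError):
            mp.weighted_median(mri, bootstrap_reps=10, seed=0)


class TestModeEstimate:
    def test_cluster_majority_sets_the_mode(self):
        mri = mp.mr_input_from_arrays([1.0] * 4, [0.001] * 4,
                                      [1.0, 1.0, 1.0, 5.0], [0.3] * 4)
        est = mp.mode_estimate(mri, weighted=False, bootstrap_reps=50, seed=0)
        assert est.beta == pytest.approx(1.0, abs=0.3)

    def test_identical_ratios_return_exactly(self):
        mri = mp.mr_input_from_arrays([1.0] * 3, [0.01] * 3, [0.7] * 3, [0.1] * 3)
        est = mp.mode_estimate(mri, bootstrap_reps=10, seed=0)
        assert est.beta == 0.7 and est.se == 0.0

    def test_fine_grid_density_oracle(self):
        mri = mp.mr_input_from_arrays([1.0] * 5, [0.001] * 5,
                                      [0.9, 1.0, 1.1, 3.0, 3.1], [0.2] * 5)
        est = mp.mode_estimate(mri, bootstrap_reps=10, seed=0, grid_size=20_000)
        # independent coarse evaluation of the same kernel density
        from mrphewas.mr import _mode_bandwidth
        ratios = np.array([0.9, 1.0, 1.1, 3.0, 3.1])
        h = _mode_bandwidth(ratios, 1.0)
        xs = np.linspace(-1, 5, 200_001)
        dens = sum(np.exp(-0.5 * ((xs - r) / h) ** 2) for r in ratios)
        assert est.beta == pytest.approx(xs[np.argmax(dens)], abs=0.01)


class TestPresso:
    def test_too_few_variants_guard(self):
        mri = mp.mr_input_from_arrays([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.02] * 3)
        with pytest.raises(MethodError):
            mp.mr_presso(mri)

    def test_planted_outlier_detected_and_corrected(self):
        rng = np.random.default_rng(31)
        m, truth = 20, -0.1
        be = rng.uniform(0.1, 0.4, m)
        so = np.full(m, 0.01)
        bo = truth * be + rng.normal(0, 0.01, m)
        bo[7] = 10 * truth * be[7]
        mri = mp.mr_input_from_arrays(be, np.full(m, 0.005), bo, so)
        res = mp.mr_presso(mri, n_sim=500, seed=1)
        assert "rs8" in res.outliers
        assert res.global_p < 0.05
        assert abs(res.beta_adjusted.beta - truth) < abs(res.beta_raw.beta - truth)

    def test_adjusted_estimate_gate_requires_both_tests(self):
        rng = np.random.default_rng(37)
        m, truth = 20, -0.1
        be = rng.uniform(0.1, 0.4, m)
        so = np.full(m, 0.01)
        bo = truth * be + rng.normal(0, 0.01, m)
        mri = mp.mr_input_from_arrays(be, np.full(m, 0.005), bo, so)
        res = mp.mr_presso(mri, n_sim=1000, seed=2)
        if res.report_adjusted:
            assert res.global_p < 0.05 and res.distortion_p < 0.05
        else:
            assert (res.beta_adjusted is None or res.global_p >= 0.05
                    or res.distortion_p is None or res.distortion_p >= 0.05)


class TestOneSampleMr:
    def test_identity_first_stage_equals_single_stage_regression(self, panel60):
        cohort = mp.simulate_cohort(panel60, 4000, seed=3)
        cohort = mp.simulate_phenome(
            cohort, [mp.TraitSpec("y", beta_menarche=0.5, noise_sd=1.0)], seed=3)
        # use the exposure itself as the score: stage 1 prediction is exact
        est = mp.one_sample_mr(cohort, cohort.exposure, "y",
                               bootstrap_reps=50, seed=5)
        X = np.column_stack([np.ones(cohort.n), cohort.exposure])
        direct = np.linalg.lstsq(X, cohort.column("y"), rcond=None)[0][1]
        assert est.beta == pytest.approx(direct, abs=1e-8)

    def test_continuous_outcome_recovery(self, panel60):
        cohort = mp.simulate_cohort(panel60, 20_000, seed=7)
        cohort = mp.simulate_phenome(
            cohort, [mp.TraitSpec("y", beta_menarche=0.5, noise_sd=1.0)], seed=7)
        score = mp.compute_grs(cohort.dosages,
                               panel60.set_index("rsid")["beta_exposure"])
        est = mp.one_sample_mr(cohort, score, "y", bootstrap_reps=200, seed=7)
        assert est.ci_low <= 0.5 <= est.ci_high
        assert not est.extras["weak_instrument"]

    def test_constant_score_rejected(self, cohort60):
        c = mp.simulate_phenome(cohort60, [mp.TraitSpec("y")], seed=1)
        with pytest.raises(EstimationError):
            mp.one_sample_mr(c, np.ones(c.n), "y", bootstrap_reps=10, seed=0)


class TestMultivariableMr:
    def test_identical_scores_are_collinear(self, cohort60):
        c = mp.simulate_phenome(cohort60, [mp.TraitSpec("y")], seed=1)
        s = np.arange(c.n, dtype=float)
        with pytest.raises(EstimationError, match="collinear"):
            mp.multivariable_mr(c, {"exposure": s, "adult_bmi": s.copy()}, "y",
                                bootstrap_reps=10, seed=0)

    def test_needs_two_exposures(self, cohort60):
        c = mp.simulate_phenome(cohort60, [mp.TraitSpec("y")], seed=1)
        with pytest.raises(MethodError):
            mp.multivariable_mr(c, {"exposure": np.arange(c.n, dtype=float)},
                                "y", bootstrap_reps=10, seed=0)


class TestEquivariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_outcome_rescaling_scales_estimates(self, c):
        mri = mp.mr_input_from_arrays(
            [0.10, 0.20, 0.30, 0.15, 0.25], [0.01] * 5,
            [0.05, 0.11, 0.14, 0.08, 0.12], [0.02, 0.03, 0.02, 0.025, 0.03])
        scaled = mri.copy()
        scaled["beta_out"] *= c
        scaled["se_out"] *= c
        for fn in (lambda d: mp.ivw(d, "fixed"), lambda d: mp.ivw(d, "random"),
                   mp.mr_egger,
                   lambda d: mp.weighted_median(d, bootstrap_reps=100, seed=3),
                   lambda d: mp.mode_estimate(d, bootstrap_reps=100, seed=3)):
            a, b = fn(mri), fn(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-6, abs=1e-9)
            assert b.se == pytest.approx(c * a.se, rel=0.35, abs=1e-9)


class TestHeterogeneity:
    def test_identical_estimates_no_heterogeneity(self):
        e = mp.MREstimate("ivw_random", 0.2, 0.1, 0.0, 0.4, 0.05, 10)
        Q, df, p, I2 = mp.cohort_heterogeneity([e, dataclasses.replace(e, se=0.3)])
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert I2 == 0.0 and df == 1

    def test_hand_computed_q(self):
        a = mp.MREstimate("ivw_random", 0.0, 0.1, -0.2, 0.2, 1.0, 10)
        b = mp.MREstimate("ivw_random", 0.6, 0.1, 0.4, 0.8, 0.0, 10)
        Q, df, p, I2 = mp.cohort_heterogeneity([a, b])
        assert Q == pytest.approx(18.0)
        from scipy import stats as ss
        assert p == pytest.approx(float(ss.chi2.sf(18.0, 1)))

    def test_single_estimate_rejected(self):
        e = mp.MREstimate("ivw_random", 0.2, 0.1, 0.0, 0.4, 0.05, 10)
        with pytest.raises(InputError):
            mp.cohort_heterogeneity([e])


class TestReportingOrientation:
    def test_per_year_decrease_flips_sign_and_interval(self):
        e = mp.MREstimate("ivw_random", -0.2, 0.05, -0.3, -0.1, 1e-4, 10)
        r = mp.per_year_decrease(e)
        assert r.beta == 0.2
        assert (r.ci_low, r.ci_high) == (0.1, 0.3)
        assert r.pval == e.pval
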