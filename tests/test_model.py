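import numpy as np
import pytest

from bidirmr.harmonize import HarmonizedInstrumentSet
from bidirmr.model import (InsufficientInstrumentsError, MRModel, cochran_q,
                           funnel_data, ivw, leave_one_out, mr_egger,
                           wald_ratio, weighted_median, weighted_mode)


def hset(gamma, Gamma, se_Gamma, se_gamma=None):
    gamma = np.asarray(gamma, float)
    if se_gamma is None:
        se_gamma = np.full_like(gamma, 0.01)
    return HarmonizedInstrumentSet.from_arrays(gamma, se_gamma, Gamma, se_Gamma)


def ratio_set(ratios, weights):
    """Instruments whose Wald ratios and first-order weights are exactly as given."""
    ratios = np.asarray(ratios, float)
    w = np.asarray(weights, float)
    gamma = np.ones_like(ratios)
    se_G = 1.0 / np.sqrt(w)        # w = gamma^2 / se_G^2 with gamma = 1
    return hset(gamma, ratios, se_G)


class TestWaldRatio:
    def test_exact_ratio(self):
        assert wald_ratio(0.1, 0.01, 0.2, 0.05).theta == pytest.approx(2.0)

    def test_first_order_delta_se(self):
        assert wald_ratio(0.1, 0.01, 0.2, 0.05).se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        r = wald_ratio(0.1, 0.01, 0.0, 0.05)
        assert r.theta == 0.0 and r.p_value == pytest.approx(1.0)

    def test_zero_gamma_is_error(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.2, 0.05)

    def test_second_order_adds_gamma_uncertainty(self):
        first = wald_ratio(0.1, 0.02, 0.2, 0.05)
        second = wald_ratio(0.1, 0.02, 0.2, 0.05, second_order=True)
        assert second.se > first.se
        assert second.se == pytest.approx(
            np.sqrt(0.05**2 / 0.01 + 0.04 * 4e-4 / 1e-4))


class TestIVW:
    def test_two_snp_closed_form(self):
        hs = hset([0.1, 0.2], [0.2, 0.4], [0.1, 0.1])
        r = ivw(hs)
        assert r.theta == pytest.approx((0.02 + 0.08) / (0.01 + 0.04), rel=1e-12)
        assert r.q_statistic == pytest.approx(0.0, abs=1e-20)
        # dispersion floor: random-effects SE equals the fixed-effect SE
        assert r.se == pytest.approx(ivw(hs, random_effects=False).se)

    def test_single_instrument_falls_back_to_wald(self):
        hs = hset([0.1], [0.2], [0.05])
        r = ivw(hs)
        w = wald_ratio(0.1, 0.01, 0.2, 0.05)
        assert (r.theta, r.se) == (pytest.approx(w.theta), pytest.approx(w.se))

    def test_null_outcome_effects(self):
        r = ivw(hset([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.1, 0.1, 0.1]))
        assert r.theta == 0.0

    def test_random_effects_never_shrink_se(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = rng.uniform(0.05, 0.3, 6)
            hs = hset(g, 2 * g + rng.normal(0, 0.05, 6), np.full(6, 0.05))
            assert ivw(hs).se >= ivw(hs, random_effects=False).se - 1e-15

    def test_matches_wls_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(42)
        for _ in range(20):
            J = rng.integers(2, 9)
            g = rng.uniform(0.05, 0.5, J)
            G = rng.normal(0.3 * g, 0.05)
            se_G = rng.uniform(0.02, 0.1, J)
            res = sm.WLS(G, g, weights=1.0 / se_G**2).fit()
            assert ivw(hset(g, G, se_G)).theta == pytest.approx(
                res.params[0], abs=1e-10)


class TestEgger:
    def test_collinear_fixture_recovers_line(self, collinear_set):
        r = mr_egger(collinear_set)
        assert r.theta == pytest.approx(2.0, abs=1e-10)
        assert r.egger_intercept == pytest.approx(0.05, abs=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hset([0.1, 0.2], [0.2, 0.4], [0.1, 0.1]))

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0.05, 0.3, 8)
        hs = hset(g, 0.02 + 1.5 * g + rng.normal(0, 0.02, 8), np.full(8, 0.05))
        a = mr_egger(hs)
        g2, G2 = hs.gamma.copy(), hs.Gamma.copy()
        g2[::2] *= -1
        G2[::2] *= -1
        b = mr_egger(hset(g2, G2, hs.se_Gamma))
        assert a.theta == pytest.approx(b.theta, rel=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, rel=1e-12)

    def test_zero_intercept_design_matches_ivw(self):
        # exactly proportional data through the origin: free intercept fits 0
        g = np.array([-0.2, -0.1, 0.1, 0.2])
        hs = hset(g, 2.0 * g, np.full(4, 0.05))
        assert mr_egger(hs).theta == pytest.approx(ivw(hs).theta, abs=1e-10)
        assert mr_egger(hs).egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_inference_uses_t_with_J_minus_2_df(self):
        rng = np.random.default_rng(9)
        g = rng.uniform(0.1, 0.3, 5)
        hs = hset(g, 2 * g + rng.normal(0, 0.08, 5), np.full(5, 0.05))
        from scipy import stats
        r = mr_egger(hs)
        assert r.p_value == pytest.approx(
            2 * stats.t.sf(abs(r.theta) / r.se, 3), rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_interpolates_middle_ratio(self):
        r = weighted_median(ratio_set([1.0, 2.0, 3.0], [1, 1, 1]),
                            n_boot=100, seed=0)
        assert r.theta == pytest.approx(2.0, abs=1e-12)

    def test_unequal_weights_pull_toward_heavy_ratio(self):
        r = weighted_median(ratio_set([1.0, 2.0, 3.0], [10, 1, 1]),
                            n_boot=100, seed=0)
        assert r.theta == pytest.approx(13 / 11, abs=1e-12)  # s-interpolation oracle

    def test_constant_ratios_recover_constant(self):
        hs = hset([0.1, 0.2, 0.4], [0.15, 0.3, 0.6], [0.05, 0.05, 0.05])
        r = weighted_median(hs, n_boot=200, seed=1)
        assert r.theta == pytest.approx(1.5, abs=1e-12)
        assert 0 < r.se < 0.5

    def test_equal_weights_equal_sample_median_for_odd_J(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ratios = np.sort(rng.normal(1.0, 0.5, 7))
            est = MRModel._weighted_median(ratios, np.ones(7))
            assert est == pytest.approx(np.median(ratios), abs=1e-12)

    def test_bootstrap_reproducible_given_seed(self):
        hs = ratio_set([0.8, 1.1, 1.5, 2.0], [1, 2, 3, 1])
        a = weighted_median(hs, n_boot=300, seed=5)
        b = weighted_median(hs, n_boot=300, seed=5)
        assert a.se == b.se

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(ratio_set([1, 2], [1, 1]))


class TestWeightedMode:
    def test_cluster_dominates(self):
        r = weighted_mode(ratio_set([1.0, 2.0, 2.0, 2.05, 3.0], np.ones(5)),
                          n_boot=100, seed=0)
        assert r.theta == pytest.approx(2.0, abs=0.25)

    def test_constant_ratios_exact(self):
        hs = hset([0.1, 0.2, 0.4], [0.15, 0.3, 0.6], [0.05, 0.05, 0.05])
        assert weighted_mode(hs, n_boot=50, seed=0).theta == pytest.approx(1.5)

    def test_dominant_weight_wins(self):
        r = weighted_mode(ratio_set([1.0, 2.0, 3.0, 4.0], [1e6, 1, 1, 1]),
                          n_boot=50, seed=0)
        assert r.theta == pytest.approx(1.0, abs=0.05)


class TestHeterogeneity:
    def test_identical_ratios_no_heterogeneity(self):
        q, df, p, i2 = cochran_q(hset([0.1, 0.2], [0.15, 0.3], [0.05, 0.05]))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert i2 == 0.0 and df == 1

    def test_two_ratio_hand_computation(self):
        # ratios 1 and 3 with unit ratio variance: Q = 2, I^2 = 0.5
        hs = ratio_set([1.0, 3.0], [1.0, 1.0])
        q, df, p, i2 = cochran_q(hs)
        assert q == pytest.approx(2.0, rel=1e-12)
        assert df == 1
        assert i2 == pytest.approx(0.5, rel=1e-12)

    def test_i2_clipped_at_zero(self):
        q, df, p, i2 = cochran_q(ratio_set([1.0, 1.01, 0.99], [1, 1, 1]))
        assert q < df and i2 == 0.0

    def test_matches_ivw_attached_q(self):
        hs = ratio_set([0.5, 1.5, 2.5], [2.0, 1.0, 0.5])
        q, df, p, i2 = cochran_q(hs)
        r = ivw(hs)
        assert r.q_statistic == pytest.approx(q, rel=1e-12)
        assert r.i_squared == pytest.approx(i2, rel=1e-12)


class TestLeaveOneOut:
    def test_constant_set_gives_identical_estimates(self, constant_set):
        full = ivw(constant_set)
        loo, same_side = leave_one_out(constant_set)
        assert len(loo) == len(constant_set)
        for _, est in loo:
            assert est.theta == pytest.approx(full.theta, rel=1e-12)
        assert same_side is True

    def test_outlier_drop_moves_estimate_most(self, outlier_set):
        hs, outlier_id = outlier_set
        full = ivw(hs)
        loo, _ = leave_one_out(hs)
        deltas = {vid: abs(est.theta - full.theta) for vid, est in loo}
        assert max(deltas, key=deltas.get) == outlier_id

    def test_cardinality(self):
        hs = ratio_set([1.0, 1.2, 0.9, 1.1, 1.05], np.ones(5))
        loo, _ = leave_one_out(hs)
        assert len(loo) == 5


class TestFunnel:
    def test_row_count_preserved(self):
        hs = ratio_set([1.0, 1.5, 2.0], [1, 1, 1])
        df, score = funnel_data(hs)
        assert len(df) == 3

    def test_symmetric_set_scores_near_zero(self):
        # ratios placed in exact +/- delta pairs around the IVW estimate
        deltas = np.array([0.1, 0.2, 0.3])
        ratios = np.concatenate([2.0 + deltas, 2.0 - deltas])
        df, score = funnel_data(ratio_set(ratios, np.ones(6)))
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_single_snp_symmetry_undefined(self):
        df, score = funnel_data(hset([0.1], [0.2], [0.05]))
        assert len(df) == 1 and score is None


class TestSummaryOutput:
    def test_summary_contains_key_quantities(self, collinear_set):
        r = mr_egger(collinear_set)
        text = r.summary()
        assert "egger" in text and "OR" in text and "intercept" in text

    def test_or_is_exp_theta(self):
        r = ivw(ratio_set([1.0, 1.1, 0.9], np.ones(3)))
        or_, lo, hi = r.odds_ratio()
        assert or_ == pytest.approx(np.exp(r.theta), rel=1e-15)
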