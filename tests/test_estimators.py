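import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrlink as M
from mrlink.estimators import (EstimationError, InsufficientInstrumentsError,
                               _mode_point, _weighted_median, wald_ratios)


def _wls_origin_oracle(bx, by, w):
    """Generic weighted least squares through the origin via lstsq."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq((sw * bx)[:, None], sw * by, rcond=None)
    return float(coef[0])


def _wls_intercept_oracle(bx, by, w):
    sw = np.sqrt(w)
    X = np.column_stack([sw, sw * bx])
    coef, *_ = np.linalg.lstsq(X, sw * by, rcond=None)
    return float(coef[0]), float(coef[1])


def _random_set(seed, k=10, beta=0.3):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.003, 0.01, k)
    sy = rng.uniform(0.005, 0.02, k)
    by = rng.normal(beta * bx, sy)
    return M.HarmonizedInstrumentSet.from_arrays(bx, sx, by, sy)


class TestWaldRatios:
    def test_formula(self):
        h = M.HarmonizedInstrumentSet.from_arrays(
            [0.2, 0.2, 0.2], [0.01] * 3, [0.1, 0.0, 0.05], [0.02] * 3)
        wr = wald_ratios(h)
        assert wr["ratio"].tolist() == pytest.approx([0.5, 0.0, 0.25])
        assert wr["se"].tolist() == pytest.approx([0.1, 0.1, 0.1])

    def test_zero_exposure_beta_excluded(self):
        h = M.HarmonizedInstrumentSet.from_arrays(
            [0.2, 0.0], [0.01] * 2, [0.1, 0.1], [0.02] * 2)
        wr = wald_ratios(h)
        assert len(wr) == 1 and wr.attrs["n_excluded"] == 1


class TestIvwMre:
    def test_homogeneous_ratios(self, toy_proportional_set):
        est = M.ivw_mre(toy_proportional_set)
        assert est.beta == pytest.approx(0.2, abs=1e-15)
        assert est.extras["Q"] == pytest.approx(0.0, abs=1e-20)
        assert est.se == pytest.approx(est.extras["se_fixed"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_oracle(self, seed):
        h = _random_set(seed)
        est = M.ivw_mre(h)
        assert est.beta == pytest.approx(
            _wls_origin_oracle(h.bx, h.by, 1 / h.sy**2), rel=1e-10)

    def test_permutation_invariance(self):
        h = _random_set(3)
        perm = np.random.default_rng(0).permutation(h.k)
        est1, est2 = M.ivw_mre(h), M.ivw_mre(h.subset(perm))
        assert est1.beta == pytest.approx(est2.beta, abs=1e-15)
        assert est1.se == pytest.approx(est2.se, abs=1e-15)

    def test_heterogeneity_never_shrinks_se(self):
        h = _random_set(1)
        est = M.ivw_mre(h)
        assert est.se >= est.extras["se_fixed"] - 1e-15

    def test_insufficient_instruments(self):
        h = M.HarmonizedInstrumentSet.from_arrays([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            M.ivw_mre(h)


class TestMrEgger:
    def test_exact_linear_recovery(self):
        bx = np.linspace(0.05, 0.3, 8)
        by = 0.03 + 0.4 * bx  # noise-free with intercept
        h = M.HarmonizedInstrumentSet.from_arrays(bx, [0.005] * 8, by, [0.01] * 8)
        est = M.mr_egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.03, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_oracle(self, seed):
        h = _random_set(seed)
        bx, by = h.bx.copy(), h.by.copy()
        flip = bx < 0
        bx[flip] *= -1
        by[flip] *= -1
        a, b = _wls_intercept_oracle(bx, by, 1 / h.sy**2)
        est = M.mr_egger(h)
        assert est.beta == pytest.approx(b, rel=1e-8)
        assert est.extras["intercept"] == pytest.approx(a, rel=1e-8, abs=1e-12)

    def test_orientation_invariance(self):
        h = _random_set(2)
        df = h.df.copy()
        df.loc[0, "beta_exp"] *= -1
        df.loc[0, "beta_out"] *= -1
        h2 = M.HarmonizedInstrumentSet("x", "y", "continuous", df)
        assert M.mr_egger(h).beta == pytest.approx(M.mr_egger(h2).beta, abs=1e-12)

    def test_recovers_effect_under_directional_pleiotropy(self):
        ivw_est, egger_est = [], []
        for r in range(60):
            s = M.scenario_preset("directional_pleiotropy", seed=7000 + r)
            h, _ = M.simulate_instrument_set(s)
            ivw_est.append(M.ivw_mre(h).beta)
            egger_est.append(M.mr_egger(h).beta)
        assert abs(np.mean(egger_est) - 0.2) < 0.03
        assert abs(np.mean(ivw_est) - 0.2) > 0.05


class TestWeightedMedian:
    def test_simple_median(self):
        assert _weighted_median(np.array([0.1, 0.2, 0.9]), np.ones(3)) == \
            pytest.approx(0.2)

    def test_breakdown_property(self, estimator_config):
        # 60% of weight at ratio 0.2, 40% at 0.8
        bx = np.full(10, 0.2)
        by = np.where(np.arange(10) < 6, 0.2, 0.8) * bx
        h = M.HarmonizedInstrumentSet.from_arrays(bx, [0.005] * 10, by, [0.01] * 10)
        est = M.weighted_median(h, estimator_config)
        assert est.beta == pytest.approx(0.2, abs=1e-9)

    def test_fixed_seed_bit_identical(self):
        h = _random_set(5)
        cfg = M.EstimatorConfig(rng_seed=11, bootstrap_reps=200)
        assert M.weighted_median(h, cfg).se == M.weighted_median(h, cfg).se

    def test_invalid_minority_simulation(self):
        # 60% valid instruments at ratio 0.2, 40% invalid at 0.8, equal
        # precision (ratio SE 0.02): the median tracks the valid cluster
        ests = []
        for r in range(100):
            rng = np.random.default_rng(8000 + r)
            k = 10
            truth = np.where(np.arange(k) < 6, 0.2, 0.8)
            bx = np.full(k, 0.2)
            sy = np.full(k, 0.004)
            by = rng.normal(truth * bx, sy)
            ests.append(_weighted_median(by / bx, bx**2 / sy**2))
        assert abs(np.mean(ests) - 0.2) < 0.03


class TestWeightedMode:
    def test_plurality_cluster(self):
        bx = np.full(10, 0.2)
        by = np.where(np.arange(10) < 7, 0.2, 0.9) * bx
        by += np.random.default_rng(0).normal(0, 0.001, 10)
        h = M.HarmonizedInstrumentSet.from_arrays(bx, [0.005] * 10, by, [0.01] * 10)
        cfg = M.EstimatorConfig(rng_seed=1, bootstrap_reps=100)
        assert M.weighted_mode(h, cfg).beta == pytest.approx(0.2, abs=0.05)

    def test_degenerate_density_returns_common_ratio(self):
        bx = np.linspace(0.1, 0.3, 5)
        h = M.HarmonizedInstrumentSet.from_arrays(bx, [0.005] * 5,
                                                  0.7 * bx, [0.01] * 5)
        cfg = M.EstimatorConfig(rng_seed=1, bootstrap_reps=100)
        assert M.weighted_mode(h, cfg).beta == pytest.approx(0.7, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.25, 0.5, 1.0, 2.0])
    def test_mode_stays_in_ratio_hull(self, phi):
        h = _random_set(9)
        ratios = h.by / h.bx
        m = _mode_point(h.bx, h.by, h.sy, phi=phi)
        assert ratios.min() - 1e-12 <= m <= ratios.max() + 1e-12


class TestMrRaps:
    def test_parameter_recovery_no_pleiotropy(self):
        ests, tau2s = [], []
        cfg = M.EstimatorConfig(rng_seed=1)
        for r in range(40):
            s = M.scenario_preset("valid_instruments", seed=9000 + r)
            h, _ = M.simulate_instrument_set(s)
            est = M.mr_raps(h, cfg)
            ests.append(est.beta)
            tau2s.append(est.extras["tau2"])
        assert abs(np.mean(ests) - 0.2) < 0.01
        assert np.median(tau2s) < 1e-5

    def test_less_biased_than_ivw_with_weak_instruments(self):
        cfg = M.EstimatorConfig(rng_seed=1)
        ivw_b, raps_b = [], []
        for r in range(60):
            s = M.scenario_preset("weak_instruments", seed=9500 + r)
            h, _ = M.simulate_instrument_set(s)
            ivw_b.append(M.ivw_mre(h).beta - 0.2)
            raps_b.append(M.mr_raps(h, cfg).beta - 0.2)
        assert abs(np.mean(raps_b)) < abs(np.mean(ivw_b))

    def test_agrees_with_ivw_in_benign_limit(self, toy_proportional_set):
        cfg = M.EstimatorConfig(rng_seed=1)
        est = M.mr_raps(toy_proportional_set, cfg)
        assert est.beta == pytest.approx(0.2, abs=1e-4)


class TestContaminationMixture:
    def test_uncontaminated_limit(self):
        bx = np.linspace(0.1, 0.3, 10)
        h = M.HarmonizedInstrumentSet.from_arrays(
            bx, [0.005] * 10, 0.3 * bx, [0.002] * 10)
        cfg = M.EstimatorConfig(rng_seed=1)
        est = M.contamination_mixture(h, cfg)
        assert est.beta == pytest.approx(0.3, abs=2 * est.extras["grid_step"])
        assert est.ci_low <= 0.3 <= est.ci_high

    def test_grid_refinement_stability(self):
        h = _random_set(4)
        e1 = M.contamination_mixture(h, M.EstimatorConfig(rng_seed=1,
                                                          conmix_grid_points=1000))
        e2 = M.contamination_mixture(h, M.EstimatorConfig(rng_seed=1,
                                                          conmix_grid_points=2000))
        assert abs(e1.beta - e2.beta) < e1.extras["grid_step"]

    def test_coverage_with_contamination(self):
        covered = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(12000 + r)
            k = 20
            bx = rng.uniform(0.05, 0.2, k)
            sy = np.full(k, 0.005)
            by = 0.2 * bx
            invalid = rng.random(k) < 0.3
            by = by + np.where(invalid, rng.normal(0, 0.05, k), 0.0)
            by = rng.normal(by, sy)
            h = M.HarmonizedInstrumentSet.from_arrays(bx, [0.003] * k, by, sy)
            est = M.contamination_mixture(h, M.EstimatorConfig(rng_seed=1))
            covered += est.ci_low <= 0.2 <= est.ci_high
        assert covered / reps >= 0.90


class TestDebiasedIvw:
    def test_reduces_to_ivw_without_exposure_error(self):
        h = _random_set(6)
        df = h.df.copy()
        df["se_exp"] = 0.0
        h0 = M.HarmonizedInstrumentSet("x", "y", "continuous", df)
        assert M.debiased_ivw(h0).beta == pytest.approx(M.ivw_mre(h0).beta,
                                                        abs=1e-14)

    def test_ratio_of_sums_oracle(self):
        h = _random_set(7)
        bx, sx, by, sy = h.bx, h.sx, h.by, h.sy
        oracle = np.sum(bx * by / sy**2) / np.sum((bx**2 - sx**2) / sy**2)
        assert M.debiased_ivw(h).beta == pytest.approx(oracle, rel=1e-12)

    def test_less_biased_than_ivw_with_weak_instruments(self):
        ivw_b, divw_b = [], []
        for r in range(60):
            s = M.scenario_preset("weak_instruments", seed=13000 + r)
            h, _ = M.simulate_instrument_set(s)
            ivw_b.append(M.ivw_mre(h).beta - 0.2)
            divw_b.append(M.debiased_ivw(h).beta - 0.2)
        assert abs(np.mean(divw_b)) < abs(np.mean(ivw_b))

    def test_degenerate_instruments_error(self):
        h = M.HarmonizedInstrumentSet.from_arrays(
            [0.001, 0.001], [0.1, 0.1], [0.01, 0.01], [0.01, 0.01])
        with pytest.raises(EstimationError, match="weak"):
            M.debiased_ivw(h)


class TestCrossMethodProperties:
    def test_scale_equivariance(self, estimator_config):
        h = _random_set(8)
        c = 3.7
        df = h.df.copy()
        df["beta_out"] *= c
        df["se_out"] *= c
        hc = M.HarmonizedInstrumentSet("x", "y", "continuous", df)
        for name, fn in [
            ("ivw", lambda s: M.ivw_mre(s)),
            ("egger", lambda s: M.mr_egger(s)),
            ("median", lambda s: M.weighted_median(s, estimator_config)),
            ("raps", lambda s: M.mr_raps(s, estimator_config)),
            ("divw", lambda s: M.debiased_ivw(s)),
        ]:
            e1, e2 = fn(h), fn(hc)
            assert e2.beta == pytest.approx(c * e1.beta, rel=1e-6), name
            # RAPS SEs come from finite-difference Hessians, exact only to
            # numerical-differentiation precision
            se_rel = 1e-2 if name == "raps" else 1e-5
            assert e2.se == pytest.approx(c * e1.se, rel=se_rel), name

    def test_direction_concordance_on_benign_data(self, estimator_config):
        agree = 0
        reps = 25
        for r in range(reps):
            s = M.scenario_preset("valid_instruments", seed=14000 + r)
            h, _ = M.simulate_instrument_set(s)
            ests = M.all_estimates(h, estimator_config)
            signs = {np.sign(e.beta) for e in ests.values()}
            agree += signs == {1.0}
        assert agree == reps

    def test_binary_outcome_reports_odds_ratio(self, toy_proportional_set):
        df = toy_proportional_set.df
        h = M.HarmonizedInstrumentSet("x", "y", "binary", df)
        est = M.ivw_mre(h)
        assert est.or_ == pytest.approx(np.exp(est.beta), rel=1e-15)
        assert est.or_ci_low == pytest.approx(np.exp(est.ci_low), rel=1e-15)

    @given(st.integers(0, 10**6))
    @settings(max_examples=15)
    def test_weighted_median_is_weighted_quantile(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=7)
        w = rng.uniform(0.1, 1.0, size=7)
        m = _weighted_median(v, w)
        assert v.min() <= m <= v.max()
        # each side carries at most half the weight, up to half the largest
        # single weight (the interpolated definition splits one observation)
        slack = 0.5 * w.max() / w.sum()
        assert w[v < m].sum() / w.sum() <= 0.5 + slack + 1e-9
        assert w[v > m].sum() / w.sum() <= 0.5 + slack + 1e-9
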