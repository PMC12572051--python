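import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shockpanel import (
    EstimationSample,
    GeneratorConfig,
    LearnerSpec,
    TimingSpec,
    aipw_summands,
    build_sample,
    ddml_ate,
    generate_panel,
    ipw_ate,
    naive_difference,
    oracle_ate,
    subgroup_ate,
)
from shockpanel.aipw import _median_aggregate


def brute_force_aipw(y, t, pi, g1, g0):
    """Independent direct summation of the estimator, term by term."""
    total = 0.0
    for yi, ti, pii, g1i, g0i in zip(y, t, pi, g1, g0):
        treated = ti * yi / pii - (ti - pii) / pii * g1i
        control = (1 - ti) * yi / (1 - pii) + (ti - pii) / (1 - pii) * g0i
        total += treated - control
    return total / len(y)


def _random_inputs(rng, n):
    y = (rng.uniform(size=n) < 0.5).astype(float)
    t = (rng.uniform(size=n) < 0.4).astype(float)
    if t.sum() == 0:
        t[0] = 1.0
    if t.sum() == n:
        t[0] = 0.0
    pi = rng.uniform(0.05, 0.95, size=n)
    g1 = rng.uniform(size=n)
    g0 = rng.uniform(size=n)
    return y, t, pi, g1, g0


class TestSummands:
    def test_hand_example(self):
        # (T,Y) = (1,1),(0,0), pi = 0.5, g1 = 1, g0 = 0 -> psi = (1,1)
        psi = aipw_summands([1, 0], [1, 0], [0.5, 0.5], [1, 1], [0, 0])
        np.testing.assert_allclose(psi, [1.0, 1.0])
        assert psi.mean() == 1.0

    def test_brute_force_oracle_100_toys(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(2, 31))
            y, t, pi, g1, g0 = _random_inputs(rng, n)
            fast = aipw_summands(y, t, pi, g1, g0).mean()
            slow = brute_force_aipw(y, t, pi, g1, g0)
            assert abs(fast - slow) < 1e-12

    def test_zero_residuals_reduce_to_g_computation(self):
        rng = np.random.default_rng(5)
        n = 40
        t = (rng.uniform(size=n) < 0.5).astype(float)
        g1 = rng.uniform(size=n)
        g0 = rng.uniform(size=n)
        y = np.where(t == 1, g1, g0)  # outcome model is exact
        pi = rng.uniform(0.1, 0.9, size=n)
        tau = aipw_summands(y, t, pi, g1, g0).mean()
        assert tau == pytest.approx(float(np.mean(g1 - g0)), abs=1e-12)

    def test_g_zero_reduces_to_ipw(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            y, t, pi, _, _ = _random_inputs(rng, n)
            zeros = np.zeros(n)
            assert aipw_summands(y, t, pi, zeros, zeros).mean() == pytest.approx(
                ipw_ate(y, t, pi), abs=1e-12
            )

    def test_rewritten_form_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            y, t, pi, g1, g0 = _random_inputs(rng, n)
            rewritten = np.mean(
                t * (y - g1) / pi - (1 - t) * (y - g0) / (1 - pi) + g1 - g0
            )
            assert abs(aipw_summands(y, t, pi, g1, g0).mean() - rewritten) < 1e-12

    def test_degenerate_propensity_rejected(self):
        with pytest.raises(ValueError):
            aipw_summands([1.0], [1.0], [1.0], [0.5], [0.5])
        with pytest.raises(ValueError):
            ipw_ate([1.0], [1.0], [0.0])

    @given(st.integers(2, 60), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_summand_mean_finite(self, n, seed):
        rng = np.random.default_rng(seed)
        y, t, pi, g1, g0 = _random_inputs(rng, n)
        psi = aipw_summands(y, t, pi, g1, g0)
        assert np.isfinite(psi).all()


class TestIpw:
    def test_hand_arithmetic(self):
        assert ipw_ate([1, 1], [1, 0], [0.5, 0.5]) == pytest.approx(0.0)

    def test_all_zero_outcomes(self):
        assert ipw_ate([0, 0, 0], [1, 0, 1], [0.4, 0.4, 0.4]) == 0.0


class TestMedianAggregation:
    def test_median_point_estimate(self):
        taus = np.array([0.01, 0.03, 0.02])
        tau, _ = _median_aggregate(taus, np.full(3, 1e-6))
        assert tau == pytest.approx(0.02)

    def test_odd_R_median_attained(self):
        taus = np.array([0.05, -0.01, 0.02, 0.04, 0.00])
        tau, _ = _median_aggregate(taus, np.full(5, 1e-6))
        assert tau in taus

    def test_se_accounts_for_resample_spread(self):
        taus = np.array([0.0, 0.1, 0.2])
        _, se_tight = _median_aggregate(np.full(3, 0.1), np.full(3, 1e-8))
        _, se_wide = _median_aggregate(taus, np.full(3, 1e-8))
        assert se_wide > se_tight


class TestDdmlAte:
    def test_ci_contains_estimate_and_shape(self, default_panel, fast_lasso):
        _, panel, _ = default_panel
        sample = build_sample(panel, TimingSpec("smoke", "physical", 2004, 0))
        est = ddml_ate(sample, fast_lasso, K=3, R=3, seed=0)
        assert est.ci_low <= est.estimate <= est.ci_high
        assert est.R == 3 and est.K == 3
        assert len(est.estimates_r) == 3
        assert est.summands.shape == (sample.n, 3)
        assert est.estimate == pytest.approx(float(np.median(est.estimates_r)))

    def test_deterministic(self, default_panel, fast_lasso):
        _, panel, _ = default_panel
        sample = build_sample(panel, TimingSpec("smoke", "physical", 2004, 0))
        e1 = ddml_ate(sample, fast_lasso, K=3, R=2, seed=5, keep_summands=False)
        e2 = ddml_ate(sample, fast_lasso, K=3, R=2, seed=5, keep_summands=False)
        assert e1.estimate == e2.estimate and e1.se == e2.se

    def test_no_treated_rejected(self, fast_lasso):
        rng = np.random.default_rng(0)
        sample = EstimationSample(
            ids=np.arange(50),
            y=(rng.uniform(size=50) < 0.5).astype(float),
            t=np.zeros(50, int),
            X=pd.DataFrame({"x": rng.normal(size=50)}),
            meta={},
        )
        with pytest.raises(ValueError):
            ddml_ate(sample, fast_lasso, K=3, R=1, seed=0)

    def test_recovery_confounded_effect(self, effect_panel, fast_lasso):
        _, panel, truth = effect_panel
        tru = oracle_ate(truth, "smoke", "physical", 0)
        sample = build_sample(panel, TimingSpec("smoke", "physical", 2004, 0))
        est = ddml_ate(sample, fast_lasso, K=5, R=3, seed=2, keep_summands=False)
        assert abs(est.estimate - tru) < 3 * est.se

    def test_randomized_matches_naive(self, fast_lasso):
        # no confounding: adjusted and unadjusted estimates agree within CI
        cfg = GeneratorConfig(
            n_individuals=8000,
            confounding_weights={},
            effect_profile={("smoke", "physical", 0): 0.05},
            seed=13,
        )
        panel, _ = generate_panel(cfg, seed=13)
        sample = build_sample(panel, TimingSpec("smoke", "physical", 2004, 0))
        naive = naive_difference(sample)
        est = ddml_ate(sample, fast_lasso, K=5, R=3, seed=3, keep_summands=False)
        assert abs(est.estimate - naive.estimate) < 1.645 * np.hypot(est.se, naive.se)


class TestSubgroup:
    def _estimate(self, default_panel, fast_lasso):
        _, panel, _ = default_panel
        sample = build_sample(panel, TimingSpec("smoke", "physical", 2004, 0))
        return sample, ddml_ate(sample, fast_lasso, K=3, R=3, seed=1)

    def test_full_mask_equals_full_ate(self, default_panel, fast_lasso):
        sample, est = self._estimate(default_panel, fast_lasso)
        sub = subgroup_ate(est, np.ones(sample.n, bool))
        assert sub.estimate == pytest.approx(est.estimate)
        assert sub.se == pytest.approx(est.se)

    def test_complementary_masks_decompose(self, default_panel, fast_lasso):
        sample, est = self._estimate(default_panel, fast_lasso)
        mask = sample.X["female"].to_numpy() == 1
        sub1 = subgroup_ate(est, mask)
        sub0 = subgroup_ate(est, ~mask)
        n1, n0 = mask.sum(), (~mask).sum()
        for r in range(est.R):
            weighted = (n1 * sub1.estimates_r[r] + n0 * sub0.estimates_r[r]) / (n1 + n0)
            assert weighted == pytest.approx(est.estimates_r[r], abs=1e-12)

    def test_empty_mask_rejected(self, default_panel, fast_lasso):
        sample, est = self._estimate(default_panel, fast_lasso)
        with pytest.raises(ValueError):
            subgroup_ate(est, np.zeros(sample.n, bool))

    def test_gender_specific_effect_recovery(self, fast_lasso):
        profile = {("smoke", "physical", 0): 0.05}
        cfg = GeneratorConfig(n_individuals=12_000, effect_profile=profile, seed=21)
        # apply the effect to women only by zeroing it for men post hoc is not
        # possible through the config; instead check strata agree under a
        # homogeneous effect and differ in precision only
        panel, truth = generate_panel(cfg, seed=21)
        sample = build_sample(panel, TimingSpec("smoke", "physical", 2004, 0))
        est = ddml_ate(sample, fast_lasso, K=5, R=3, seed=4)
        fem = sample.X["female"].to_numpy() == 1
        sub_f = subgroup_ate(est, fem)
        sub_m = subgroup_ate(est, ~fem)
        # homogeneous truth: the two strata CIs overlap
        assert sub_f.ci_low <= sub_m.ci_high and sub_m.ci_low <= sub_f.ci_high


class TestNaive:
    def test_hand_arithmetic(self):
        sample = EstimationSample(
            ids=np.arange(5),
            y=np.array([1.0, 1.0, 0.0, 0.0, 0.0]),
            t=np.array([1, 1, 1, 0, 0]),
            X=pd.DataFrame({"x": np.zeros(5)}),
            meta={},
        )
        est = naive_difference(sample)
        assert est.estimate == pytest.approx(2.0 / 3.0)

    def test_identical_arms_zero(self):
        sample = EstimationSample(
            ids=np.arange(6),
            y=np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0]),
            t=np.array([1, 1, 1, 0, 0, 0]),
            X=pd.DataFrame({"x": np.zeros(6)}),
            meta={},
        )
        assert naive_difference(sample).estimate == pytest.approx(0.0)

    def test_one_arm_rejected(self):
        sample = EstimationSample(
            ids=np.arange(3),
            y=np.ones(3),
            t=np.ones(3, int),
            X=pd.DataFrame({"x": np.zeros(3)}),
            meta={},
        )
        with pytest.raises(ValueError):
            naive_difference(sample)
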