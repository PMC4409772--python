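"""Outcome models: closed-form checks, brute-force oracles, symmetry
properties, and the sample-size formula."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from copdce.models import (
    OutcomeEstimate,
    SampleSizeSpec,
    fit_binary_model,
    fit_linear_model,
    fit_ordinal_model,
    fit_rate_model,
    fit_time_to_event,
    sample_size_nb,
)


class TestRateModel:
    def test_identical_arms_rr_one(self):
        counts = np.array([0, 1, 2, 3, 1] * 2)
        arm = ["BFC"] * 5 + ["FSC"] * 5
        est = fit_rate_model(counts, arm)
        assert est.estimate == pytest.approx(1.0, abs=1e-6)
        assert est.arm_summary["adjusted_rate_bfc"] == pytest.approx(counts.mean())

    def test_crude_rr_is_ratio_of_means(self):
        # arm A: 20 events over 10 person-years; arm B: 10 over 10
        counts = np.r_[np.full(10, 2), np.full(10, 1)]
        arm = ["BFC"] * 10 + ["FSC"] * 10
        est = fit_rate_model(counts, arm, person_time=np.ones(20))
        assert est.estimate == pytest.approx(2.0, rel=1e-5)
        assert est.arm_summary["adjusted_rate_bfc"] == pytest.approx(2.0, rel=1e-5)
        assert est.arm_summary["adjusted_rate_fsc"] == pytest.approx(1.0, rel=1e-5)

    def test_offset_scales_rates(self):
        counts = np.r_[np.full(10, 2), np.full(10, 1)]
        arm = ["BFC"] * 10 + ["FSC"] * 10
        pt = np.r_[np.full(10, 2.0), np.full(10, 1.0)]  # A rate 1.0, B rate 1.0
        est = fit_rate_model(counts, arm, person_time=pt)
        assert est.estimate == pytest.approx(1.0, rel=1e-5)

    def test_dispersion_zero_reproduces_poisson(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, 200)
        arm = rng.random(200) < 0.5
        a = fit_rate_model(counts, arm, alpha=0)
        b = fit_rate_model(counts, arm, alpha=1e-8)
        assert np.log(a.estimate) == pytest.approx(np.log(b.estimate), abs=1e-6)

    def test_label_swap_inverts_rr(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.9, 300)
        arm = np.where(rng.random(300) < 0.4, "BFC", "FSC")
        swapped = np.where(arm == "BFC", "FSC", "BFC")
        a = fit_rate_model(counts, arm)
        b = fit_rate_model(counts, swapped)
        assert a.estimate == pytest.approx(1 / b.estimate, rel=1e-4)

    def test_all_zero_arm_flagged(self):
        counts = np.r_[np.zeros(10), np.full(10, 1)]
        arm = ["BFC"] * 10 + ["FSC"] * 10
        est = fit_rate_model(counts, arm)
        assert est.metadata["one_arm_all_zero"]

    def test_nb_recovers_dispersion(self):
        rng = np.random.default_rng(2)
        n = 4000
        frailty = rng.gamma(1 / 1.2, 1.2, n)
        counts = rng.poisson(0.9 * frailty)
        arm = rng.random(n) < 0.5
        est = fit_rate_model(counts, arm)
        assert est.metadata["alpha"] == pytest.approx(1.2, abs=0.25)


class TestTimeToEvent:
    def test_identical_arms_hr_one(self):
        times = np.r_[1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        flags = np.ones(10, bool)
        est, curves = fit_time_to_event(times, flags, ["BFC"] * 5 + ["FSC"] * 5)
        assert est.estimate == pytest.approx(1.0, abs=1e-6)
        assert set(curves) == {"BFC", "FSC"}

    def test_four_subject_partial_likelihood_oracle(self):
        # times {1,2,3,4}, all events, arms alternate; the brute-force MLE
        # maximizes the Cox partial likelihood directly
        times = np.array([1.0, 2.0, 3.0, 4.0])
        arms = np.array([0.0, 1.0, 0.0, 1.0])

        def neg_log_pl(beta):
            ll = 0.0
            for i in range(4):
                risk = np.arange(4) >= i
                ll += beta * arms[i] - np.log(np.exp(beta * arms[risk]).sum())
            return -ll

        oracle = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded").x
        est, _ = fit_time_to_event(times, np.ones(4, bool),
                                   np.where(arms == 1, "BFC", "FSC"))
        assert np.log(est.estimate) == pytest.approx(oracle, abs=1e-4)

    def test_large_sample_hazard_ratio_recovery(self):
        rng = np.random.default_rng(3)
        n = 5000
        t0 = rng.exponential(1.0, n)
        t1 = rng.exponential(0.5, n)  # true HR 2
        times = np.r_[t1, t0]
        flags = np.ones(2 * n, bool)
        est, _ = fit_time_to_event(times, flags, ["BFC"] * n + ["FSC"] * n)
        assert 1.9 <= est.estimate <= 2.1

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            fit_time_to_event([1.0, 2.0], [False, False], ["BFC", "FSC"])


class TestBinaryOrdinalLinear:
    def test_odds_ratio_cross_product(self):
        flags = np.r_[np.ones(30), np.zeros(70), np.ones(15), np.zeros(85)]
        arm = ["BFC"] * 100 + ["FSC"] * 100
        est = fit_binary_model(flags, arm)
        assert est.estimate == pytest.approx((30 * 85) / (70 * 15), rel=1e-5)

    def test_identical_arms_null_effects(self):
        flags = np.r_[np.ones(20), np.zeros(30)]
        values = np.r_[np.linspace(0, 1, 25), np.linspace(0, 1, 25)]
        arm = (["BFC"] * 10 + ["FSC"] * 10 + ["BFC"] * 15 + ["FSC"] * 15)
        rng = np.random.default_rng(0)
        order = rng.permutation(50)
        est_or = fit_binary_model(flags, np.array(arm))
        assert est_or.p_value > 0.9
        est_lin = fit_linear_model(np.r_[np.ones(25), np.ones(25)],
                                   ["BFC"] * 25 + ["FSC"] * 25)
        assert est_lin.estimate == pytest.approx(0.0, abs=1e-10)

    def test_ordinal_degenerate_flagged(self):
        est = fit_ordinal_model(["1"] * 20, ["BFC"] * 10 + ["FSC"] * 10)
        assert not est.converged and est.metadata["degenerate"]

    def test_ordinal_recovers_shift(self):
        rng = np.random.default_rng(4)
        n = 2000
        latent = rng.logistic(size=2 * n) + np.r_[np.full(n, 0.7), np.zeros(n)]
        cats = np.digitize(latent, [-1, 0.5, 2]).astype(str)
        est = fit_ordinal_model(cats, ["BFC"] * n + ["FSC"] * n)
        assert est.estimate == pytest.approx(np.exp(0.7), rel=0.2)

    def test_linear_mean_difference(self):
        vals = np.r_[np.full(50, 2.0), np.full(50, 1.5)]
        est = fit_linear_model(vals, ["BFC"] * 50 + ["FSC"] * 50)
        assert est.estimate == pytest.approx(0.5)
        assert est.measure == "mean_difference"


class TestSampleSize:
    def test_study_power_calculation(self):
        spec = SampleSizeSpec(base_rate=0.5, rate_reduction=0.20, alpha=0.05,
                              power=0.90, dispersion=1.2, follow_up=1.0)
        assert sample_size_nb(spec) == 1457

    def test_poisson_limit(self):
        spec = SampleSizeSpec(base_rate=0.5, rate_reduction=0.20, dispersion=0.0)
        assert sample_size_nb(spec) == 950

    def test_zero_reduction_rejected(self):
        with pytest.raises(ValueError, match="rate_reduction"):
            sample_size_nb(SampleSizeSpec(base_rate=0.5, rate_reduction=0.0))

    def test_monotonicity(self):
        base = dict(base_rate=0.5, rate_reduction=0.2, dispersion=1.2)
        n0 = sample_size_nb(SampleSizeSpec(**base))
        assert sample_size_nb(SampleSizeSpec(**{**base, "rate_reduction": 0.3})) <= n0
        assert sample_size_nb(SampleSizeSpec(**{**base, "base_rate": 0.8})) <= n0
        assert sample_size_nb(SampleSizeSpec(**{**base, "dispersion": 2.0})) >= n0
        assert sample_size_nb(SampleSizeSpec(**base, power=0.95)) >= n0
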