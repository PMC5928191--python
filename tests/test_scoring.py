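"""Tube scoring, end-point prediction, lag estimation, and the full assay."""

import math

import numpy as np
import pytest

from sdcmpn import (
    AssayIncompleteError,
    DilutionDesign,
    FluorescenceSample,
    GrowthFit,
    ScoringConfig,
    SimulationConfig,
    TubeSeries,
    estimate_lag,
    fit_growth_curve,
    predict_t_end,
    run_assay,
    score_tube,
    simulate_tubes,
)

MU_THAL = math.log(2) / 0.84  # fast diatom benchmark growth rate


def make_tube(times, values, tier=1, replicate=1, f_start=None):
    samples = tuple(FluorescenceSample(t=float(t), F=float(f))
                    for t, f in zip(times, values))
    return TubeSeries(tier=tier, replicate=replicate, samples=samples,
                      f_start=values[0] if f_start is None else f_start)


class TestGrowthCurveFit:
    def test_noiseless_exponential_recovered(self):
        t = np.arange(0, 12)
        tube = make_tube(t, 4.0 * np.exp(0.7 * t))
        fit = fit_growth_curve(tube, lld_f=1.0)
        assert fit.mu == pytest.approx(0.7)
        assert fit.f_init == pytest.approx(4.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_points_below_lld_are_excluded(self):
        t = np.arange(0, 12)
        f = 4.0 * np.exp(0.7 * t)
        full = fit_growth_curve(make_tube(t, f), lld_f=1.0)
        clipped = fit_growth_curve(make_tube(t, f), lld_f=50.0)
        assert clipped.mu == pytest.approx(full.mu)
        assert clipped.n_points < full.n_points

    def test_plateau_restricted_fit_recovers_planted_rate(self):
        """Simulated tube with a stationary plateau: fitting only the
        pre-plateau window recovers the planted rate within 1%."""
        design = DilutionDesign(X=0, q=2, r=1, V=5.0)
        config = SimulationConfig(
            n_viable_true=50.0, design=design, mu_true=0.7, per_cell_f=10.0,
            lld_f=20.0, plateau_f=5e4, noise_sd=0.0, duration_days=20.0,
            monitor_interval=1.0,
        )
        tubes, counts = simulate_tubes(config, seed=3)
        tube = next(t for t, c in zip(tubes, counts.ravel()) if c > 0)
        fit = fit_growth_curve(tube, lld_f=20.0, t_max=6.0)
        assert fit.mu == pytest.approx(0.7, rel=0.01)

    def test_too_few_points_raise(self):
        tube = make_tube([0, 1, 2, 3], [0.5, 0.6, 0.7, 20.0])
        with pytest.raises(ValueError):
            fit_growth_curve(tube, lld_f=1.0)


class TestPredictTEnd:
    def test_fast_species_third_tier_whole_days(self):
        """t_gen 0.84 d, LLD 117 cells/mL, N = 10 cells/mL, third tier:
        13 whole days at the 5-generation margin, 11 at 3."""
        raw5 = predict_t_end(10.0, 117.0, MU_THAL, tier_offset=2, y_margin=5)
        raw3 = predict_t_end(10.0, 117.0, MU_THAL, tier_offset=2, y_margin=3)
        assert raw5 == pytest.approx(12.76, abs=0.01)
        assert round(raw5) == 13
        assert round(raw3) == 11

    def test_equal_start_and_lld_gives_margin_generations(self):
        mu = 0.6
        t = predict_t_end(117.0, 117.0, mu, tier_offset=0, y_margin=5)
        assert t == pytest.approx(5 * math.log(2) / mu)

    def test_monotonicities(self):
        base = predict_t_end(10.0, 117.0, 0.6, 1, 5)
        assert predict_t_end(10.0, 117.0, 0.9, 1, 5) < base
        assert predict_t_end(30.0, 117.0, 0.6, 1, 5) < base
        extra = predict_t_end(10.0, 117.0, 0.6, 1, 6)
        assert extra - base == pytest.approx(math.log(2) / 0.6)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            predict_t_end(10.0, 117.0, 0.0, 0, 5)


class TestScoreTube:
    def test_flat_below_lld_is_negative(self):
        tube = make_tube(np.arange(0, 22, 2), [58.0] * 11, f_start=58.0)
        assert score_tube(tube, lld_f=117.0, t_end=20.0) == "negative"

    def test_threshold_crossing_is_positive(self):
        t = np.arange(0, 22, 2)
        f = 10.0 * np.exp(0.8 * t)
        tube = make_tube(t, f, f_start=10.0)
        assert score_tube(tube, lld_f=117.0, t_end=20.0) == "positive"

    def test_positive_persists_through_decline(self):
        """Rise then decline: repeated monitoring keeps the positive even
        when late single-day reads would miss it."""
        t = np.arange(0, 16, 1)
        rise = 50.0 * np.exp(0.8 * np.minimum(t, 9))
        decline = np.where(t > 9, rise * np.exp(-1.2 * (t - 9)), rise)
        tube = make_tube(t, decline, f_start=50.0)
        assert score_tube(tube, lld_f=117.0, t_end=15.0) == "positive"
        # a single read at day 14 would have missed it
        assert decline[14] < 8 * 117.0

    def test_unobserved_past_t_end_is_pending(self):
        tube = make_tube([0, 2, 4], [50.0, 55.0, 60.0], f_start=50.0)
        assert score_tube(tube, lld_f=117.0, t_end=10.0) == "pending"

    def test_crossing_at_first_read_after_t_end_counts(self):
        """Monitoring is discrete: a crossing first seen at the first
        reading after the raw end point still scores positive."""
        t = [0, 2, 4, 6, 8, 10]
        f = [50, 50, 50, 700, 800, 1000]
        tube = make_tube(t, f, f_start=50.0)
        assert score_tube(tube, lld_f=117.0, t_end=9.5) == "positive"

    def test_monotone_in_fluorescence(self):
        """Raising any reading never flips a positive to negative."""
        t = np.arange(0, 22, 2)
        f = np.array([50.0] * 7 + [950.0] + [50.0] * 3)
        tube = make_tube(t, f, f_start=50.0)
        assert score_tube(tube, lld_f=117.0, t_end=20.0) == "positive"
        raised = make_tube(t, f * 1.7, f_start=50.0)
        assert score_tube(raised, lld_f=117.0, t_end=20.0) == "positive"

    def test_threshold_nesting(self):
        """Positives at the strict 8x threshold are a subset of positives
        at the relaxed 1.5x threshold."""
        t = np.arange(0, 22, 2)
        rng = np.random.default_rng(5)
        strict = ScoringConfig(threshold_factor=8.0)
        relaxed = ScoringConfig(threshold_factor=1.5)
        for _ in range(50):
            f = np.exp(rng.uniform(3.0, 7.5, t.size))
            tube = make_tube(t, f, f_start=float(f[0]))
            s = score_tube(tube, 117.0, 20.0, strict)
            r = score_tube(tube, 117.0, 20.0, relaxed)
            if s == "positive":
                assert r == "positive"


class TestRunAssay:
    def test_all_sterile_is_below_detection(self, standard_design, perfect_calibration):
        config = SimulationConfig(n_viable_true=0.0, design=standard_design,
                                  lld_f=117.0, duration_days=20.0)
        tubes, _ = simulate_tubes(config, seed=1)
        result = run_assay(tubes, standard_design, perfect_calibration)
        assert result.n_viable == 0.0
        assert result.below_detection

    def test_pending_tubes_raise(self, standard_design, perfect_calibration):
        config = SimulationConfig(n_viable_true=100.0,
                                  design=DilutionDesign(X=-2),
                                  lld_f=117.0, duration_days=10.0)
        tubes, _ = simulate_tubes(config, seed=2)
        with pytest.raises(AssayIncompleteError) as err:
            run_assay(tubes, DilutionDesign(X=-2), perfect_calibration)
        assert err.value.pending

    def test_interval_coverage_of_true_concentration(self, perfect_calibration):
        """The exp(+/-2 sigma) interval brackets the true concentration in
        at least 90% of simulated assays."""
        design = DilutionDesign(X=-2)
        n_true, n_rep, covered = 100.0, 200, 0
        for i in range(n_rep):
            config = SimulationConfig(n_viable_true=n_true, design=design,
                                      lld_f=117.0)
            tubes, _ = simulate_tubes(config, seed=10_000 + i)
            result = run_assay(tubes, design, perfect_calibration)
            lo, hi = result.n_viable_ci
            covered += lo <= n_true <= hi
        assert covered / n_rep >= 0.90

    def test_untreated_culture_ci_contains_reference_count(self, perfect_calibration):
        """A fully viable untreated culture's MPN interval contains the
        flow-cytometry-style reference concentration."""
        n0 = 3.6e3
        design = DilutionDesign(X=choose_X(n0))
        config = SimulationConfig(n_viable_true=n0, design=design, lld_f=117.0)
        tubes, _ = simulate_tubes(config, seed=77)
        result = run_assay(tubes, design, perfect_calibration)
        lo, hi = result.n_viable_ci
        assert lo <= n0 <= hi


def choose_X(n):
    from sdcmpn import choose_dilution_range
    return choose_dilution_range(n, V=5.0)


class TestLagEstimate:
    def test_equal_intercepts_no_lag(self):
        fit = GrowthFit(mu=0.7, f_init=500.0, r2=1.0, n_points=5)
        lag = estimate_lag(fit, f_init_prime_untreated=5.0, n_viable_treated=100.0)
        assert lag.lag_days == pytest.approx(0.0)

    def test_halved_intercept_one_doubling(self):
        fit = GrowthFit(mu=math.log(2), f_init=250.0, r2=1.0, n_points=5)
        lag = estimate_lag(fit, f_init_prime_untreated=5.0, n_viable_treated=100.0)
        assert lag.lag_days == pytest.approx(1.0)
        assert lag.lag_generations == pytest.approx(1.0)

    def test_negative_lag_permitted(self):
        fit = GrowthFit(mu=0.7, f_init=1000.0, r2=1.0, n_points=5)
        lag = estimate_lag(fit, f_init_prime_untreated=5.0, n_viable_treated=100.0)
        assert lag.lag_days < 0

    def test_rejects_nonpositive_inputs(self):
        fit = GrowthFit(mu=0.7, f_init=500.0, r2=1.0, n_points=5)
        with pytest.raises(ValueError):
            estimate_lag(fit, 5.0, 0.0)
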