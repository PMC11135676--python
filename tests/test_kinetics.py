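"""Gompertz production model, T0 detection, fitting, and comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulchkit.kinetics import (
    DegenerateFitError,
    GompertzFit,
    GompertzParams,
    GrowthCurve,
    KineticSummary,
    NoTransitionError,
    ProductionCurve,
    ReplicateKinetics,
    compare_parameters,
    detect_transition_time,
    fit_gompertz,
    gompertz_value,
    production_duration,
    production_start_time,
    summarize_strain,
)
from pulchkit.synthio import GENOTYPE_PRESETS, generate_growth_curve


def _curve_from_params(params, times, strain="s", rep="1"):
    return ProductionCurve(strain, rep, times, gompertz_value(params, times))


class TestGompertzValue:
    P = GompertzParams(y0=0.0, K=1.0, mumax=1.0, lam=5.0)

    def test_asymptotes(self):
        assert gompertz_value(self.P, -50.0) == pytest.approx(0.0, abs=1e-6)
        assert gompertz_value(self.P, 1000.0) == pytest.approx(1.0, abs=1e-6)

    def test_max_slope_equals_mumax(self):
        # finite-difference oracle on a dense grid
        t = np.linspace(-20, 40, 200001)
        y = gompertz_value(self.P, t)
        max_slope = np.max(np.diff(y) / np.diff(t))
        assert max_slope == pytest.approx(self.P.mumax, abs=1e-4)

    @given(
        y0=st.floats(0.0, 0.5),
        span=st.floats(0.01, 2.0),
        mumax=st.floats(1e-3, 1.0),
        lam=st.floats(-10.0, 20.0),
        t1=st.floats(-50.0, 50.0),
        dt=st.floats(1e-6, 50.0),
    )
    def test_monotone_nondecreasing(self, y0, span, mumax, lam, t1, dt):
        p = GompertzParams(y0=y0, K=y0 + span, mumax=mumax, lam=lam)
        assert gompertz_value(p, t1 + dt) >= gompertz_value(p, t1) - 1e-15

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GompertzParams(y0=0.2, K=0.1, mumax=1.0, lam=0.0)
        with pytest.raises(ValueError):
            GompertzParams(y0=0.0, K=0.1, mumax=-1.0, lam=0.0)


def _brute_force_t0(curve, window_points, r2_min, deviation_frac, run_length):
    """Exhaustive-scan oracle: same rule, no shortcuts."""
    t, od = curve.times, curve.od600
    log_od = np.log(od)
    windows = []
    for i in range(t.size - window_points + 1):
        tw, yw = t[i : i + window_points], log_od[i : i + window_points]
        slope, intercept = np.polyfit(tw, yw, 1)
        ss_res = np.sum((yw - (slope * tw + intercept)) ** 2)
        ss_tot = np.sum((yw - yw.mean()) ** 2)
        if ss_tot > 0 and 1 - ss_res / ss_tot >= r2_min and slope > 0:
            windows.append((slope, intercept, i))
    if not windows:
        return None
    slope, intercept, i0 = max(windows, key=lambda w: w[0])
    for j in range(i0 + window_points, t.size):
        pred = [np.exp(slope * t[k] + intercept) for k in range(j, j + run_length)]
        if j + run_length - 1 < t.size and all(
            (pred[q] - od[j + q]) / pred[q] > deviation_frac
            for q in range(run_length)
        ):
            return t[j]
    return None


class TestDetectTransition:
    def test_matches_exhaustive_oracle_on_noise_free_logistic(self):
        times = np.arange(0, 30.001, 0.5)
        curve = generate_growth_curve(GENOTYPE_PRESETS["WT"], times, noise_sd=0.0, seed=0)
        est = detect_transition_time(curve)
        oracle = _brute_force_t0(curve, 5, 0.99, 0.05, 3)
        assert abs(est.t0 - oracle) <= 0.5  # within one sampling interval

    def test_pure_exponential_raises_no_transition(self):
        t = np.arange(0, 10.001, 0.5)
        curve = GrowthCurve("s", "1", t, 0.01 * np.exp(0.5 * t))
        with pytest.raises(NoTransitionError):
            detect_transition_time(curve)

    def test_t0_spread_across_seeds_is_bounded(self):
        # With OD noise 0.01 the sub-0.1-OD points are noise-dominated, so
        # the reference window (and hence T0) jitters by a few sampling
        # intervals; the spread should stay within +/- 3 intervals (SD <= 1.5 h).
        times = np.arange(0, 30.001, 0.5)
        t0s = [
            detect_transition_time(
                generate_growth_curve(GENOTYPE_PRESETS["WT"], times,
                                      noise_sd=0.01, seed=s)
            ).t0
            for s in range(15)
        ]
        assert np.std(t0s) <= 1.5
        assert max(t0s) - min(t0s) <= 6 * 0.5 * 2  # hard cap on the range

    def test_too_few_points_rejected(self):
        t = np.arange(0, 4.0, 0.5)
        curve = GrowthCurve("s", "1", t, 0.01 * np.exp(0.5 * t))
        with pytest.raises(ValueError):
            detect_transition_time(curve, window_points=5)


class TestFitGompertz:
    def test_recovers_noiseless_parameters(self):
        truth = GompertzParams(y0=0.01, K=0.10, mumax=0.02, lam=2.0)
        fit = fit_gompertz(_curve_from_params(truth, np.arange(0, 30.01, 0.5)))
        assert fit.converged
        for name in ("y0", "K", "mumax", "lam"):
            got, want = getattr(fit.params, name), getattr(truth, name)
            assert got == pytest.approx(want, rel=1e-3, abs=1e-6)

    def test_parameter_recovery_suite(self, rng):
        # 50 random parameter sets within realistic assay ranges; the lag
        # and duration are drawn so the curve completes within the 40 h
        # observation window (otherwise K is not identifiable)
        for _ in range(50):
            y0 = float(rng.uniform(0.0, 0.05))
            K = float(rng.uniform(0.1, 1.0))
            duration = float(rng.uniform(3.0, 25.0))
            truth = GompertzParams(
                y0=y0, K=K, mumax=(K - y0) / duration,
                lam=float(rng.uniform(0.0, 8.0)),
            )
            fit = fit_gompertz(_curve_from_params(truth, np.arange(0, 40.01, 0.5)))
            assert fit.converged
            for name in ("K", "mumax", "lam", "y0"):
                got, want = getattr(fit.params, name), getattr(truth, name)
                assert got == pytest.approx(want, rel=1e-3, abs=1e-4), name

    def test_constant_series_is_degenerate(self):
        t = np.arange(0, 10.01, 0.5)
        with pytest.raises(DegenerateFitError):
            fit_gompertz(ProductionCurve("s", "1", t, np.full(t.size, 0.05)))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_gompertz(ProductionCurve("s", "1", np.arange(5.0), np.arange(5.0) / 10))


class TestProductionStartTime:
    WT = GompertzParams(y0=0.01, K=0.10, mumax=0.005, lam=6.0)

    def test_identical_fits_never_deviate(self):
        assert production_start_time(self.WT, self.WT, t0=6.0, delta=0.005) is None

    def test_matches_exhaustive_scan_oracle(self):
        mutant = GompertzParams(y0=0.01, K=0.2, mumax=0.05, lam=4.0)
        flatref = GompertzParams(y0=0.01, K=0.011, mumax=1e-6, lam=0.0)
        t0, delta, step = 6.0, 0.005, 0.1
        got = production_start_time(mutant, flatref, t0=t0, delta=delta,
                                    grid_step=step)
        # oracle: scan every grid time exhaustively
        rel = np.arange(-10.0, 30.0 + step / 2, step)
        diff = gompertz_value(mutant, rel + t0) - gompertz_value(flatref, rel + t0)
        oracle = next(
            rel[i] for i in range(rel.size - 1)
            if diff[i] > delta and diff[i + 1] > delta
        )
        assert got == pytest.approx(oracle, abs=step)

    @given(delta=st.floats(0.001, 0.05), delta_up=st.floats(0.0, 0.05))
    def test_monotone_in_delta(self, delta, delta_up):
        mutant = GompertzParams(y0=0.01, K=0.3, mumax=0.03, lam=4.0)
        s1 = production_start_time(mutant, self.WT, t0=6.0, delta=delta)
        s2 = production_start_time(mutant, self.WT, t0=6.0, delta=delta + delta_up)
        if s2 is not None:
            assert s1 is not None and s1 <= s2


class TestProductionDuration:
    def test_tangent_algebra(self):
        p = GompertzParams(y0=0.0, K=0.1, mumax=0.02, lam=3.0)
        assert production_duration(p) == pytest.approx(5.0)

    def test_scale_cancellation(self):
        p1 = GompertzParams(y0=0.0, K=0.1, mumax=0.02, lam=3.0)
        p2 = GompertzParams(y0=0.0, K=0.2, mumax=0.04, lam=3.0)
        assert production_duration(p1) == production_duration(p2)

    @given(
        span=st.floats(0.01, 1.0),
        mumax=st.floats(1e-3, 0.5),
        lam=st.floats(-5.0, 15.0),
    )
    def test_equals_numeric_tangent_construction(self, span, mumax, lam):
        """The inflection tangent crosses y0 and K a span/mumax apart."""
        p = GompertzParams(y0=0.01, K=0.01 + span, mumax=mumax, lam=lam)
        # inflection of the modified Gompertz: where the inner exponent is 0
        t_inf = lam + span / (mumax * math.e)
        # step scaled to the curve's own time constant span/(mumax*e) so the
        # central-difference slope is accurate even for fast, shallow curves
        h = 1e-3 * span / (mumax * math.e)
        slope = (gompertz_value(p, t_inf + h) - gompertz_value(p, t_inf - h)) / (2 * h)
        y_inf = gompertz_value(p, t_inf)
        t_lo = t_inf + (p.y0 - y_inf) / slope
        t_hi = t_inf + (p.K - y_inf) / slope
        assert production_duration(p) == pytest.approx(t_hi - t_lo, rel=1e-6)
        assert production_duration(p) == pytest.approx(span / mumax)


def _replicate(strain, rep, K, mumax, start):
    fit = GompertzFit(
        params=GompertzParams(y0=0.01, K=K, mumax=mumax, lam=5.0),
        residual_sd=0.001, converged=True, n_obs=61,
    )
    return ReplicateKinetics(strain=strain, replicate=rep, fit=fit,
                             start_time=start, t0=6.0)


class TestSummaries:
    def test_single_replicate_reports_zero_sd(self):
        s = summarize_strain([_replicate("a", "1", 0.3, 0.02, -2.0)])
        assert s.replicate_n == 1
        assert s.sds["max_a410"] == 0.0

    def test_identical_replicates(self):
        reps = [_replicate("a", str(i), 0.3, 0.02, -2.0) for i in range(3)]
        s = summarize_strain(reps)
        assert s.means["max_a410"] == pytest.approx(0.3)
        assert s.sds["max_a410"] == 0.0

    def test_mean_sd_match_hand_computation(self):
        reps = [_replicate("a", str(i), K, 0.02, -2.0)
                for i, K in enumerate([0.2, 0.3, 0.4])]
        s = summarize_strain(reps)
        assert s.means["max_a410"] == pytest.approx(0.3)
        assert s.sds["max_a410"] == pytest.approx(0.1)  # sample SD of 0.2,0.3,0.4
        assert s.means["duration"] == pytest.approx(np.mean([0.19, 0.29, 0.39]) / 0.02)

    def test_mixed_strains_rejected(self):
        with pytest.raises(ValueError):
            summarize_strain([_replicate("a", "1", 0.3, 0.02, -2.0),
                              _replicate("b", "1", 0.3, 0.02, -2.0)])


def _summary(strain, mean, sd, n=3):
    means = {p: mean for p in ("start_time", "duration", "max_rate", "max_a410")}
    sds = {p: sd for p in ("start_time", "duration", "max_rate", "max_a410")}
    return KineticSummary(strain=strain, replicate_n=n, means=means, sds=sds)


class TestCompareParameters:
    def test_identical_groups_are_not_significant(self):
        table = compare_parameters(
            [_summary("a", 0.3, 0.0), _summary("b", 0.3, 0.0)], "max_a410"
        )
        assert table.raw_p.iloc[0] == 1.0
        assert not table.significant.iloc[0]

    def test_bonferroni_definition(self):
        # 4 strains -> 6 pairs; adjusted p = min(1, raw p * 6)
        sums = [_summary(s, m, 0.05) for s, m in
                zip("abcd", [0.1, 0.2, 0.3, 0.4])]
        table = compare_parameters(sums, "max_a410")
        assert len(table) == 6
        expected = np.minimum(1.0, table.raw_p * 6)
        assert np.allclose(table.adj_p, expected)

    def test_welch_t_matches_textbook_formula(self):
        a = np.array([0.30, 0.32, 0.34])
        b = np.array([0.40, 0.45, 0.41])
        sa = _summary("a", float(a.mean()), float(a.std(ddof=1)))
        sb = _summary("b", float(b.mean()), float(b.std(ddof=1)))
        table = compare_parameters([sa, sb], "max_a410")
        # hand-computed Welch t and df
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_stat = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy.stats import t as t_dist
        p_hand = 2 * t_dist.sf(abs(t_stat), df)
        assert table.raw_p.iloc[0] == pytest.approx(p_hand, rel=1e-10)

    def test_adjusted_p_bounds(self):
        sums = [_summary(s, m, 0.08) for s, m in zip("abcde", [0.1, 0.15, 0.2, 0.3, 0.31])]
        table = compare_parameters(sums, "duration")
        assert (table.adj_p >= table.raw_p).all()
        assert (table.adj_p <= 1.0).all()

    def test_single_replicate_strain_rejected(self):
        with pytest.raises(ValueError):
            compare_parameters([_summary("a", 0.3, 0.0, n=1),
                                _summary("b", 0.4, 0.1)], "max_a410")
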