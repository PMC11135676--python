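"""Pulcherrimin production kinetics anchored to the growth-phase transition.

Pulcherrimin accumulation is read out as absorbance at 410 nm (A410) of
alkali-solubilized cell pellets sampled along a growth curve.  The analysis
has three steps:

1. Detect T0, the time at which OD600 growth deviates from exponential
   (entry into the transition/stationary phase), by sliding-window
   log-linear fitting.
2. Fit each strain x replicate A410 time course with the Zwietering
   modified-Gompertz model

       y(t) = y0 + (K - y0) * exp(-exp(mumax * e * (lam - t) / (K - y0) + 1))

   whose parameters are the baseline ``y0``, the plateau (carrying
   capacity) ``K``, the maximum production rate ``mumax`` (slope at the
   inflection) and the lag time ``lam``.
3. Summarize, per strain, the production start time relative to T0, the
   production duration, the maximum rate and the maximum A410, and compare
   strains pairwise with Bonferroni-corrected Welch t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GrowthCurve",
    "ProductionCurve",
    "GompertzParams",
    "GompertzFit",
    "TransitionEstimate",
    "ReplicateKinetics",
    "KineticSummary",
    "NoExponentialPhaseError",
    "NoTransitionError",
    "DegenerateFitError",
    "gompertz_value",
    "detect_transition_time",
    "fit_gompertz",
    "production_start_time",
    "production_duration",
    "summarize_strain",
    "compare_parameters",
]

_E = math.e


class NoExponentialPhaseError(ValueError):
    """No sliding window of the growth curve is acceptably log-linear."""


class NoTransitionError(ValueError):
    """The growth curve never deviates from the exponential reference."""


class DegenerateFitError(ValueError):
    """The production curve has too little dynamic range to fit."""


def _check_series(times, values, value_name: str, min_value: float | None = None):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty time series")
    if times.size != values.size:
        raise ValueError("times and values differ in length")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if min_value is not None and np.any(values <= min_value):
        raise ValueError(f"{value_name} values must be > {min_value}")
    return times, values


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time course for one strain and replicate."""

    strain: str
    replicate: str
    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t, v = _check_series(self.times, self.od600, "od600", min_value=0.0)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", v)


@dataclass(frozen=True)
class ProductionCurve:
    """An A410 (pulcherrimin) time course for one strain and replicate.

    ``t0_anchored`` flags whether times are relative to the growth-phase
    transition (negative before T0) rather than hours since inoculation.
    """

    strain: str
    replicate: str
    times: np.ndarray
    a410: np.ndarray
    t0_anchored: bool = False

    def __post_init__(self) -> None:
        t, v = _check_series(self.times, self.a410, "a410")
        if np.any(v < 0):
            raise ValueError("a410 values must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "a410", v)


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the modified-Gompertz production model.

    y0 : baseline absorbance; K : plateau absorbance; mumax : maximum
    production rate (absorbance/h); lam : lag time (h).
    """

    y0: float
    K: float
    mumax: float
    lam: float

    def __post_init__(self) -> None:
        if not self.K > self.y0:
            raise ValueError("K must exceed y0")
        if not self.mumax > 0:
            raise ValueError("mumax must be positive")


@dataclass(frozen=True)
class GompertzFit:
    """A fitted model plus diagnostics."""

    params: GompertzParams
    residual_sd: float
    converged: bool
    n_obs: int


@dataclass(frozen=True)
class TransitionEstimate:
    """The exponential-to-stationary transition for one growth curve."""

    strain: str
    replicate: str
    t0: float
    exp_rate: float
    fit_window: tuple[float, float]


def gompertz_value(params: GompertzParams, t):
    """Evaluate the modified-Gompertz curve at time(s) ``t`` (hours).

    Monotone nondecreasing in t; tends to ``y0`` as t -> -inf and to ``K``
    as t -> +inf; the slope at the inflection equals ``mumax``.
    """
    t = np.asarray(t, dtype=float)
    span = params.K - params.y0
    inner = params.mumax * _E * (params.lam - t) / span + 1.0
    # exp(inner) overflows harmlessly to +inf -> outer exp underflows to 0
    with np.errstate(over="ignore"):
        val = params.y0 + span * np.exp(-np.exp(inner))
    return val if val.ndim else float(val)


def detect_transition_time(
    curve: GrowthCurve,
    window_points: int = 5,
    r2_min: float = 0.99,
    deviation_frac: float = 0.05,
    run_length: int = 3,
) -> TransitionEstimate:
    """Find T0, the time growth deviates from exponential.

    log(OD600) is fitted in every sliding window of ``window_points``
    consecutive observations; among windows with R^2 >= ``r2_min`` the one
    with maximal slope defines the exponential reference line.  T0 is the
    earliest time after that window at which the observed OD falls below
    the extrapolated exponential by more than ``deviation_frac``
    (relatively) for ``run_length`` consecutive points.
    """
    t, od = curve.times, curve.od600
    n = t.size
    if n < 2 * window_points:
        raise ValueError(f"need at least {2 * window_points} observations")
    log_od = np.log(od)

    best = None  # (slope, intercept, i_start)
    for i in range(n - window_points + 1):
        tw = t[i : i + window_points]
        yw = log_od[i : i + window_points]
        slope, intercept = np.polyfit(tw, yw, 1)
        resid = yw - (slope * tw + intercept)
        ss_tot = np.sum((yw - yw.mean()) ** 2)
        if ss_tot == 0:
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        if r2 >= r2_min and slope > 0 and (best is None or slope > best[0]):
            best = (slope, intercept, i)
    if best is None:
        raise NoExponentialPhaseError(
            f"no window of {window_points} points reaches R^2 >= {r2_min}"
        )
    slope, intercept, i0 = best
    window = (float(t[i0]), float(t[i0 + window_points - 1]))

    after = np.arange(i0 + window_points, n)
    predicted = np.exp(slope * t[after] + intercept)
    shortfall = (predicted - od[after]) / predicted
    deviating = shortfall > deviation_frac
    for j in range(deviating.size - run_length + 1):
        if deviating[j : j + run_length].all():
            return TransitionEstimate(
                strain=curve.strain,
                replicate=curve.replicate,
                t0=float(t[after[j]]),
                exp_rate=float(slope),
                fit_window=window,
            )
    raise NoTransitionError("growth never deviates from the exponential reference")


def _gompertz_f(t, y0, K, mumax, lam):
    span = K - y0
    with np.errstate(over="ignore"):
        return y0 + span * np.exp(-np.exp(mumax * _E * (lam - t) / span + 1.0))


def fit_gompertz(
    curve: ProductionCurve,
    min_dynamic_range: float = 0.02,
    max_nfev: int = 10000,
) -> GompertzFit:
    """Fit the modified-Gompertz model to an A410 course by nonlinear
    least squares.

    Initialization from the data: y0 = min, K = max, mumax = steepest
    observed secant slope, lam = time of first rise above y0 + 10% of the
    range.  Non-convergence is flagged, not silent; a dynamic range below
    ``min_dynamic_range`` raises :class:`DegenerateFitError`.
    """
    t, y = curve.times, curve.a410
    if t.size < 6:
        raise ValueError("need at least 6 observations to fit")
    lo, hi = float(y.min()), float(y.max())
    rng = hi - lo
    if rng < min_dynamic_range:
        raise DegenerateFitError(
            f"dynamic range {rng:.4g} below floor {min_dynamic_range:.4g}"
        )
    secants = np.diff(y) / np.diff(t)
    mu0 = max(float(secants.max()), rng / (t[-1] - t[0]))
    above = np.nonzero(y > lo + 0.1 * rng)[0]
    lam0 = float(t[above[0]]) if above.size else float(t[0])
    p0 = [lo, hi, mu0, lam0]
    eps = max(rng * 1e-3, 1e-9)
    bounds = (
        [lo - rng, lo + eps, 1e-9, t[0] - (t[-1] - t[0])],
        [hi - eps, hi + rng, np.inf, t[-1] + (t[-1] - t[0])],
    )
    p0 = np.clip(p0, bounds[0], bounds[1])
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            _gompertz_f, t, y, p0=p0, bounds=bounds, max_nfev=max_nfev
        )
    except RuntimeError:
        converged = False
        popt = p0
    resid = y - _gompertz_f(t, *popt)
    dof = max(t.size - 4, 1)
    params = GompertzParams(y0=float(popt[0]), K=float(popt[1]),
                            mumax=float(popt[2]), lam=float(popt[3]))
    return GompertzFit(
        params=params,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        converged=converged,
        n_obs=int(t.size),
    )


def production_start_time(
    mutant_fit: GompertzParams,
    reference_fit: GompertzParams,
    t0: float,
    delta: float,
    grid_step: float = 0.1,
    grid_start: float = -10.0,
    grid_end: float = 30.0,
) -> float | None:
    """Earliest time (hours relative to T0) at which the predicted mutant
    A410 exceeds the predicted reference A410 by more than ``delta``,
    sustained for two consecutive grid points.  Returns None if never.

    ``grid_start``/``grid_end`` bound the scan, in hours relative to T0.
    """
    rel = np.arange(grid_start, grid_end + grid_step / 2, grid_step)
    t_abs = rel + t0
    diff = gompertz_value(mutant_fit, t_abs) - gompertz_value(reference_fit, t_abs)
    exceeds = diff > delta
    sustained = exceeds[:-1] & exceeds[1:]
    idx = np.nonzero(sustained)[0]
    return float(rel[idx[0]]) if idx.size else None


def production_duration(params: GompertzParams) -> float:
    """Duration of the production phase via the inflection-tangent
    construction: the interval between the tangent line's crossings of the
    baseline y0 and the plateau K.  For the modified-Gompertz model this is
    exactly (K - y0) / mumax hours.
    """
    return (params.K - params.y0) / params.mumax


@dataclass(frozen=True)
class ReplicateKinetics:
    """Per-replicate kinetic quantities feeding the strain summary."""

    strain: str
    replicate: str
    fit: GompertzFit
    start_time: float | None  # hours relative to T0
    t0: float


_SUMMARY_PARAMS = ("start_time", "duration", "max_rate", "max_a410")


@dataclass(frozen=True)
class KineticSummary:
    """Per-strain replicate mean and SD of the four kinetic parameters:
    production start time relative to T0, production duration, maximum
    production rate (mumax) and maximum A410 (K)."""

    strain: str
    replicate_n: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    @property
    def start_time(self) -> float:
        return self.means["start_time"]

    @property
    def duration(self) -> float:
        return self.means["duration"]

    @property
    def max_rate(self) -> float:
        return self.means["max_rate"]

    @property
    def max_a410(self) -> float:
        return self.means["max_a410"]


def summarize_strain(replicates: list[ReplicateKinetics]) -> KineticSummary:
    """Aggregate per-replicate fits into per-strain mean and SD.

    max_rate is the fitted mumax and max_a410 the fitted K.  Replicates
    with no detected production start are excluded from the start-time
    average only.  A single replicate reports SD 0 (flagged by n=1).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    strains = {r.strain for r in replicates}
    if len(strains) > 1:
        raise ValueError(f"mixed strains in input: {sorted(strains)}")
    values = {
        "start_time": [r.start_time for r in replicates if r.start_time is not None],
        "duration": [production_duration(r.fit.params) for r in replicates],
        "max_rate": [r.fit.params.mumax for r in replicates],
        "max_a410": [r.fit.params.K for r in replicates],
    }
    means, sds = {}, {}
    for name in _SUMMARY_PARAMS:
        v = np.asarray(values[name], dtype=float)
        if v.size == 0:
            means[name], sds[name] = math.nan, math.nan
        else:
            means[name] = float(v.mean())
            sds[name] = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return KineticSummary(
        strain=replicates[0].strain,
        replicate_n=len(replicates),
        means=means,
        sds=sds,
    )


def compare_parameters(
    summaries: list[KineticSummary],
    parameter: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sided Welch t-tests on one kinetic parameter across
    strains, Bonferroni-corrected (adjusted p = min(1, raw p x number of
    pairs)).

    Returns a DataFrame with columns strain_a, strain_b, raw_p, adj_p,
    significant.  Degenerate pairs (zero variance in both groups) get
    raw p = 1 and are never significant.
    """
    if parameter not in _SUMMARY_PARAMS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if len(summaries) < 2:
        raise ValueError("need at least two strains to compare")
    for s in summaries:
        if s.replicate_n < 2:
            raise ValueError(f"strain {s.strain!r} has < 2 replicates")
    pairs = [
        (summaries[i], summaries[j])
        for i in range(len(summaries))
        for j in range(i + 1, len(summaries))
    ]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = stats.ttest_ind_from_stats(
            a.means[parameter], a.sds[parameter], a.replicate_n,
            b.means[parameter], b.sds[parameter], b.replicate_n,
            equal_var=False,
        )
        raw_p = float(res.pvalue)
        if math.isnan(raw_p):
            raw_p = 1.0
        adj_p = min(1.0, raw_p * m)
        rows.append(
            {
                "strain_a": a.strain,
                "strain_b": b.strain,
                "parameter": parameter,
                "raw_p": raw_p,
                "adj_p": adj_p,
                "significant": adj_p < alpha,
            }
        )
    return pd.DataFrame(rows)
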