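"""Instantaneous growth-rate estimation from sparse growth curves.

Dilution-to-extinction isolates of oligotrophic marine bacteria are typically
counted by flow cytometry at irregular, sparse time points, which makes the
classical "fit one line through the exponential phase" approach fragile.
The estimator implemented here works directly on log2-transformed cell
densities:

1. slide a 3-point window (stride 1) along the curve and fit ordinary least
   squares to (time, log2 density); the slope is an instantaneous doubling
   rate in doublings/day and the slope standard error (1 residual degree of
   freedom) quantifies its uncertainty;
2. fan each window out into nine candidate rates — {slope - se, slope,
   slope + se} assigned to the window's start, middle and end times;
3. take the median candidate rate at each unique sampling time, so interior
   time points (covered by up to three windows) pool up to nine or more
   candidates;
4. delimit the exponential phase by fitting a decreasing four-parameter
   logistic ("sigmoid decay") to rate vs. time and keeping the rates before
   the inflection point; if the fit fails, fall back to the three rates of
   largest absolute value;
5. summarize replicate curves per culture condition (median +/- dispersion of
   pooled exponential-phase rates, growth/no-growth call) and assemble
   growth envelopes across a condition gradient (temperature, salinity,
   carbon).

All rates are doublings (divisions) per day; times are days; densities are
cells/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DuplicateTimesError,
    EmptyInputError,
    NonPositiveDensityError,
    TooFewPointsError,
)

__all__ = [
    "GrowthCurve",
    "WindowEstimate",
    "CandidateRate",
    "InstantRateSeries",
    "SigmoidFit",
    "ConditionSummary",
    "GrowthEnvelope",
    "compute_window_estimates",
    "generate_candidates",
    "median_rate_series",
    "fit_sigmoid_decay",
    "exponential_phase_rates",
    "estimate_rate_series",
    "summarize_condition",
    "growth_envelope",
]

OFFSET_TAGS = ("minus", "center", "plus")
POSITION_TAGS = ("start", "middle", "end")


@dataclass(frozen=True)
class GrowthCurve:
    """A single replicate growth curve with its culture condition.

    Parameters
    ----------
    strain_id, replicate_id
        Free-text identifiers.
    condition
        Mapping of condition variable name to value, e.g.
        ``{"temperature_C": 18.5, "salinity_ppt": 30.0}``.
    times
        Sampling times in days, strictly increasing.
    densities
        Cell densities in cells/ml, strictly positive, same length as times.
    """

    strain_id: str
    replicate_id: str
    condition: Mapping[str, float]
    times: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        densities = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "densities", densities)
        if times.ndim != 1 or densities.ndim != 1:
            raise ValueError("times and densities must be 1-D")
        if times.size != densities.size:
            raise ValueError("times and densities must have equal length")
        if times.size < 1:
            raise TooFewPointsError("a growth curve needs at least one point")
        if np.any(np.diff(times) <= 0):
            raise DuplicateTimesError("sampling times must be strictly increasing")
        if np.any(densities <= 0) or not np.all(np.isfinite(densities)):
            raise NonPositiveDensityError("cell densities must be finite and > 0")

    @property
    def log2_densities(self) -> np.ndarray:
        return np.log2(self.densities)

    @property
    def fold_increase(self) -> float:
        """Maximum density divided by the first observed density."""
        return float(self.densities.max() / self.densities[0])


@dataclass(frozen=True)
class WindowEstimate:
    """OLS slope of log2 density vs. time over one 3-point window."""

    window_index: int
    window_times: tuple[float, float, float]
    slope: float
    slope_se: float
    intercept: float

    def __post_init__(self) -> None:
        t = self.window_times
        if not (t[0] < t[1] < t[2]):
            raise DuplicateTimesError("window times must be strictly increasing")
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.slope_se < 0:
            raise ValueError("slope standard error must be >= 0")


@dataclass(frozen=True)
class CandidateRate:
    """One of the nine rate candidates a window contributes."""

    time: float
    rate: float
    window_index: int
    offset_tag: str  # minus | center | plus
    position_tag: str  # start | middle | end


@dataclass(frozen=True)
class InstantRateSeries:
    """Median instantaneous doubling rate at each unique sampling time."""

    times: np.ndarray
    median_rates: np.ndarray
    candidates: tuple[CandidateRate, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "median_rates", np.asarray(self.median_rates, dtype=float))


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter decreasing logistic fitted to rate vs. time.

    r(t) = r_low + (r_high - r_low) / (1 + exp((t - t_inflect) / tau))

    ``converged`` is True only when the optimizer succeeded, the inflection
    lies inside the observed time span, and r_high > r_low.
    """

    r_high: float
    r_low: float
    t_inflect: float
    tau: float
    converged: bool
    rss: float


@dataclass(frozen=True)
class ConditionSummary:
    """Pooled exponential-phase growth statistics for one culture condition."""

    condition: Mapping[str, float]
    exp_phase_rates: tuple[tuple[float, float], ...]
    representative_rate: float
    mean_rate: float
    rate_dispersion: float
    rate_range: tuple[float, float]
    max_density: float
    fold_increase: float
    growth_call: bool
    n_replicates: int = 1


@dataclass(frozen=True)
class GrowthEnvelope:
    """Growth summaries ordered along one condition variable."""

    variable: str
    summaries: tuple[ConditionSummary, ...]
    max_rate: float
    max_rate_condition: Mapping[str, float] | None
    permissive_range: tuple[float, float] | None
    non_permissive_values: tuple[float, ...] = field(default_factory=tuple)

    @property
    def has_growth(self) -> bool:
        return self.permissive_range is not None


def compute_window_estimates(
    curve: GrowthCurve, window_size: int = 3
) -> list[WindowEstimate]:
    """Fit OLS to log2 density vs. time in every stride-1 window of 3 points.

    Returns ``n - 2`` estimates for a curve of ``n`` points. The slope
    standard error uses the single residual degree of freedom a 3-point
    regression provides: ``sqrt(SSE / sum((t_i - tbar)^2))``.
    """
    if window_size != 3:
        raise ValueError("only 3-point windows are supported")
    n = curve.times.size
    if n < window_size:
        raise TooFewPointsError(
            f"need at least {window_size} points, got {n}"
        )
    y = curve.log2_densities
    estimates: list[WindowEstimate] = []
    for i in range(n - window_size + 1):
        t = curve.times[i : i + window_size]
        yw = y[i : i + window_size]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.linregress(t, yw)
        # SE from residuals with the window's single residual dof; linregress
        # reports NaN on zero-variance y, where the correct SE is 0
        sse = float(np.sum((yw - (res.intercept + res.slope * t)) ** 2))
        sxx = float(np.sum((t - t.mean()) ** 2))
        estimates.append(
            WindowEstimate(
                window_index=i,
                window_times=(float(t[0]), float(t[1]), float(t[2])),
                slope=float(res.slope),
                slope_se=math.sqrt(sse / (window_size - 2) / sxx),
                intercept=float(res.intercept),
            )
        )
    return estimates


def generate_candidates(w: WindowEstimate) -> list[CandidateRate]:
    """Fan a window estimate out into its nine candidate rates.

    Cartesian product of {slope - se, slope, slope + se} with the window's
    start, middle and end times.
    """
    rates = (w.slope - w.slope_se, w.slope, w.slope + w.slope_se)
    out = []
    for offset_tag, rate in zip(OFFSET_TAGS, rates):
        for position_tag, time in zip(POSITION_TAGS, w.window_times):
            out.append(
                CandidateRate(
                    time=time,
                    rate=rate,
                    window_index=w.window_index,
                    offset_tag=offset_tag,
                    position_tag=position_tag,
                )
            )
    return out


def median_rate_series(candidates: Sequence[CandidateRate]) -> InstantRateSeries:
    """Median candidate rate at each unique time, order-independent."""
    if len(candidates) == 0:
        raise EmptyInputError("no candidate rates to aggregate")
    by_time: dict[float, list[float]] = {}
    for c in candidates:
        by_time.setdefault(c.time, []).append(c.rate)
    times = np.array(sorted(by_time), dtype=float)
    medians = np.array([np.median(by_time[t]) for t in times])
    return InstantRateSeries(
        times=times, median_rates=medians, candidates=tuple(candidates)
    )


def _sigmoid(t: np.ndarray, r_high: float, r_low: float, t_inflect: float, tau: float) -> np.ndarray:
    # exponent clipped: exp(>700) overflows float64 but saturates the same
    z = np.clip((t - t_inflect) / tau, -700.0, 700.0)
    return r_low + (r_high - r_low) / (1.0 + np.exp(z))


def fit_sigmoid_decay(
    series: InstantRateSeries, n_restarts: int = 5, seed: int = 0
) -> SigmoidFit:
    """Fit the decreasing logistic to the median rate series.

    Never raises on fit failure: a non-converged ``SigmoidFit`` is returned
    when the series is too short (< 4 distinct times), the optimizer fails,
    the fitted inflection falls outside the observed span, or the fitted
    curve is not decreasing (r_high <= r_low). Initial values are jittered
    over a fixed-seed set of restarts for robustness.
    """
    t = series.times
    r = series.median_rates
    failed = SigmoidFit(
        r_high=float("nan"),
        r_low=float("nan"),
        t_inflect=float("nan"),
        tau=float("nan"),
        converged=False,
        rss=float("nan"),
    )
    if t.size < 4:
        return failed
    span = float(t[-1] - t[0])
    if span <= 0 or np.ptp(r) == 0:
        return failed

    x0 = np.array([float(r.max()), float(r.min()), float(t[0] + span / 2), span / 8])
    lo = [-np.inf, -np.inf, float(t[0]) - span, 1e-9]
    hi = [np.inf, np.inf, float(t[-1]) + span, np.inf]
    rng = np.random.default_rng(seed)

    def residuals(p: np.ndarray) -> np.ndarray:
        return _sigmoid(t, *p) - r

    best = None
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.5, 1.5, size=4)
        start = np.clip(start, lo, hi)
        try:
            res = optimize.least_squares(residuals, start, bounds=(lo, hi))
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        return failed
    (r_high, r_low, t_inflect, tau), rss = best
    converged = (
        bool(t[0] <= t_inflect <= t[-1]) and r_high > r_low and tau > 0
    )
    if not converged:
        return failed
    return SigmoidFit(
        r_high=float(r_high),
        r_low=float(r_low),
        t_inflect=float(t_inflect),
        tau=float(tau),
        converged=True,
        rss=rss,
    )


def exponential_phase_rates(
    series: InstantRateSeries, fit: SigmoidFit, top_n: int = 3
) -> tuple[tuple[float, float], ...]:
    """Select the (time, rate) pairs belonging to exponential phase.

    With a converged sigmoid fit the exponential phase is the period strictly
    before the inflection point. Without one (or when no point precedes the
    inflection) the fallback keeps the ``top_n`` rates of largest absolute
    value, breaking ties on equal |rate| by earlier time.
    """
    if series.times.size == 0:
        raise EmptyInputError("empty rate series")
    pairs = list(zip(series.times.tolist(), series.median_rates.tolist()))
    if fit.converged:
        selected = [(t, r) for t, r in pairs if t < fit.t_inflect]
        if selected:
            return tuple(selected)
    # fallback: largest |rate| first, earlier time breaks ties
    ranked = sorted(pairs, key=lambda p: (-abs(p[1]), p[0]))
    chosen = ranked[: min(top_n, len(ranked))]
    return tuple(sorted(chosen))


def estimate_rate_series(curve: GrowthCurve, window_size: int = 3) -> InstantRateSeries:
    """Run windows -> nine candidates -> per-time medians for one curve."""
    candidates: list[CandidateRate] = []
    for w in compute_window_estimates(curve, window_size=window_size):
        candidates.extend(generate_candidates(w))
    return median_rate_series(candidates)


def summarize_condition(
    curves: Sequence[GrowthCurve],
    growth_rate_floor: float = 0.1,
    fold_floor: float = 4.0,
    window_size: int = 3,
) -> ConditionSummary:
    """Pool exponential-phase rates across replicates of one condition.

    The representative rate is the median of the pooled exponential-phase
    rates; dispersion is their sample standard deviation (0 for a single
    value); the range is also reported since published "+/-" conventions
    vary. A condition is called growth-positive when the representative rate
    reaches ``growth_rate_floor`` AND at least one replicate achieved a
    ``fold_floor``-fold density increase.
    """
    if len(curves) == 0:
        raise EmptyInputError("need at least one replicate curve")
    pooled: list[tuple[float, float]] = []
    for curve in curves:
        series = estimate_rate_series(curve, window_size=window_size)
        fit = fit_sigmoid_decay(series)
        pooled.extend(exponential_phase_rates(series, fit))
    rates = np.array([r for _, r in pooled])
    representative = float(np.median(rates))
    dispersion = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    max_fold = max(c.fold_increase for c in curves)
    growth_call = (representative >= growth_rate_floor) and (max_fold >= fold_floor)
    return ConditionSummary(
        condition=dict(curves[0].condition),
        exp_phase_rates=tuple(pooled),
        representative_rate=representative,
        mean_rate=float(np.mean(rates)),
        rate_dispersion=dispersion,
        rate_range=(float(rates.min()), float(rates.max())),
        max_density=float(max(c.densities.max() for c in curves)),
        fold_increase=float(max_fold),
        growth_call=growth_call,
        n_replicates=len(curves),
    )


def growth_envelope(
    summaries: Sequence[ConditionSummary], variable: str
) -> GrowthEnvelope:
    """Order condition summaries along one variable and find the envelope.

    The permissive range is the (min, max) of variable values with a
    positive growth call; with no growth-positive condition the envelope is
    flagged empty (max_rate is NaN) rather than raising.
    """
    if len(summaries) == 0:
        raise EmptyInputError("no condition summaries")
    for s in summaries:
        if variable not in s.condition:
            raise KeyError(f"condition variable {variable!r} missing from a summary")
    ordered = tuple(sorted(summaries, key=lambda s: s.condition[variable]))
    positive = [s for s in ordered if s.growth_call]
    negative_values = tuple(
        float(s.condition[variable]) for s in ordered if not s.growth_call
    )
    if not positive:
        return GrowthEnvelope(
            variable=variable,
            summaries=ordered,
            max_rate=float("nan"),
            max_rate_condition=None,
            permissive_range=None,
            non_permissive_values=negative_values,
        )
    best = max(positive, key=lambda s: s.representative_rate)
    values = [float(s.condition[variable]) for s in positive]
    return GrowthEnvelope(
        variable=variable,
        summaries=ordered,
        max_rate=float(best.representative_rate),
        max_rate_condition=dict(best.condition),
        permissive_range=(min(values), max(values)),
        non_permissive_values=negative_values,
    )
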