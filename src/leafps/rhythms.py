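"""Diel leaf-movement rhythm analysis.

Inclination (or centroid-elevation) series are first baseline-detrended
with a centred moving average at least one expected period wide, then fit
by harmonic regression: for each candidate period T on a fine grid, a
linear least-squares fit of

    y(t) = c + sum_{k=1..K} a_k cos(2*pi*k*t/T) + b_k sin(2*pi*k*t/T)

is evaluated and the period minimizing the residual sum of squares is
refined locally.  The reported amplitude is that of the fundamental,
sqrt(a_1^2 + b_1^2) (half the fitted peak-to-trough); the phase is the
time of the fundamental's peak after dusk, modulo the period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import ConfigurationError
from .schedule import LightSchedule

FLAT_VARIANCE_TOL = 1e-10


@dataclass
class MovementSeries:
    """Uniformly sampled movement series: times in hours, values in
    degrees (or mm), with an optional light schedule for phasing."""

    times: np.ndarray
    values: np.ndarray
    schedule: LightSchedule | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size < 2:
            raise ConfigurationError("times and values must align, length >= 2")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ConfigurationError("sampling must be uniform and increasing")
        self.times = t
        self.values = v

    @property
    def interval_h(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def span_h(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class RhythmResult:
    """Fitted rhythm parameters.

    period in hours; phase = hours after dusk of the fitted fundamental
    peak, on [0, period); amplitude = half peak-to-trough of the
    fundamental, in the units of the input; goodness = residual variance
    fraction (0 = perfect fit).  Arrhythmic series (variance below
    tolerance) report amplitude 0 and NaN period/phase.
    """

    period_h: float
    phase_h: float
    amplitude: float
    goodness: float
    arrhythmic: bool = False


def detrend_series(s: MovementSeries, baseline_window_h: float = 24.0) -> MovementSeries:
    """Subtract a centred moving-average baseline and align the mean to 0.

    The window (default 24 h) should be at least one expected period so
    the oscillation itself is not removed; edge baselines use shrinking
    windows.
    """
    # n samples span the window: for a window equal to one period of a
    # sampled oscillation the average then cancels it exactly
    n = max(1, int(round(baseline_window_h / s.interval_h)))
    if n > s.times.size:
        raise ConfigurationError("series shorter than the baseline window")
    kernel = np.ones(n)
    baseline = np.convolve(s.values, kernel, mode="same") / np.convolve(
        np.ones_like(s.values), kernel, mode="same"
    )
    out = s.values - baseline
    out = out - out.mean()
    return replace(s, values=out)


def _harmonic_design(t: np.ndarray, period: float, n_harmonics: int) -> np.ndarray:
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        w = 2 * np.pi * k / period
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.column_stack(cols)


def _rss(t: np.ndarray, y: np.ndarray, period: float, n_harmonics: int) -> float:
    X = _harmonic_design(t, period, n_harmonics)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def fit_rhythm(
    s: MovementSeries,
    period_range: tuple[float, float] = (18.0, 34.0),
    n_harmonics: int = 3,
    grid_step_h: float = 0.05,
    phase_reference: str = "dusk",
) -> RhythmResult:
    """Estimate period, phase and amplitude by a harmonic-regression scan.

    Periods are scanned on a ``grid_step_h`` grid over ``period_range``
    and the best is refined to sub-grid precision.  ``phase_reference``
    is ``'dusk'`` (default; lights-off from the series' schedule, or t=0
    when no schedule is attached) or ``'dawn'``.
    """
    t = s.times - s.times[0]
    y = s.values
    if float(np.var(y)) < FLAT_VARIANCE_TOL:
        return RhythmResult(float("nan"), float("nan"), 0.0, 1.0, arrhythmic=True)
    lo, hi = period_range
    if not 0 < lo < hi:
        raise ConfigurationError("invalid period range")
    if s.span_h < 2 * lo:
        raise ConfigurationError("need at least 2 full cycles of data")
    grid = np.arange(lo, hi + grid_step_h / 2, grid_step_h)
    rss = np.array([_rss(t, y, T, n_harmonics) for T in grid])
    i = int(np.argmin(rss))
    bl = grid[max(i - 1, 0)]
    bu = grid[min(i + 1, grid.size - 1)]
    if bu > bl:
        res = minimize_scalar(
            lambda T: _rss(t, y, T, n_harmonics),
            bounds=(bl, bu),
            method="bounded",
            options={"xatol": 1e-9},
        )
        period = float(res.x)
    else:
        period = float(grid[i])

    X = _harmonic_design(t, period, n_harmonics)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    goodness = float(resid @ resid) / tss if tss > 0 else 0.0
    a1, b1 = beta[1], beta[2]
    amplitude = float(np.hypot(a1, b1))
    # fundamental peak: a1 cos(wt) + b1 sin(wt) = A cos(w (t - t_peak))
    t_peak = period * np.arctan2(b1, a1) / (2 * np.pi)
    if phase_reference == "dusk":
        ref = s.schedule.first_dusk_h() - s.times[0] if s.schedule else 0.0
    elif phase_reference == "dawn":
        ref = s.schedule.dawn_h - s.times[0] if s.schedule else 0.0
    else:
        raise ConfigurationError("phase_reference must be 'dusk' or 'dawn'")
    phase = float(np.mod(t_peak - ref, period))
    return RhythmResult(period, phase, amplitude, goodness)


def predict(result: RhythmResult, s: MovementSeries, n_harmonics: int = 3) -> np.ndarray:
    """Model prediction at the series' own time points (refits the linear
    coefficients at the fitted period)."""
    if result.arrhythmic:
        return np.full_like(s.values, s.values.mean())
    t = s.times - s.times[0]
    X = _harmonic_design(t, result.period_h, n_harmonics)
    beta, *_ = np.linalg.lstsq(X, s.values, rcond=None)
    return X @ beta
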