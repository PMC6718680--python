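"""Summary statistics of the segmented EEG.

Sliding-window state proportions, first-occurrence times, the initial
slope ``a`` of the alpha-suppression proportion, event-duration series,
occurrence frequency ``F_alpha``, per-event average amplitudes ``A_alpha``
and ``A_IaS``, induction slopes, the exponential-saturation fit of
``F_alpha``, and baseline spectral comparators (delta power, alpha-to-
delta ratio).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit
from scipy.signal import welch

from .intervals import IntervalSet
from .segmentation import Segmentation

__all__ = [
    "ProportionSeries",
    "EventSeries",
    "TimeSeries",
    "sliding_proportions",
    "first_occurrence_time",
    "initial_slope",
    "duration_series",
    "group_average_series",
    "occurrence_frequency",
    "event_amplitude_series",
    "linear_slope_fit",
    "exp_saturation_fit",
    "baseline_band_features",
]

logger = logging.getLogger(__name__)


@dataclass
class TimeSeries:
    """(time, value) pairs on a regular or event-driven grid."""

    times: np.ndarray  # s
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class EventSeries(TimeSeries):
    """Per-event series (durations in s, or amplitudes in uV) at event times."""


@dataclass
class ProportionSeries:
    """Sliding-window percentages of time in each state; they sum to 100."""

    times: np.ndarray
    p_alpha: np.ndarray
    p_ies: np.ndarray
    p_hyp: np.ndarray
    window: float = 240.0


def sliding_proportions(
    seg: Segmentation, window: float = 240.0, step: float = 1.0
) -> ProportionSeries:
    """State proportions over a backward-looking window ``[t - window, t]``.

    The window is truncated at the span start; proportions divide by the
    effective window length, so the three states always sum to 100%.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    a0, b0 = seg.span
    times = np.arange(a0 + step, b0 + step / 2.0, step)
    lo = np.maximum(times - window, a0)
    eff = times - lo

    def coverage(iv: IntervalSet) -> np.ndarray:
        if len(iv) == 0:
            return np.zeros_like(times)
        # cumulative covered time C(t); overlap of [lo, t] = C(t) - C(lo)
        knots = np.concatenate([[a0], np.column_stack([iv.starts, iv.ends]).ravel(), [b0]])
        knots = np.clip(knots, a0, b0)
        cum = np.zeros_like(knots)
        total = 0.0
        for k, (s, e) in enumerate(iv):
            cum[2 * k + 1] = total
            total += e - s
            cum[2 * k + 2] = total
        cum[-1] = total
        return np.interp(times, knots, cum) - np.interp(lo, knots, cum)

    cov_a = coverage(seg.consensus_aS)
    cov_i = coverage(seg.ies)
    p_alpha = 100.0 * cov_a / eff
    p_ies = 100.0 * cov_i / eff
    return ProportionSeries(
        times=times,
        p_alpha=p_alpha,
        p_ies=p_ies,
        p_hyp=100.0 - p_alpha - p_ies,
        window=window,
    )


def first_occurrence_time(
    times: np.ndarray, proportion: np.ndarray, threshold: float = 5.0
) -> float | None:
    """Earliest evaluation instant with proportion >= threshold, else None."""
    hits = np.nonzero(np.asarray(proportion) >= threshold)[0]
    return float(np.asarray(times)[hits[0]]) if hits.size else None


def initial_slope(
    times: np.ndarray, p_alpha: np.ndarray, fit_span_min: float = 10.0
) -> float:
    """Through-origin slope ``a`` of ``P_alpha`` (% per minute).

    Least-squares fit of ``y = a t`` over the first ``fit_span_min``
    minutes, with ``t`` in minutes.
    """
    t_min = np.asarray(times, dtype=float) / 60.0
    y = np.asarray(p_alpha, dtype=float)
    sel = t_min <= fit_span_min + 1e-12
    t_min, y = t_min[sel], y[sel]
    if t_min.size < 2:
        raise ValueError("need at least two points inside the fit span")
    denom = float(np.sum(t_min**2))
    return float(np.sum(t_min * y) / denom) if denom > 0 else 0.0


def duration_series(seg: Segmentation) -> EventSeries:
    """Consensus alpha-suppression durations, anchored at event starts."""
    iv = seg.consensus_aS
    return EventSeries(times=iv.starts.copy(), values=iv.durations.copy())


def group_average_series(
    collection: list[EventSeries | TimeSeries], grid_step: float = 1.0,
    t_max: float | None = None, min_patients: int = 3,
) -> TimeSeries:
    """Group mean of per-patient series, linearly interpolated on a grid.

    Each patient's event-driven series is interpolated onto a common 1-s
    grid. Interpolation is only defined between a patient's first and
    last event, so outside that range the patient does not contribute;
    grid points supported by fewer than ``min_patients`` contributing
    patients are dropped (a handful of patients is not a group average).
    Patients with no events at all are excluded with a warning.
    """
    usable = [s for s in collection if s.times.size > 0]
    if len(usable) < len(collection):
        logger.warning(
            "%d patient(s) with no events excluded from the group average",
            len(collection) - len(usable),
        )
    if not usable:
        raise ValueError("no patient has any event")
    if t_max is None:
        t_max = max(float(s.times[-1]) for s in usable)
    grid = np.arange(0.0, t_max + grid_step / 2.0, grid_step)
    stack = np.vstack([np.interp(grid, s.times, s.values) for s in usable])
    defined = np.vstack(
        [(grid >= s.times[0]) & (grid <= s.times[-1]) for s in usable]
    )
    counts = defined.sum(axis=0)
    keep = counts >= min(min_patients, len(usable))
    values = np.where(defined, stack, 0.0).sum(axis=0)[keep] / counts[keep]
    return TimeSeries(times=grid[keep], values=values)


def occurrence_frequency(
    seg: Segmentation,
    w_f: float = 50.0,
    step: float = 10.0,
    anchor: str = "start",
) -> TimeSeries:
    """Alpha-suppression occurrence frequency ``F_alpha`` in events/min.

    Counts distinct consensus events whose anchor time (start by default,
    midpoint selectable) lies in the centered window
    ``[t - w_f/2, t + w_f/2)``, divided by the window width in minutes.
    """
    if w_f <= 0 or step <= 0:
        raise ValueError("w_f and step must be positive")
    iv = seg.consensus_aS
    anchors = iv.starts if anchor == "start" else (iv.starts + iv.ends) / 2.0
    times = np.arange(seg.span[0], seg.span[1] + step / 2.0, step)
    lo = np.searchsorted(anchors, times - w_f / 2.0, side="left")
    hi = np.searchsorted(anchors, times + w_f / 2.0, side="left")
    return TimeSeries(times=times, values=(hi - lo) / (w_f / 60.0))


def event_amplitude_series(
    s_alpha_mag: np.ndarray, fs: float, intervals: IntervalSet
) -> EventSeries:
    """Average of ``|S_alpha|`` over each event: ``A = (1/|T|) int |S_alpha|``.

    ``s_alpha_mag`` is the rectified alpha-band signal (one channel, or a
    cross-channel average of rectified channels). The integral treats the
    samples as piecewise linear and handles fractional endpoints exactly.
    """
    y = np.asarray(s_alpha_mag, dtype=float)
    n = y.size
    dt = 1.0 / fs
    cum = np.concatenate([[0.0], cumulative_trapezoid(y, dx=dt)])

    def integral_to(t: float) -> float:
        # exact integral of the piecewise-linear interpolant on [0, t]
        t = min(max(t, 0.0), (n - 1) * dt)
        i = min(int(t / dt), n - 2)
        frac = t - i * dt
        y_t = y[i] + (y[i + 1] - y[i]) * (frac / dt)
        return float(cum[i] + 0.5 * (y[i] + y_t) * frac)

    times, values = [], []
    for s, e in intervals:
        if e <= s:
            raise ValueError("zero-length event interval")
        area = integral_to(e) - integral_to(s)
        times.append(s)
        values.append(area / (e - s))
    return EventSeries(times=np.asarray(times), values=np.asarray(values))


def linear_slope_fit(
    series: TimeSeries, fit_span_min: float = 10.0
) -> tuple[float, float]:
    """OLS slope and intercept over the first ``fit_span_min`` minutes.

    Times are converted to minutes, so the slope is per minute.
    """
    t_min = series.times / 60.0
    sel = t_min <= fit_span_min + 1e-12
    t, y = t_min[sel], series.values[sel]
    if t.size < 2:
        raise ValueError("need at least two points inside the fit span")
    if np.ptp(t) == 0:
        return 0.0, float(np.mean(y))
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope), float(intercept)


def exp_saturation_fit(series: TimeSeries) -> tuple[float, float, float]:
    """Fit ``y(t) = F_max (1 - exp(-t / tau))`` with ``t`` in minutes.

    Multi-start nonlinear least squares; returns ``(F_max, tau, R^2)``.
    A constant series is degenerate: the plateau is the constant and
    ``tau`` collapses to the lower bound.
    """
    t = series.times / 60.0
    y = series.values
    if t.size < 4:
        raise ValueError("need at least four points")
    y_scale = float(np.max(np.abs(y)))
    if y_scale == 0:
        return 0.0, 1e-3, 1.0
    if np.ptp(y) < 1e-12 * y_scale:
        return float(y[0]), 1e-3, 1.0

    def model(tt, f_max, tau):
        return f_max * (1.0 - np.exp(-tt / tau))

    best = None
    for tau0 in (0.2, 0.5, 1.0, 2.0, 5.0, 10.0):
        try:
            popt, _ = curve_fit(
                model, t, y, p0=[max(y.max(), 1e-6), tau0],
                bounds=([0.0, 1e-4], [np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError:
            continue
        resid = y - model(t, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("exponential-saturation fit did not converge")
    sse, (f_max, tau) = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return float(f_max), float(tau), r2


def baseline_band_features(
    rec, induction_span: tuple[float, float]
) -> tuple[float, float]:
    """Welch delta power and alpha-to-delta power ratio over induction.

    Delta is integrated over [0.5, 5] Hz and alpha over [8, 14] Hz on the
    Fp1/Fp2 average; the span must cover at least 60 s.
    """
    a, b = induction_span
    if b - a < 60.0:
        raise ValueError("induction span must cover at least 60 s")
    i0, i1 = int(a * rec.fs), int(b * rec.fs)
    x = (rec.channel("Fp1") + rec.channel("Fp2"))[i0:i1] / 2.0
    nperseg = min(int(4 * rec.fs), x.size)
    f, pxx = welch(x, fs=rec.fs, nperseg=nperseg)

    def band_power(f_lo: float, f_hi: float) -> float:
        sel = (f >= f_lo) & (f <= f_hi)
        return float(np.trapezoid(pxx[sel], f[sel]))

    delta = band_power(0.5, 5.0)
    alpha = band_power(8.0, 14.0)
    return delta, alpha / delta if delta > 0 else np.inf
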