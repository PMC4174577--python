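"""Trace-level statistics: cross-/autocorrelation, FWHM, noise variance, mEPSC detection.

The central quantity is the normalized cross-correlation function between two
simultaneously recorded current traces: the shared variance at each lag over
the geometric mean of the two traces' variances.  Its value at zero lag is
the Pearson correlation of the two sample vectors, and its peak (``CC_peak``)
is what the connectivity model converts into a cross-synaptic synchrony
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .trace import Trace


@dataclass
class CorrelationResult:
    """A normalized correlation function.

    ``values[i]`` is the correlation at ``lags[i]`` (ms).  A positive peak
    lag means the *first* trace is delayed relative to the second.
    """

    lags: np.ndarray
    values: np.ndarray
    peak: float
    peak_lag: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ms": self.lags, "correlation": self.values})


@dataclass
class EventList:
    """Detected synaptic events.

    ``times`` are event onset times (ms, strictly increasing); ``amplitudes``
    are peak deviations from baseline (pA, negative for inward events);
    ``rise_times`` are 10-90% rise times (ms).  ``is_mepsc`` marks events
    that satisfy the rise-time criterion; slower events are kept but flagged.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    rise_times: np.ndarray
    is_mepsc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.rise_times = np.asarray(self.rise_times, dtype=float)
        if self.is_mepsc is None:
            self.is_mepsc = np.ones(self.times.size, dtype=bool)
        self.is_mepsc = np.asarray(self.is_mepsc, dtype=bool)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.rise_times <= 0):
            raise ValueError("rise times must be positive")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times,
                "amplitude_pA": self.amplitudes,
                "rise_ms": self.rise_times,
                "is_mepsc": self.is_mepsc,
            }
        )


def _check_pair(a: Trace, b: Trace, max_lag: float) -> None:
    if abs(a.dt - b.dt) > 1e-12:
        raise ValueError(f"sample intervals differ: {a.dt} vs {b.dt} ms")
    if a.n != b.n:
        raise ValueError(f"trace lengths differ: {a.n} vs {b.n} samples")
    if not 0 < max_lag < a.duration_ms:
        raise ValueError(
            f"max_lag must lie in (0, {a.duration_ms}) ms, got {max_lag}"
        )


def _norm_xcorr(x: np.ndarray, y: np.ndarray, n_lag: int) -> np.ndarray:
    """values[tau] = sum_t x[t + tau] y[t] / (n * sd_x * sd_y), tau in [-n_lag, n_lag]."""
    n = x.size
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt(np.mean(x * x))
    sy = np.sqrt(np.mean(y * y))
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance trace: correlation undefined")
    full = signal.correlate(x, y, mode="full", method="fft")
    centre = n - 1
    vals = full[centre - n_lag : centre + n_lag + 1] / (n * sx * sy)
    # clip FFT round-off so the Cauchy-Schwarz bound holds exactly
    return np.clip(vals, -1.0, 1.0)


def cross_correlation(
    a: Trace,
    b: Trace,
    max_lag: float = 200.0,
    epoch: float | None = None,
) -> CorrelationResult:
    """Normalized cross-correlation of two equally sampled traces.

    Both traces are mean-subtracted; each lag is normalized by the geometric
    mean of the two full-trace variances, so the zero-lag value equals the
    Pearson correlation of the sample vectors and all values lie in [-1, 1].

    Parameters
    ----------
    max_lag : float
        Largest lag magnitude, ms.
    epoch : float, optional
        When given, the record is cut into consecutive epochs of this length
        (ms), a correlation function is computed per epoch, and the epoch
        functions are averaged.  Useful for long records with slow drift.
    """
    _check_pair(a, b, max_lag)
    n_lag = int(round(max_lag / a.dt))
    lags = np.arange(-n_lag, n_lag + 1) * a.dt
    if epoch is None:
        vals = _norm_xcorr(a.samples, b.samples, n_lag)
    else:
        ne = int(round(epoch / a.dt))
        if ne <= n_lag:
            raise ValueError("epoch must be longer than max_lag")
        m = a.n // ne
        if m < 1:
            raise ValueError("record shorter than one epoch")
        acc = np.zeros(2 * n_lag + 1)
        for k in range(m):
            sl = slice(k * ne, (k + 1) * ne)
            acc += _norm_xcorr(a.samples[sl], b.samples[sl], n_lag)
        vals = acc / m
    i = int(np.argmax(vals))
    return CorrelationResult(lags=lags, values=vals, peak=float(vals[i]),
                             peak_lag=float(lags[i]))


def autocorrelation(a: Trace, max_lag: float = 200.0,
                    epoch: float | None = None) -> CorrelationResult:
    """Normalized autocorrelation; value at lag 0 is exactly 1."""
    res = cross_correlation(a, a, max_lag=max_lag, epoch=epoch)
    res.values[res.lags == 0.0] = 1.0
    i = int(np.argmax(res.values))
    res.peak = float(res.values[i])
    res.peak_lag = float(res.lags[i])
    return res


def fwhm(acf: CorrelationResult) -> float:
    """Full width at half maximum of a correlation function peaked at lag 0.

    Crossing points of the half-maximum level are located by linear
    interpolation between lag samples.  Raises if the function never falls
    below half maximum on either side within the available lags.
    """
    i0 = int(np.argmin(np.abs(acf.lags)))
    peak = acf.values[i0]
    if np.max(acf.values) > peak + 1e-9:
        raise ValueError("correlation function does not peak at lag 0")
    half = peak / 2.0

    def _cross(idx_range) -> float:
        prev = i0
        for j in idx_range:
            if acf.values[j] < half:
                # interpolate between prev (>= half) and j (< half)
                x0, x1 = acf.lags[prev], acf.lags[j]
                y0, y1 = acf.values[prev], acf.values[j]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = j
        raise ValueError("correlation never crosses half maximum within max_lag")

    right = _cross(range(i0 + 1, acf.values.size))
    left = _cross(range(i0 - 1, -1, -1))
    return float(right - left)


def noise_variance(a: Trace, detrend_window: float = 0.0) -> float:
    """Variance (pA²) of a trace about a running-average baseline.

    ``detrend_window`` is the baseline window in ms; 0 means plain mean
    subtraction.  Invariant to constant offsets by construction.
    """
    if detrend_window < 0:
        raise ValueError("detrend_window must be non-negative")
    x = a.samples
    if detrend_window == 0:
        return float(np.var(x))
    size = max(1, int(round(detrend_window / a.dt)))
    baseline = ndimage.uniform_filter1d(x, size=size, mode="nearest")
    return float(np.var(x - baseline))


def _walk_back_crossing(y: np.ndarray, start: int, level: float, floor: int) -> float:
    """Fractional sample position of the last upward crossing of ``level``
    at or before ``start`` (``y`` negative-going; ``level`` negative)."""
    j = start
    while j > floor and y[j] <= level:
        j -= 1
    if y[j] <= level:  # never rose above level within the lookback
        return float(j)
    if j == start:
        return float(j)
    y0, y1 = y[j], y[j + 1]
    frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    return float(j) + min(max(frac, 0.0), 1.0)


def detect_mepscs(
    a: Trace,
    threshold: float = -2.0,
    max_rise: float = 1.0,
    baseline_window: float = 100.0,
    smooth: float = 0.2,
    min_width: float = 0.3,
    merge_gap: float = 1.0,
) -> EventList:
    """Detect inward miniature-EPSC-like events in a current trace.

    The trace is detrended with a running-median baseline (robust to the
    fluctuating baselines that defeat naive thresholding), lightly smoothed,
    and scanned for contiguous excursions below ``threshold`` lasting at
    least ``min_width`` ms.  For each excursion the event peak is the most
    negative detrended sample, the onset is the preceding baseline (zero)
    crossing, and the 10-90% rise time is interpolated between onset and
    peak.  Events slower than ``max_rise`` are reported but flagged as
    non-mEPSC.

    Parameters
    ----------
    threshold : float
        Detection threshold in pA; must be negative (inward events).
    max_rise : float
        Largest 10-90% rise time (ms) accepted as an mEPSC.
    baseline_window : float
        Running-median window, ms.
    smooth : float
        Gaussian smoothing sigma, ms, applied before threshold crossing.
    min_width : float
        Minimum time (ms) an excursion must stay below threshold.
    merge_gap : float
        Excursions separated by less than this gap (ms) are treated as one
        event (noise briefly re-crossing the threshold during a decay).
    """
    if threshold >= 0:
        raise ValueError("threshold must be negative (inward events)")
    if max_rise <= 0:
        raise ValueError("max_rise must be positive")
    dt = a.dt
    w = max(1, int(round(baseline_window / dt)))
    baseline = (
        pd.Series(a.samples).rolling(w, center=True, min_periods=1).median().to_numpy()
    )
    x = a.samples - baseline
    xs = ndimage.gaussian_filter1d(x, sigma=max(smooth / dt, 1e-9))

    below = xs <= threshold
    if not below.any():
        return EventList(np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    idx = np.flatnonzero(below)
    run_starts = idx[np.r_[True, np.diff(idx) > 1]]
    run_ends = idx[np.r_[np.diff(idx) > 1, True]]
    # merge runs separated by brief re-crossings (noise riding on one event)
    gap = max(1, int(round(merge_gap / dt)))
    merged_starts, merged_ends = [run_starts[0]], [run_ends[0]]
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - merged_ends[-1] <= gap:
            merged_ends[-1] = e
        else:
            merged_starts.append(s)
            merged_ends.append(e)
    run_starts, run_ends = np.asarray(merged_starts), np.asarray(merged_ends)

    min_samples = max(1, int(round(min_width / dt)))
    times, amps, rises, flags = [], [], [], []
    for s, e in zip(run_starts, run_ends):
        if e - s + 1 < min_samples:
            continue
        peak_i = s + int(np.argmin(xs[s : e + 1]))
        amp_s = float(xs[peak_i])  # smoothed amplitude sets the 10/90% levels
        floor = max(0, peak_i - int(round(20.0 / dt)))
        p90 = _walk_back_crossing(xs, peak_i, 0.9 * amp_s, floor)
        p10 = _walk_back_crossing(xs, int(p90), 0.1 * amp_s, floor)
        rise = max((p90 - p10) * dt, dt * 1e-3)
        times.append(p10 * dt)  # onset = 10% crossing
        amps.append(float(x[peak_i]))
        rises.append(rise)
        flags.append(rise <= max_rise)

    order = np.argsort(times)
    times = np.asarray(times)[order]
    keep = np.r_[True, np.diff(times) > 0]  # drop duplicate onsets
    return EventList(
        times[keep],
        np.asarray(amps)[order][keep],
        np.asarray(rises)[order][keep],
        np.asarray(flags, dtype=bool)[order][keep],
    )
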