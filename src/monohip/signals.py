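"""Time-series plumbing: zero-phase low-pass filtering, cross-correlation
synchronization with linear drift correction, gait-cycle segmentation and
100-point time normalization.

All operations work on :class:`TimeSeries`, a thin container for uniformly
sampled scalar or tri-axial signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

N_POINTS = 100


@dataclass
class TimeSeries:
    """Uniformly sampled signal: time stamps (s), values, sampling rate (Hz).

    `values` is a 1-D vector or an (N, k) matrix (e.g. a tri-axial stream).
    """

    t: np.ndarray
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.t) != len(self.values):
            raise ValueError("t and values must have the same length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) > 1e-6):
                raise ValueError("time stamps must be uniformly spaced at fs")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    def column(self, i: int) -> np.ndarray:
        return self.values if self.values.ndim == 1 else self.values[:, i]


@dataclass
class FilterSpec:
    """Zero-phase FIR low-pass specification.

    The default order honors the printed "2nd-order, 3.2 Hz" description of
    the reference pre-processing chain; at 128 Hz such a short FIR barely
    attenuates, so a practical order around 50 taps is recommended (the
    processing pipeline uses 50).
    """

    order: int = 2
    cutoff: float = 3.2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def taps(self, fs: float) -> np.ndarray:
        if not self.cutoff < fs / 2:
            raise ValueError("cutoff must be below the Nyquist frequency")
        return sps.firwin(self.order + 1, self.cutoff, window="hamming",
                          fs=fs)


@dataclass
class SyncModel:
    """Linear clock-drift model: delay(t) = offset + slope * t."""

    offset: float
    slope: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.offset) and np.isfinite(self.slope)):
            raise ValueError("offset and slope must be finite")

    def delay_at(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.offset + self.slope * np.asarray(t, dtype=float)

    def apply(self, t: np.ndarray | float) -> np.ndarray | float:
        """Map a lagging clock back onto the reference clock."""
        return np.asarray(t, dtype=float) - self.delay_at(t)


def lowpass_zero_phase(ts: TimeSeries, spec: FilterSpec | None = None
                       ) -> TimeSeries:
    """Forward-backward FIR low-pass: zero phase lag, unit DC gain.

    Edges are handled by reflect-padding one filter length, which avoids
    startup transients inside short gait trials.
    """
    spec = spec or FilterSpec()
    b = spec.taps(ts.fs)
    ntaps = len(b)
    if len(ts) <= 3 * ntaps:
        raise ValueError(
            f"signal ({len(ts)} samples) must be longer than 3x the filter "
            f"length ({ntaps} taps)")
    if spec.zero_phase:
        out = sps.filtfilt(b, [1.0], ts.values, axis=0, padtype="even",
                           padlen=ntaps)
    else:
        out = sps.lfilter(b, [1.0], ts.values, axis=0)
    return TimeSeries(ts.t, out, ts.fs)


def estimate_delay(ref: TimeSeries, test: TimeSeries) -> float:
    """Delay of `test` relative to `ref` by normalized cross-correlation.

    Positive result means `test` lags `ref`. Both signals are linearly
    resampled to the faster of the two rates before correlating; the
    correlation is Pearson-type (mean-removed, unit-variance) and ties
    between equal peaks are broken toward the smallest absolute delay.
    """
    if min(ref.duration, test.duration) < 2.0:
        raise ValueError("signals must overlap for at least 2 s")
    fs = max(ref.fs, test.fs)

    def _resample(ts: TimeSeries) -> np.ndarray:
        x = ts.values if ts.values.ndim == 1 else np.linalg.norm(
            ts.values, axis=1)
        if np.isclose(ts.fs, fs):
            return x.astype(float)
        n = int(np.floor(ts.duration * fs)) + 1
        tt = ts.t[0] + np.arange(n) / fs
        return np.interp(tt, ts.t, x)

    a = _resample(ref)
    b = _resample(test)
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = np.std(a), np.std(b)
    if sa < 1e-12 or sb < 1e-12:
        raise ValueError("cannot correlate a flat (zero-variance) signal")
    c = sps.correlate(b, a, mode="full") / (sa * sb * min(len(a), len(b)))
    lags = sps.correlation_lags(len(b), len(a), mode="full")
    peak = c.max()
    near = np.flatnonzero(c >= peak - 1e-12 * max(1.0, abs(peak)))
    k = near[np.argmin(np.abs(lags[near]))]
    return float(lags[k] / fs)


def fit_drift(delays: list[tuple[float, float]] | np.ndarray) -> SyncModel:
    """Ordinary least-squares line through (measurement time, delay) points."""
    pts = np.asarray(delays, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (t, delay) points")
    t, d = pts[:, 0], pts[:, 1]
    if np.ptp(t) < 1e-12:
        raise ValueError("time points must be distinct")
    slope, offset = np.polyfit(t, d, 1)
    return SyncModel(offset=float(offset), slope=float(slope))


def segment_cycles(ts: TimeSeries, events: np.ndarray) -> list[TimeSeries]:
    """Half-open slices [hs_i, hs_{i+1}) of a signal at heel-strike times.

    Consecutive slices partition the in-range samples: nothing lost,
    nothing duplicated.
    """
    ev = np.asarray(events, dtype=float)
    if len(ev) < 2:
        warnings.warn("fewer than 2 events: no cycles to segment",
                      stacklevel=2)
        return []
    if np.any(np.diff(ev) <= 0):
        raise ValueError("events must be strictly increasing")
    # the final event may mark the exclusive end boundary, one sample past
    # the last time stamp
    if ev[0] < ts.t[0] - 0.5 / ts.fs or ev[-1] > ts.t[-1] + 1.0 / ts.fs \
            + 1e-9:
        raise ValueError("events must lie inside the signal time span")
    idx = np.searchsorted(ts.t, ev, side="left")
    out = []
    for i0, i1 in zip(idx[:-1], idx[1:]):
        out.append(TimeSeries(ts.t[i0:i1], ts.values[i0:i1], ts.fs))
    return out


def time_normalize(cycle: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Linear interpolation of one gait cycle onto `n_points` equally spaced
    samples (endpoints preserved)."""
    x = np.asarray(cycle, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("cycle must contain at least 2 samples")
    src = np.arange(n, dtype=float)
    dst = np.linspace(0.0, n - 1.0, n_points)
    if x.ndim == 1:
        return np.interp(dst, src, x)
    return np.column_stack([np.interp(dst, src, x[:, j])
                            for j in range(x.shape[1])])
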