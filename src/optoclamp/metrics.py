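"""Quantitative readouts used to evaluate firing-rate control.

All metrics operate on plain spike-event lists (time, unit id) and sampled
traces, so they apply equally to simulated trials and to recorded logs read
from disk.  The suite covers:

* RMS tracking error between achieved and target rate over a window;
* settling time — first entry into a +/- band around the target of the
  LOWESS-smoothed rate (tri-cube weights, 2.5 s window by default) after
  which the smoothed rate never leaves the band;
* the pair-averaged cross-correlogram (5 ms bins by default), normalised by
  bin width and reference spike count to give a rate in Hz;
* the synchrony index  Sync_ij = N_cc / sqrt((N_i^2 + N_j^2) / 2)  where
  N_cc counts spike pairs within +/- 10 ms;
* CV_ISI, the coefficient of variation of the interspike-interval
  distribution (population SD by default; 1 for a Poisson process);
* the spike-triggered average of a stimulus signal and the full width at
  half maximum of such an average;
* threshold-based population-burst detection with onset-aligned profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

__all__ = [
    "SpikeEventList", "SettlingConfig", "CorrelogramConfig",
    "rms_tracking_error", "settling_time", "cross_correlogram",
    "synchrony_index", "cv_isi", "spike_triggered_average", "fwhm",
    "burst_profile",
]


@dataclass(frozen=True)
class SpikeEventList:
    """Timestamped (time, unit) events — the universal activity record."""

    times: np.ndarray
    units: np.ndarray
    t_start: float
    t_end: float
    n_units: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        units = np.asarray(self.units, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "units", units)
        if times.shape != units.shape:
            raise ValueError("times and units must have equal length")
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("spike times must be non-decreasing")
        if units.size and (units.min() < 0 or units.max() >= self.n_units):
            raise ValueError("unit ids out of range")

    def __len__(self) -> int:
        return self.times.size

    def unit_times(self, unit: int) -> np.ndarray:
        return self.times[self.units == unit]

    def population_rate(self, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
        """Binned population rate in Hz/unit: (bin centers, rates)."""
        edges = np.arange(self.t_start, self.t_end + bin_width, bin_width)
        counts, _ = np.histogram(self.times, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, counts / (self.n_units * bin_width)


@dataclass(frozen=True)
class SettlingConfig:
    """Settling-time definition: band around the target and LOWESS window."""

    band: float = 0.25          # Hz/unit
    lowess_window: float = 2.5  # s (tri-cube weights)

    def __post_init__(self) -> None:
        if self.band <= 0:
            raise ValueError("band must be positive")
        if self.lowess_window <= 0:
            raise ValueError("lowess_window must be positive")


@dataclass(frozen=True)
class CorrelogramConfig:
    bin: float = 0.005
    max_lag: float = 0.5
    sync_window: float = 0.010

    def __post_init__(self) -> None:
        if self.bin <= 0:
            raise ValueError("bin must be positive")
        if self.sync_window < self.bin:
            raise ValueError("sync_window must be >= bin")


def rms_tracking_error(
    times: np.ndarray,
    f: np.ndarray,
    target: np.ndarray | float,
    window: tuple[float, float],
) -> float:
    """Root-mean-square of (f - target) over [t0, t1]."""
    times = np.asarray(times, float)
    f = np.asarray(f, float)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t1 > t0")
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise ValueError("window contains no samples")
    target = np.broadcast_to(np.asarray(target, float), f.shape)
    err = f[mask] - target[mask]
    return float(np.sqrt(np.mean(err ** 2)))


def settling_time(
    times: np.ndarray,
    f: np.ndarray,
    target: float,
    cfg: SettlingConfig = SettlingConfig(),
    onset: float = 0.0,
) -> Optional[float]:
    """Time after ``onset`` at which the LOWESS-smoothed rate enters the band
    target +/- cfg.band and never leaves it again; None if it never settles."""
    times = np.asarray(times, float)
    f = np.asarray(f, float)
    if times.size == 0 or times[-1] <= onset:
        raise ValueError("trace must extend beyond the onset")
    span = times[-1] - times[0]
    frac = min(1.0, cfg.lowess_window / span) if span > 0 else 1.0
    smoothed = _lowess(f, times, frac=frac, it=0, delta=0.01 * span,
                       return_sorted=False)
    after = times >= onset
    inside = np.abs(smoothed[after] - target) <= cfg.band
    if not inside.all() and not inside.any():
        return None
    # last index at which the trace is outside the band
    outside_idx = np.flatnonzero(~inside)
    if outside_idx.size == 0:
        return 0.0
    first_settled = outside_idx[-1] + 1
    if first_settled >= inside.size:
        return None
    return float(times[after][first_settled] - onset)


def _pair_lag_counts(ref: np.ndarray, other: np.ndarray,
                     edges: np.ndarray) -> np.ndarray:
    """Histogram of (t_other - t_ref) lags for all pairs within the edge span."""
    counts = np.zeros(edges.size - 1, dtype=float)
    lo, hi = edges[0], edges[-1]
    left = np.searchsorted(other, ref + lo, side="left")
    right = np.searchsorted(other, ref + hi, side="right")
    for t, a, b in zip(ref, left, right):
        if b > a:
            counts += np.histogram(other[a:b] - t, bins=edges)[0]
    return counts


def cross_correlogram(
    spikes: SpikeEventList,
    cfg: CorrelogramConfig = CorrelogramConfig(),
    unit_pairs: Optional[Sequence[tuple[int, int]]] = None,
    normalize: str = "rate",
) -> tuple[np.ndarray, np.ndarray]:
    """Pair-averaged cross-correlogram.

    Returns (lag bin centers, values).  With ``normalize='rate'`` (default)
    each pair's lag histogram is divided by its reference spike count and the
    bin width, giving a conditional rate in Hz; ``'counts'`` returns raw
    pair-averaged counts.
    """
    if spikes.n_units < 2:
        raise ValueError("cross-correlogram needs at least 2 units")
    if normalize not in ("rate", "counts"):
        raise ValueError(f"unknown normalization {normalize!r}")
    n_bins = int(round(cfg.max_lag / cfg.bin))
    # symmetric bins with a zero-centred bin: centres -n*bin .. +n*bin
    edges = (np.arange(-n_bins, n_bins + 2) - 0.5) * cfg.bin
    centers = 0.5 * (edges[:-1] + edges[1:])
    if unit_pairs is None:
        unit_pairs = [(i, j) for i in range(spikes.n_units)
                      for j in range(spikes.n_units) if i != j]
    by_unit = {u: spikes.unit_times(u) for u in
               {u for pair in unit_pairs for u in pair}}
    acc = np.zeros_like(centers)
    n_used = 0
    for i, j in unit_pairs:
        ref, other = by_unit[i], by_unit[j]
        if ref.size == 0:
            continue
        counts = _pair_lag_counts(ref, other, edges)
        if normalize == "rate":
            counts /= ref.size * cfg.bin
        acc += counts
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable unit pairs (all reference trains empty)")
    return centers, acc / n_used


def synchrony_index(
    spikes_i: np.ndarray,
    spikes_j: np.ndarray,
    cfg: CorrelogramConfig = CorrelogramConfig(),
) -> float:
    """Sync_ij = N_cc / sqrt((N_i^2 + N_j^2) / 2) with N_cc the number of
    spike pairs within +/- cfg.sync_window; symmetric in its arguments."""
    ti = np.sort(np.asarray(spikes_i, float))
    tj = np.sort(np.asarray(spikes_j, float))
    if ti.size == 0 or tj.size == 0:
        raise ValueError("synchrony index requires two non-empty trains")
    left = np.searchsorted(tj, ti - cfg.sync_window, side="left")
    right = np.searchsorted(tj, ti + cfg.sync_window, side="right")
    n_cc = int(np.sum(right - left))
    denom = np.sqrt((ti.size ** 2 + tj.size ** 2) / 2.0)
    return n_cc / denom


def cv_isi(spike_times: np.ndarray, ddof: int = 0) -> float:
    """SD(ISI) / mean(ISI); population (biased) SD by default."""
    t = np.asarray(spike_times, float)
    if t.size < 3:
        raise ValueError("CV_ISI requires at least 3 spikes")
    isi = np.diff(t)
    mean = isi.mean()
    if mean <= 0:
        raise ValueError("degenerate ISI distribution (zero mean interval)")
    return float(isi.std(ddof=ddof) / mean)


def spike_triggered_average(
    spike_times: np.ndarray,
    signal: np.ndarray,
    sample_interval: float,
    window: tuple[float, float],
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of signal segments aligned to spike times.

    ``window = (t_pre, t_post)`` in seconds with t_pre <= 0 <= t_post; spikes
    whose window falls partly outside the trace are excluded.  Returns
    (lag axis, averaged segment).
    """
    t_pre, t_post = window
    if t_pre > 0 or t_post < 0 or t_post <= t_pre:
        raise ValueError("window must satisfy t_pre <= 0 <= t_post, t_post > t_pre")
    signal = np.asarray(signal, float)
    n_pre = int(round(-t_pre / sample_interval))
    n_post = int(round(t_post / sample_interval))
    idx = np.round((np.asarray(spike_times, float) - t0) / sample_interval).astype(int)
    ok = (idx - n_pre >= 0) & (idx + n_post < signal.size)
    idx = idx[ok]
    if idx.size == 0:
        raise ValueError("no spikes with a full window inside the trace")
    offsets = np.arange(-n_pre, n_post + 1)
    segments = signal[idx[:, None] + offsets[None, :]]
    return offsets * sample_interval, segments.mean(axis=0)


def fwhm(x: np.ndarray, y: np.ndarray,
         baseline_frac: float = 0.1) -> Optional[float]:
    """Full width at half maximum of a unimodal curve.

    The baseline is the mean of the first ``baseline_frac`` of the samples;
    half-max crossings are linearly interpolated.  Returns None (undefined)
    for flat curves or curves whose maximum does not rise above baseline.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("curve must have matching x/y with >= 3 samples")
    n_base = max(1, int(round(baseline_frac * y.size)))
    base = y[:n_base].mean()
    yc = y - base
    peak = yc.max()
    if peak <= 0 or np.ptp(y) == 0:
        return None
    i_peak = int(np.argmax(yc))
    half = 0.5 * peak

    def _cross(idx_range, reverse: bool) -> float:
        prev = i_peak
        for i in idx_range:
            if yc[i] < half:
                x0, x1 = x[i], x[prev]
                y0, y1 = yc[i], yc[prev]
                return x0 + (half - y0) / (y1 - y0) * (x1 - x0)
            prev = i
        return x[prev]  # never drops below half within the curve

    left = _cross(range(i_peak - 1, -1, -1), True)
    right = _cross(range(i_peak + 1, x.size), False)
    return float(right - left)


def burst_profile(
    spikes: SpikeEventList,
    threshold_rate: Optional[float] = None,
    min_gap: float = 0.1,
    bin_width: float = 0.025,
) -> tuple[list[tuple[float, float]], tuple[np.ndarray, np.ndarray]]:
    """Threshold-based population-burst detection.

    Bursts are maximal intervals where the binned population rate is at or
    above ``threshold_rate`` (default: 2x the median rate), merged when
    separated by gaps shorter than ``min_gap``.  Returns the (onset, offset)
    list and the onset-aligned average rate profile (lag axis, mean rate).
    """
    centers, rate = spikes.population_rate(bin_width)
    if threshold_rate is None:
        threshold_rate = 2.0 * float(np.median(rate))
    above = rate >= threshold_rate
    if threshold_rate <= 0:
        above = rate > 0
    bursts: list[tuple[float, float]] = []
    start = None
    for i, hi in enumerate(above):
        if hi and start is None:
            start = centers[i] - 0.5 * bin_width
        elif not hi and start is not None:
            bursts.append((start, centers[i - 1] + 0.5 * bin_width))
            start = None
    if start is not None:
        bursts.append((start, centers[-1] + 0.5 * bin_width))
    merged: list[tuple[float, float]] = []
    for b in bursts:
        if merged and b[0] - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)
    if not merged:
        return [], (np.array([]), np.array([]))
    span = max(b[1] - b[0] for b in merged)
    n = int(round(span / bin_width)) + 1
    lags = np.arange(n) * bin_width
    profiles = np.full((len(merged), n), np.nan)
    for k, (on, _) in enumerate(merged):
        i0 = int(np.searchsorted(centers, on))
        seg = rate[i0:i0 + n]
        profiles[k, : seg.size] = seg
    with np.errstate(invalid="ignore"):
        mean_profile = np.nanmean(profiles, axis=0)
    return merged, (lags, mean_profile)
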