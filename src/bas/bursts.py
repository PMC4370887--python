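"""Burst detection: background estimation and thresholded burst search.

Bursts are contiguous runs of bins whose counts strictly exceed
``background + k_sigma * sigma``; runs separated by at most ``gap_bins``
below-threshold bins are merged, and runs shorter than ``min_bins`` are
discarded. The burst amplitude is the background-subtracted integrated
count over the run — the quantity whose distribution the concentration
histograms bin — with the peak bin count retained for QC.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .trace import IntensityTrace

__all__ = ["BurstEvent", "estimate_background", "detect_bursts"]

DEFAULT_K_SIGMA = 5.0
DEFAULT_MIN_BINS = 2
DEFAULT_GAP_BINS = 1


@dataclass(frozen=True)
class BurstEvent:
    """One detected single-particle transit."""

    start: float       # s
    end: float         # s (exclusive bin edge); end > start
    amplitude: float   # background-subtracted integrated counts
    peak: float        # max counts in any bin of the burst
    n_bins: int

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("end must be > start")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")


def estimate_background(trace: IntensityTrace, clip_sigma: float = 3.0,
                        max_iter: int = 100) -> Tuple[float, float]:
    """Robust background (rate in counts/s, sigma in counts/bin).

    Iterative sigma-clipping: bins more than ``clip_sigma`` Poisson
    standard deviations above the running mean are discarded until the
    kept set is stable. Sigma is the Poisson value sqrt(mean counts/bin).

    Raises if fewer than 1000 bins are available, or if clipping removes
    more than half the trace (signal-saturated: dilute the sample).
    """
    counts = trace.counts
    if len(counts) < 1000:
        raise ValueError("need at least 1000 bins to estimate background")
    if counts.max() == 0:
        return 0.0, 0.0
    keep = np.ones(len(counts), dtype=bool)
    cut = counts.max()
    for _ in range(max_iter):
        mean = counts[keep].mean()
        sigma = np.sqrt(mean)
        # integer-valued counts: round the clip level up so sparse
        # backgrounds (mean << 1) keep their occasional 1-count bins
        cut = int(np.ceil(mean + clip_sigma * sigma))
        new_keep = counts <= cut
        if new_keep.sum() < 0.5 * len(counts):
            raise ValueError(
                "more than half the trace clipped as signal; the sample "
                "is too concentrated for background estimation — dilute")
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    mean = _debias_clipped_poisson(counts[keep].mean(), cut)
    return float(mean / trace.bin_width), float(np.sqrt(mean))


def _debias_clipped_poisson(clipped_mean: float, cut: int,
                            n_iter: int = 20) -> float:
    """Poisson rate whose mean conditional on X <= cut equals the
    observed clipped mean."""
    from scipy import stats as _stats

    if clipped_mean <= 0:
        return 0.0
    lam = clipped_mean
    for _ in range(n_iter):
        denom = _stats.poisson.cdf(cut, lam)
        if denom <= 0:
            break
        cond_mean = lam * _stats.poisson.cdf(cut - 1, lam) / denom
        if cond_mean <= 0:
            break
        lam *= clipped_mean / cond_mean
    return lam


def _poisson_threshold(lam: float, k_sigma: float) -> float:
    """Count level whose Poisson tail matches the Gaussian k-sigma tail.

    For sparse backgrounds (lam << 1) the Gaussian rule bg + k*sqrt(bg)
    sits below 2 counts and fires constantly on ordinary shot noise;
    the matched Poisson quantile keeps the intended per-bin false-alarm
    probability. For lam >~ 10 the two rules coincide.
    """
    from scipy import stats as _stats

    if lam <= 0:
        return 0.0
    p_tail = _stats.norm.sf(k_sigma)
    # smallest m with P(X >= m) <= p_tail; sf(m-1) = P(X >= m)
    m = max(int(lam), 1)
    while _stats.poisson.sf(m - 1, lam) > p_tail:
        m += 1
    return float(m - 1)


def detect_bursts(trace: IntensityTrace,
                  k_sigma: float = DEFAULT_K_SIGMA,
                  min_bins: int = DEFAULT_MIN_BINS,
                  gap_bins: int = DEFAULT_GAP_BINS,
                  background: Optional[Tuple[float, float]] = None,
                  pad_bins: Optional[int] = None) -> List[BurstEvent]:
    """Detect bursts in a trace.

    ``background`` may supply a precomputed (rate, sigma) pair from
    :func:`estimate_background`; otherwise it is estimated first.
    A bin belongs to a burst only if its counts strictly exceed the
    threshold; a bin at exactly the threshold is excluded. Once a run
    triggers, the integration window is widened by ``pad_bins`` (one
    transit time by default) on each side so dim-burst wings below
    threshold still contribute to the amplitude. Events are returned
    sorted by start time (empty list if none).
    """
    if background is None:
        background = estimate_background(trace)
    bg_rate, sigma = background
    bg_per_bin = bg_rate * trace.bin_width
    threshold = max(bg_per_bin + k_sigma * sigma,
                    _poisson_threshold(bg_per_bin, k_sigma))
    if pad_bins is None:
        pad_bins = int(round(trace.acq.transit_time / trace.bin_width))

    above = trace.counts > threshold
    if not above.any():
        return []
    padded = np.concatenate(([0], above.astype(np.int8), [0]))
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive

    # merge runs separated by <= gap_bins below-threshold bins
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= gap_bins:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    merged = [[s, e] for s, e in merged if e - s >= min_bins]

    # widen integration windows by pad_bins; where neighbouring windows
    # would overlap, split at the midpoint so distinct bursts stay
    # distinct events (padding must not extend the coincidence window)
    n = len(trace.counts)
    padded = [[max(0, s - pad_bins), min(n, e + pad_bins)]
              for s, e in merged]
    for prev, cur in zip(padded, padded[1:]):
        if cur[0] < prev[1]:
            mid = (prev[1] + cur[0]) // 2
            prev[1] = mid
            cur[0] = mid

    events: List[BurstEvent] = []
    bin_w = trace.bin_width
    t0 = trace.times[0]
    for s, e in padded:
        seg = trace.counts[s:e]
        amplitude = float(seg.sum() - bg_per_bin * (e - s))
        if amplitude <= 0:
            continue
        events.append(BurstEvent(
            start=t0 + s * bin_w,
            end=t0 + e * bin_w,
            amplitude=amplitude,
            peak=float(seg.max()),
            n_bins=int(e - s),
        ))
    return events
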