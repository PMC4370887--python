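"""BAS histograms: concentration per log-spaced burst-intensity bin.

The central result object of burst analysis spectroscopy. The burst
count in intensity bin i divided by ``detection_rate_constant x
duration`` gives the particle concentration C_i (pM) in that bin;
``mean_bin_intensity`` (I_i) is the mean burst amplitude of the events
in the bin. A single acquisition is quantitative over a limited window:
bins are flagged valid from the brightest downwards while (i) the
cumulative in-cuvette concentration stays below the single-particle
limit, (ii) the bin intensity stays within a ~100-fold window of the
brightest valid bin, and (iii) the bin holds at least 5 events.
Dilution series extend the window: histograms measured at several
dilutions are stitched by least squares on their complementary
cumulative concentration curves.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .bursts import BurstEvent
from .params import AcquisitionParams
from .population import LiposomeSpecies, brightness_of, sample_diameters
from .simulate import SINGLE_PARTICLE_LIMIT_PM

__all__ = [
    "BasHistogram", "log_edges", "build_histogram", "fraction_of_total",
    "merge_dilution_series", "mean_intensity_ratio", "estimate_cv",
    "CvEstimate", "DEFAULT_BINS_PER_DECADE",
]

DEFAULT_BINS_PER_DECADE = 24
#: one acquisition quantitatively spans about a 100-fold intensity range
INTENSITY_WINDOW_FOLD = 100.0
MIN_EVENTS_PER_BIN = 5
#: a bin is unquantifiable once expected coincidence (pile-up) events
#: exceed this fraction of its observed events
PILEUP_FRACTION_LIMIT = 0.2
#: overlap bins enter the dilution-series scale fit only with this many
#: events on both sides
MIN_EVENTS_FOR_SCALE_FIT = 20
#: the intensity window anchors at the brightest bin this well populated
WINDOW_ANCHOR_MIN_EVENTS = 20


@dataclass
class BasHistogram:
    """Concentration (pM, as measured in the cuvette) per intensity bin."""

    bin_edges: np.ndarray            # len n+1, strictly increasing
    concentration: np.ndarray        # pM per bin (C_i), measured
    mean_bin_intensity: np.ndarray   # mean amplitude per bin (I_i)
    n_events: np.ndarray
    dilution_factor: float = 1.0
    acq: Optional[AcquisitionParams] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.mean_bin_intensity = np.asarray(self.mean_bin_intensity,
                                             dtype=float)
        self.n_events = np.asarray(self.n_events, dtype=int)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.concentration) != len(self.bin_edges) - 1:
            raise ValueError("concentration length must be n_edges - 1")
        if np.any(self.concentration < 0):
            raise ValueError("concentration must be >= 0")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")
        if self.valid is None:
            self.valid = self._validity_mask()
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def _validity_mask(self) -> np.ndarray:
        """Bins quantitative within this single acquisition."""
        n = len(self.concentration)
        valid = np.zeros(n, dtype=bool)
        occupied = np.flatnonzero(self.n_events >= MIN_EVENTS_PER_BIN)
        if len(occupied) == 0:
            return valid
        # the ~100-fold window is anchored at the brightest *well
        # populated* bin; a handful of stray bright events must not
        # swing the window away from the dominant species
        anchored = np.flatnonzero(self.n_events >= WINDOW_ANCHOR_MIN_EVENTS)
        anchor = anchored.max() if len(anchored) else occupied.max()
        top_intensity = self.mean_bin_intensity[anchor]
        pileup = self._expected_pileup_events()
        cum = 0.0
        for i in range(occupied.max(), -1, -1):
            cum += self.concentration[i]
            if cum >= SINGLE_PARTICLE_LIMIT_PM:
                break
            if self.n_events[i] < MIN_EVENTS_PER_BIN:
                continue
            if (self.mean_bin_intensity[i] > 0 and top_intensity > 0
                    and top_intensity / self.mean_bin_intensity[i]
                    > INTENSITY_WINDOW_FOLD):
                continue
            if pileup is not None and \
                    pileup[i] > PILEUP_FRACTION_LIMIT * self.n_events[i]:
                continue
            valid[i] = True
        return valid

    def _expected_pileup_events(self) -> Optional[np.ndarray]:
        """Expected coincidence (two-particle) events per bin.

        Two transits within one coincidence window merge into a single
        event near the summed amplitude; at high concentration this
        fake-event tail sits a few-fold above an abundant species and
        destroys quantitation there. Pairs whose smaller member adds
        < 25% are ignored: they barely move the larger event. Requires
        acquisition metadata; returns None without it.
        """
        if self.acq is None:
            return None
        window = 2.0 * self.acq.transit_time
        rate_per_event = window / self.acq.duration
        n = self.n_events.astype(float)
        occ = np.flatnonzero(n > 0)
        fake = np.zeros(len(n))
        intens = self.mean_bin_intensity
        for a, j in enumerate(occ):
            for k in occ[a:]:
                lo, hi = sorted((intens[j], intens[k]))
                summed = lo + hi
                if lo < summed / 5.0:  # smaller member adds < 25%
                    continue
                i = int(np.searchsorted(self.bin_edges, summed)) - 1
                if 0 <= i < len(n):
                    mult = 1.0 if j == k else 2.0
                    fake[i] += 0.5 * mult * n[j] * n[k] * rate_per_event
        return fake

    @property
    def n_bins(self) -> int:
        return len(self.concentration)

    @property
    def total_concentration(self) -> float:
        return float(self.concentration.sum())

    @property
    def undiluted_concentration(self) -> np.ndarray:
        """Per-bin concentration rescaled to the undiluted sample."""
        return self.concentration * self.dilution_factor

    @property
    def mean_intensity(self) -> float:
        """Concentration-weighted mean burst intensity."""
        total = self.concentration.sum()
        if total == 0:
            raise ValueError("empty histogram")
        return float((self.concentration * self.mean_bin_intensity).sum()
                     / total)

    @property
    def total_intensity_concentration(self) -> float:
        """Sum of I_i * C_i — the total fluorescence of the sample."""
        return float((self.concentration * self.mean_bin_intensity).sum())


def log_edges(lo: float, hi: float,
              bins_per_decade: int = DEFAULT_BINS_PER_DECADE) -> np.ndarray:
    """Log-spaced bin edges covering [lo, hi]."""
    if not (lo > 0 and hi > lo):
        raise ValueError("need 0 < lo < hi")
    n = int(math.ceil(math.log10(hi / lo) * bins_per_decade))
    return lo * 10 ** (np.arange(n + 1) / bins_per_decade)


def _amplitudes(bursts) -> np.ndarray:
    if len(bursts) and isinstance(bursts[0], BurstEvent):
        return np.array([b.amplitude for b in bursts], dtype=float)
    return np.asarray(bursts, dtype=float)


def build_histogram(bursts: Union[Sequence[BurstEvent], np.ndarray],
                    acq: AcquisitionParams,
                    edges: Optional[np.ndarray] = None,
                    dilution_factor: float = 1.0) -> BasHistogram:
    """Bin burst amplitudes into a BAS histogram.

    C_i = (events in bin i) / (detection_rate_constant x duration), in
    pM as measured; ``dilution_factor`` records how the measured sample
    relates to the undiluted one.
    """
    amps = _amplitudes(bursts)
    if len(amps) == 0:
        warnings.warn("no bursts: returning an all-zero histogram")
        if edges is None:
            edges = log_edges(1.0, 10.0)
    elif edges is None:
        edges = log_edges(amps.min() * 0.999, amps.max() * 1.001)
    n_i, _ = np.histogram(amps, bins=edges)
    conc = n_i / (acq.detection_rate_constant * acq.duration)
    mean_i = np.zeros(len(n_i))
    if len(amps):
        sums, _ = np.histogram(amps, bins=edges, weights=amps)
        nz = n_i > 0
        mean_i[nz] = sums[nz] / n_i[nz]
    # empty bins carry the geometric bin centre so ratios stay defined
    nz = n_i > 0
    centres = np.sqrt(edges[:-1] * edges[1:])
    mean_i[~nz] = centres[~nz]
    return BasHistogram(bin_edges=edges, concentration=conc,
                        mean_bin_intensity=mean_i, n_events=n_i,
                        dilution_factor=dilution_factor, acq=acq)


def fraction_of_total(h: BasHistogram) -> np.ndarray:
    """Per-bin concentration fractions f_i = C_i / sum(C); sums to 1."""
    total = h.concentration.sum()
    if total <= 0:
        raise ValueError("histogram has zero total concentration")
    return h.concentration / total


def mean_intensity_ratio(h1: BasHistogram, h2: BasHistogram
                         ) -> Tuple[float, float]:
    """(fold, implied diameter ratio) between two histograms.

    fold is the ratio of concentration-weighted mean burst intensities;
    since brightness scales with surface area, the implied diameter
    ratio is sqrt(fold).
    """
    fold = h1.mean_intensity / h2.mean_intensity
    return fold, math.sqrt(fold)


def _ccdf(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Complementary cumulative sum over masked bins (from the top)."""
    v = np.where(mask, values, 0.0)
    return v[::-1].cumsum()[::-1]


def merge_dilution_series(series: Sequence[Union[BasHistogram,
                                                 Tuple[BasHistogram, float]]]
                          ) -> BasHistogram:
    """Stitch histograms measured at several dilutions into one.

    All histograms must share bin edges. Concentrations are rescaled to
    undiluted values; the least-dilute histogram anchors the result and
    each more-dilute histogram is brought onto it by a least-squares
    scale factor fitted on the complementary cumulative concentration
    over the bins where both are valid. The output covers the union of
    the validity windows, with the anchor's concentrations untouched in
    its own window.
    """
    histos: List[BasHistogram] = []
    for item in series:
        if isinstance(item, tuple):
            h, f = item
            h = replace(h, dilution_factor=f, valid=h.valid)
        else:
            h = item
        histos.append(h)
    if len(histos) < 2:
        raise ValueError("need at least two histograms to merge")
    edges0 = histos[0].bin_edges
    for h in histos[1:]:
        if len(h.bin_edges) != len(edges0) or not np.allclose(h.bin_edges,
                                                              edges0):
            raise ValueError("histograms must share bin edges")
    histos.sort(key=lambda h: h.dilution_factor)

    anchor = histos[0]
    merged_c = np.where(anchor.valid, anchor.undiluted_concentration, 0.0)
    merged_i = anchor.mean_bin_intensity.copy()
    merged_n = np.where(anchor.valid, anchor.n_events, 0)
    covered = anchor.valid.copy()

    def _clean(h):
        """Bins essentially free of expected coincidence events."""
        pile = h._expected_pileup_events()
        if pile is None:
            return np.ones(h.n_bins, dtype=bool)
        return pile <= 0.05 * np.maximum(h.n_events, 1)

    merged_clean = _clean(anchor)

    for h in histos[1:]:
        overlap = covered & h.valid
        if not overlap.any():
            lo = edges0[:-1][h.valid].min() if h.valid.any() else np.nan
            hi = edges0[1:][covered].max() if covered.any() else np.nan
            raise ValueError(
                "no overlap between dilution "
                f"{h.dilution_factor:g}x (valid from intensity {lo:g}) "
                f"and the merged window (up to {hi:g})")
        # the relative scale is fitted only where both acquisitions
        # measured the overlap well and without coincidence
        # contamination; otherwise the calibrated dilution factors are
        # trusted as-is (scale 1)
        fit_bins = overlap & (merged_n >= MIN_EVENTS_FOR_SCALE_FIT) \
            & (h.n_events >= MIN_EVENTS_FOR_SCALE_FIT) \
            & merged_clean & _clean(h)
        if fit_bins.any():
            # cumulate over the shared support so the two complementary
            # cumulative curves are comparable bin by bin
            cc_m = _ccdf(merged_c, fit_bins)
            cc_h = _ccdf(h.undiluted_concentration, fit_bins)
            num = float((cc_m * cc_h)[fit_bins].sum())
            den = float((cc_h * cc_h)[fit_bins].sum())
            scale = num / den if den > 0 else 1.0
        else:
            scale = 1.0
        new_bins = h.valid & ~covered
        merged_c[new_bins] = scale * h.undiluted_concentration[new_bins]
        merged_i[new_bins] = h.mean_bin_intensity[new_bins]
        merged_n[new_bins] = h.n_events[new_bins]
        covered |= h.valid

    return BasHistogram(bin_edges=edges0, concentration=merged_c,
                        mean_bin_intensity=merged_i, n_events=merged_n,
                        dilution_factor=1.0, acq=anchor.acq, valid=covered)


@dataclass(frozen=True)
class CvEstimate:
    """Result of Monte Carlo CV template matching."""

    cv: float
    mean_diameter: float          # nm, NaN when no calibration supplied
    distance: float               # KS statistic at the optimum
    cv_grid: np.ndarray
    distances: np.ndarray
    metric: str = "ks"


def estimate_cv(intensities: Union[BasHistogram, np.ndarray],
                cv_grid: Sequence[float],
                mean_diameter_grid: Optional[Sequence[float]] = None,
                n_template: int = 10_000,
                seed: int = 0,
                intensity_per_area: Optional[float] = None) -> CvEstimate:
    """Infer population size CV by Monte Carlo template matching.

    For each CV on the grid, a template of ``n_template`` particle
    intensities is simulated (diameters from the truncated normal,
    brightness proportional to d^2) and compared with the observed
    burst-intensity distribution by the Kolmogorov-Smirnov statistic on
    median-normalized intensities; the minimizing CV is returned. The
    normalization makes the match scale-free — the template shape
    depends only on CV — so the mean diameter is identified separately:
    when ``intensity_per_area`` (counts per nm^2 of membrane) is given,
    the data median is converted to a diameter and snapped to
    ``mean_diameter_grid`` if provided; otherwise NaN is returned.
    """
    cv_grid = np.asarray(sorted(cv_grid), dtype=float)
    if np.any(cv_grid < 0.0) or np.any(cv_grid > 1.0):
        raise ValueError("cv_grid values must be within [0, 1]")
    if isinstance(intensities, BasHistogram):
        data = np.repeat(intensities.mean_bin_intensity,
                         intensities.n_events)
    else:
        data = np.asarray(intensities, dtype=float)
    data = data[data > 0]
    if len(data) == 0:
        raise ValueError("no positive intensities supplied")
    data_med = np.median(data)
    data_norm = data / data_med

    rng = np.random.default_rng(seed)
    distances = np.empty(len(cv_grid))
    med_raw = np.empty(len(cv_grid))
    for j, cv in enumerate(cv_grid):
        proto = LiposomeSpecies(mean_diameter=1.0, cv=float(cv),
                                concentration=0.0)
        d = sample_diameters(proto, n_template, rng) if cv > 0 \
            else np.ones(n_template)
        template = d ** 2
        med_raw[j] = np.median(template)
        stat = stats.ks_2samp(data_norm, template / med_raw[j]).statistic
        distances[j] = stat
    best = int(np.argmin(distances))
    if best in (0, len(cv_grid) - 1) and len(cv_grid) > 1:
        warnings.warn("best CV lies on the grid boundary; widen the grid")

    mean_d = float("nan")
    if intensity_per_area is not None:
        # data_med ~ ipa * pi * m^2 * median(d_tilde^2)
        mean_d = math.sqrt(data_med / (intensity_per_area * math.pi
                                       * med_raw[best]))
        if mean_diameter_grid is not None:
            grid = np.asarray(mean_diameter_grid, dtype=float)
            mean_d = float(grid[np.argmin(np.abs(grid - mean_d))])
    return CvEstimate(cv=float(cv_grid[best]), mean_diameter=mean_d,
                      distance=float(distances[best]), cv_grid=cv_grid,
                      distances=distances)
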