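"""Fission kinetics from time courses of BAS histograms.

A :class:`FissionTimeCourse` holds one histogram per reaction time
(shared bin edges). Heat-map rows are the fractional fluorescence per
bin, I_i C_i / sum_n I_n C_n, so every row sums to one and a row's
brightness profile shows where the membrane currently resides on the
intensity (size) axis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .histogram import BasHistogram

__all__ = [
    "FissionTimeCourse", "HeatMap", "fractional_intensity_row",
    "total_signal_series", "product_bin_window", "time_to_plateau",
    "dose_response",
]


@dataclass
class FissionTimeCourse:
    """Histograms of one fission reaction sampled over time (minutes)."""

    times: np.ndarray                 # minutes, strictly increasing
    histograms: List[BasHistogram]    # shared bin edges
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.histograms):
            raise ValueError("times and histograms must align")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.histograms:
            e0 = self.histograms[0].bin_edges
            for h in self.histograms[1:]:
                if len(h.bin_edges) != len(e0) or \
                        not np.allclose(h.bin_edges, e0):
                    raise ValueError("histograms must share bin edges")

    @property
    def bin_edges(self) -> np.ndarray:
        return self.histograms[0].bin_edges


@dataclass
class HeatMap:
    """Row-normalized fractional-intensity matrix (one row per sample)."""

    values: np.ndarray       # (n_rows, n_bins), each row sums to 1
    row_labels: list
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("heat-map values must be >= 0")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each heat-map row must sum to 1")

    @classmethod
    def from_timecourse(cls, tc: FissionTimeCourse) -> "HeatMap":
        rows = np.array([fractional_intensity_row(h)
                         for h in tc.histograms])
        return cls(values=rows, row_labels=[f"{t:g} min" for t in tc.times],
                   bin_edges=tc.bin_edges)


def fractional_intensity_row(h: BasHistogram) -> np.ndarray:
    """Fractional fluorescence per bin: I_i C_i / sum_n I_n C_n."""
    w = h.mean_bin_intensity * h.concentration
    total = w.sum()
    if total <= 0:
        raise ValueError("histogram carries no fluorescence")
    return w / total


def total_signal_series(tc: FissionTimeCourse) -> np.ndarray:
    """Total fluorescence sum(I_i C_i) per time, normalized to its max.

    For a lossless fission reaction the values stay near 1 throughout;
    deviations report fluorescent material escaping (or entering) the
    detected size window.
    """
    totals = np.array([h.total_intensity_concentration
                       for h in tc.histograms])
    if len(totals) == 0:
        raise ValueError("time course is empty")
    return totals / totals.max()


def product_bin_window(tc: FissionTimeCourse,
                       intensity_factor: float = 2.0) -> np.ndarray:
    """Bins holding the smallest fission products.

    The modal product bin is the most concentrated bin of the final
    histogram; the window keeps bins whose mean intensity is at most
    ``intensity_factor`` times that bin's.
    """
    final = tc.histograms[-1]
    if final.concentration.sum() == 0:
        raise ValueError("final histogram is empty")
    modal = int(np.argmax(final.concentration))
    cutoff = intensity_factor * final.mean_bin_intensity[modal]
    return final.mean_bin_intensity <= cutoff


def time_to_plateau(tc: FissionTimeCourse,
                    window: Optional[np.ndarray] = None,
                    frac: float = 0.95,
                    plateau_rtol: float = 0.10) -> float:
    """First time the product-window concentration reaches ``frac`` of
    its plateau (the final value), by linear interpolation.

    Raises if the plateau is not reached (last two samples differ by
    more than ``plateau_rtol`` relative to the final value).
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    if window is None:
        window = product_bin_window(tc)
    conc = np.array([h.concentration[window].sum() for h in tc.histograms])
    if len(conc) < 2:
        raise ValueError("need at least two time points")
    plateau = conc[-1]
    if plateau <= 0:
        raise ValueError("no product concentration at the final time")
    if abs(conc[-1] - conc[-2]) > plateau_rtol * plateau:
        raise ValueError(
            "plateau not reached: last two points differ by "
            f"{abs(conc[-1] - conc[-2]) / plateau:.1%}")
    target = frac * plateau
    if conc[0] >= target:
        return float(tc.times[0])
    above = np.flatnonzero(conc >= target)
    if len(above) == 0:  # frac of final exceeded nowhere before the end
        return float(tc.times[-1])
    i = above[0]
    t0, t1 = tc.times[i - 1], tc.times[i]
    c0, c1 = conc[i - 1], conc[i]
    return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))


def dose_response(histos: Sequence[Tuple[float, BasHistogram]],
                  reference: BasHistogram,
                  window: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Fraction of starting-size fluorescence remaining vs protein dose.

    ``window`` marks the starting-liposome bins; by default it is the
    bins within 2-fold of the reference's dominant-fluorescence bin.
    The remaining fraction is the fractional intensity in the window,
    normalized to the reference's, so a zero-activity condition scores
    ~1 and complete conversion near 0.
    """
    ref_row = fractional_intensity_row(reference)
    if window is None:
        modal = int(np.argmax(ref_row))
        modal_i = reference.mean_bin_intensity[modal]
        window = reference.mean_bin_intensity >= modal_i / 2.0
    ref_mass = ref_row[window].sum()
    if ref_mass <= 0:
        raise ValueError("reference has no fluorescence in the window")
    rows = []
    for conc, h in histos:
        if len(h.bin_edges) != len(reference.bin_edges) or \
                not np.allclose(h.bin_edges, reference.bin_edges):
            raise ValueError("histogram binning does not match reference")
        row = fractional_intensity_row(h)
        rows.append({"protein_conc": conc,
                     "remaining_fraction": row[window].sum() / ref_mass})
    return pd.DataFrame(rows)
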