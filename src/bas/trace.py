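"""Time-binned photon-count traces."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import AcquisitionParams

__all__ = ["IntensityTrace"]

#: ground-truth burst annotation columns attached by the simulator
GROUND_TRUTH_COLUMNS = ("arrival_s", "diameter_nm", "brightness",
                        "beam_factor", "amplitude")


@dataclass
class IntensityTrace:
    """Photon counts on a uniform time grid.

    ``ground_truth`` (optional) is a DataFrame of simulated burst
    annotations — one row per particle transit, with arrival time,
    particle diameter, brightness, beam attenuation factor and the
    noiseless integrated amplitude (counts). Overlapping transits are
    kept as separate rows even though their photons sum in the trace.
    """

    times: np.ndarray
    counts: np.ndarray
    acq: AcquisitionParams
    ground_truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        if not np.all(counts == np.round(counts)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time grid must be uniform")

    @property
    def bin_width(self) -> float:
        if len(self.times) > 1:
            return float(self.times[1] - self.times[0])
        return self.acq.bin_width

    @property
    def duration(self) -> float:
        return len(self.counts) * self.bin_width

    def __len__(self) -> int:
        return len(self.counts)
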