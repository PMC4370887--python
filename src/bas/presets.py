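"""Preset scenarios mirroring the calibration and fission experiments.

Concentration convention: 0.01 mg/mL of extruded lipid corresponds to
roughly 50-100 pM of 200 nm liposomes (mass per liposome scales with
membrane area), so the starting populations are set in that range.
Rate constants are scenario parameters chosen so that the small-product
plateau falls near 60 min at 23 C and near 30 min at 37 C, i.e. the
37 C rate is twice the 23 C rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import AcquisitionParams, FissionParams
from .population import LiposomeSpecies

__all__ = ["PRESETS", "get_preset", "RunConfig"]

#: extrusion polydispersity observed for large liposomes
EXTRUSION_CV = 0.35
#: polydispersity of the ~20 nm fission products
PRODUCT_CV = 0.30

K23_PER_MIN = 0.05   # 23 C first-order fission rate, 1/min
K37_PER_MIN = 0.10   # 37 C: 2-fold faster


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    preset: str
    seed: int = 0
    outdir: str = "bas_run"
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    fission: Optional[FissionParams] = None

    def to_dict(self) -> dict:
        d = {"preset": self.preset, "seed": self.seed, "outdir": self.outdir,
             "acquisition": self.acquisition.to_dict()}
        if self.fission is not None:
            d["fission"] = self.fission.to_dict()
        return d


def _fig1() -> dict:
    return {
        "kind": "size_ladder",
        "species": [LiposomeSpecies(d, EXTRUSION_CV, 100.0)
                    for d in (200.0, 100.0, 50.0)],
        "expected_folds": {"200:100": 4.0, "200:50": 16.0},
        "acquisition": AcquisitionParams(duration=240.0),
    }


def _fig2() -> dict:
    return {
        "kind": "fission_endpoint",
        "parent": LiposomeSpecies(200.0, EXTRUSION_CV, 20.0),
        "fission": FissionParams(rate_constant=K37_PER_MIN / 60.0,
                                 product_mean_diameter=20.0,
                                 product_cv=PRODUCT_CV),
        "reaction_time_s": 40 * 60.0 * 20,  # >> 1/k: complete conversion
        "dilutions": [1.0, 10.0],
        "acquisition": AcquisitionParams(duration=240.0),
    }


def _fig3(k_per_min: float, t_max_min: float, label: str) -> dict:
    return {
        "kind": "kinetics",
        "parent": LiposomeSpecies(200.0, EXTRUSION_CV, 50.0),
        "fission": FissionParams(rate_constant=k_per_min / 60.0,
                                 product_mean_diameter=20.0,
                                 product_cv=PRODUCT_CV),
        "times_min": np.linspace(0.0, t_max_min, 8)[1:],
        "dilution": 10.0,
        "temperature_label": label,
        # high-flux calibration: plateau detection needs ~2% counting
        # precision per time point
        "acquisition": AcquisitionParams(duration=240.0,
                                         detection_rate_constant=0.2),
    }


PRESETS = {
    "fig1": _fig1,
    "fig2": _fig2,
    "fig3-23C": lambda: _fig3(K23_PER_MIN, 100.0, "23C"),
    "fig3-37C": lambda: _fig3(K37_PER_MIN, 50.0, "37C"),
}


def get_preset(name: str) -> dict:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}") from None
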