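"""Acquisition and fission parameter containers.

All times are seconds, lengths nanometres, concentrations picomolar,
rates per second unless noted. ``AcquisitionParams`` describes one
confocal burst-counting (or FCS) acquisition; ``FissionParams`` one
first-order fission scenario.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

BOLTZMANN = 1.380649e-23  # J/K

TRANSIT_MODES = ("scan", "diffusion")
FISSION_MODES = ("direct", "cascade")


@dataclass(frozen=True)
class AcquisitionParams:
    """Instrument and sampling parameters for a simulated acquisition.

    Parameters
    ----------
    bin_width : float
        Photon-counting bin width in seconds.
    duration : float
        Total acquisition length in seconds.
    detection_rate_constant : float
        Burst flux calibration, bursts s^-1 pM^-1. The product with the
        sample concentration gives the mean single-particle burst rate.
    background_rate : float
        Mean background count rate, counts/s.
    brightness_scale : float
        Peak detected count rate (counts/s) per unit particle brightness
        for a particle at the centre of the beam.
    transit_time : float
        Transit duration through the detection volume in scan mode, s.
    transit_mode : str
        "scan" (stage-scanned, fixed transit time) or "diffusion" (FCS).
    psf_aspect : float
        Axial/lateral aspect ratio kappa of the Gaussian detection volume.
    beam_waist : float
        Lateral 1/e^2 beam waist w0 in nm.
    temperature : float
        Sample temperature in K (used for Stokes-Einstein diffusion).
    viscosity : float
        Solvent viscosity in Pa s. ``math.inf`` freezes all particles.
    seed : int, optional
        Default RNG seed for simulations run with these parameters.
    """

    bin_width: float = 1e-4
    duration: float = 60.0
    detection_rate_constant: float = 0.05
    background_rate: float = 1000.0
    brightness_scale: float = 8000.0
    transit_time: float = 5e-4
    transit_mode: str = "scan"
    psf_aspect: float = 5.0
    beam_waist: float = 300.0
    temperature: float = 296.0
    viscosity: float = 0.93e-3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("bin_width", "duration", "detection_rate_constant",
                     "background_rate", "brightness_scale", "transit_time",
                     "beam_waist", "temperature", "viscosity"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if self.psf_aspect < 1:
            raise ValueError("psf_aspect (kappa) must be >= 1")
        if self.transit_mode not in TRANSIT_MODES:
            raise ValueError(f"transit_mode must be one of {TRANSIT_MODES}")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))

    @property
    def axial_waist(self) -> float:
        """Axial 1/e^2 extent z0 = kappa * w0, nm."""
        return self.psf_aspect * self.beam_waist

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class FissionParams:
    """First-order fission of parent liposomes into smaller products.

    ``rate_constant`` is the per-parent conversion rate k (s^-1); a
    fraction 1 - exp(-k t) of parents has reacted after time t.
    ``mode`` selects the product mechanism: "direct" (parents shatter
    straight into products near ``product_mean_diameter``) or "cascade"
    (repeated area-halving steps down to the product size).
    ``partition_bias`` is a diagnostic knob multiplying the label density
    inherited by products by (1 + bias); 0 means unbiased partitioning
    and exact conservation of total labelled membrane area.
    """

    rate_constant: float
    product_mean_diameter: float = 20.0
    product_cv: float = 0.30
    mode: str = "direct"
    partition_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")
        if not self.product_mean_diameter > 0:
            raise ValueError("product_mean_diameter must be > 0")
        if self.product_cv < 0:
            raise ValueError("product_cv must be >= 0")
        if self.mode not in FISSION_MODES:
            raise ValueError(f"mode must be one of {FISSION_MODES}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FissionParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def stokes_einstein_diffusion(diameter_nm: float, temperature: float,
                              viscosity: float) -> float:
    """Diffusion coefficient (m^2/s) of a sphere of given diameter (nm)."""
    if not diameter_nm > 0:
        raise ValueError("diameter must be > 0")
    if math.isinf(viscosity):
        return 0.0
    radius_m = 0.5 * diameter_nm * 1e-9
    return BOLTZMANN * temperature / (6.0 * math.pi * viscosity * radius_m)
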