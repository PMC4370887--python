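"""Render single-particle fluorescence traces and FCS traces.

Burst mode (``simulate_trace``): particle transits arrive as a Poisson
process with rate ``detection_rate_constant x concentration``; each
transit deposits a Gaussian-shaped packet of expected counts whose peak
is the particle brightness scaled by the beam attenuation at a random
impact parameter; photon shot noise is Poisson per bin on top of a
Poisson background.

FCS mode (``simulate_fcs_trace``): a fixed number of particles performs
Brownian motion (Stokes-Einstein diffusion) through a 3D Gaussian
observation volume inside a periodic box; the detected rate is the sum
of per-particle Gaussian-volume weights.
"""
from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .params import AcquisitionParams, stokes_einstein_diffusion
from .population import LiposomePopulation
from .trace import IntensityTrace

__all__ = ["simulate_trace", "simulate_fcs_trace", "effective_volume_L",
           "mean_particles_in_volume", "SINGLE_PARTICLE_LIMIT_PM"]

#: concentration above which bursts no longer arise from single particles
SINGLE_PARTICLE_LIMIT_PM = 500.0

#: impact parameters are drawn uniformly on [0, IMPACT_MAX * beam_waist]
IMPACT_MAX = 1.5


def _rng_for(acq: AcquisitionParams, seed: Optional[int]) -> np.random.Generator:
    if seed is None:
        seed = acq.seed
    return np.random.default_rng(seed)


def simulate_trace(pop: LiposomePopulation, acq: AcquisitionParams,
                   seed: Optional[int] = None) -> IntensityTrace:
    """Simulate a stage-scanned burst acquisition of a population.

    Returns an :class:`IntensityTrace` whose ``ground_truth`` DataFrame
    lists every particle transit (arrival time, diameter, brightness,
    beam factor, noiseless amplitude in counts), including transits that
    overlap in the rendered trace.
    """
    rng = _rng_for(acq, seed)
    conc = pop.total_concentration
    if conc > SINGLE_PARTICLE_LIMIT_PM:
        warnings.warn(
            f"concentration {conc:.0f} pM exceeds the single-particle "
            f"limit (~{SINGLE_PARTICLE_LIMIT_PM:.0f} pM); bursts will "
            "overlap and counts will be lost to coincidence")
    if acq.duration < 10 * acq.transit_time:
        warnings.warn("duration shorter than 10 transit times; "
                      "burst statistics will be poor")
    n_bins = acq.n_bins
    times = np.arange(n_bins) * acq.bin_width
    expected = np.full(n_bins, acq.background_rate * acq.bin_width)

    gt = pd.DataFrame({c: np.empty(0) for c in
                       ("arrival_s", "diameter_nm", "brightness",
                        "beam_factor", "amplitude")})
    if conc > 0:
        rate = acq.detection_rate_constant * conc
        n_bursts = rng.poisson(rate * acq.duration)
        if n_bursts > 0:
            t0 = np.sort(rng.uniform(0.0, acq.duration, size=n_bursts))
            diam, bright = pop.draw_particles(n_bursts, rng)
            b = rng.uniform(0.0, IMPACT_MAX * acq.beam_waist, size=n_bursts)
            beam = np.exp(-2.0 * (b / acq.beam_waist) ** 2)
            peak_rate = acq.brightness_scale * bright * beam

            sigma_t = acq.transit_time / 2.0
            half = max(int(math.ceil(4.0 * sigma_t / acq.bin_width)), 1)
            offsets = np.arange(-half, half + 1)
            centre_bin = t0 / acq.bin_width
            idx = np.floor(centre_bin)[:, None] + offsets[None, :]
            t_bin = (idx + 0.5) * acq.bin_width
            shape = np.exp(-0.5 * ((t_bin - t0[:, None]) / sigma_t) ** 2)
            contrib = peak_rate[:, None] * shape * acq.bin_width
            amplitude = contrib.sum(axis=1)

            flat_idx = idx.astype(np.int64).ravel()
            flat_val = contrib.ravel()
            inside = (flat_idx >= 0) & (flat_idx < n_bins)
            np.add.at(expected, flat_idx[inside], flat_val[inside])

            gt = pd.DataFrame({
                "arrival_s": t0,
                "diameter_nm": diam,
                "brightness": bright,
                "beam_factor": beam,
                "amplitude": amplitude,
            })

    counts = rng.poisson(expected)
    return IntensityTrace(times=times, counts=counts, acq=acq,
                          ground_truth=gt)


def effective_volume_L(acq: AcquisitionParams) -> float:
    """FCS effective volume pi^{3/2} w0^2 z0 in litres."""
    w0, z0 = acq.beam_waist, acq.axial_waist
    v_nm3 = math.pi ** 1.5 * w0 ** 2 * z0
    return v_nm3 * 1e-24


AVOGADRO = 6.02214076e23


def mean_particles_in_volume(pop: LiposomePopulation,
                             acq: AcquisitionParams) -> float:
    """Mean particle number in the FCS effective volume (= 1/G(0))."""
    return pop.total_concentration * 1e-12 * AVOGADRO * effective_volume_L(acq)


#: simulation box half-widths in units of (w0, w0, z0)
_BOX_HALF = 3.0


def simulate_fcs_trace(pop: LiposomePopulation, acq: AcquisitionParams,
                       seed: Optional[int] = None,
                       chunk_bins: int = 20000) -> IntensityTrace:
    """Simulate diffusion-driven intensity fluctuations for FCS.

    Requires ``acq.transit_mode == "diffusion"``. The number of
    simulated particles follows from the population concentration and
    the periodic box volume (box half-widths 3 w0 laterally, 3 z0
    axially); brightness is surface-area-proportional per particle and
    diffusion is Stokes-Einstein at ``acq.temperature``/``acq.viscosity``.
    """
    if acq.transit_mode != "diffusion":
        raise ValueError("simulate_fcs_trace requires transit_mode="
                         "'diffusion'")
    rng = _rng_for(acq, seed)
    w0, z0 = acq.beam_waist, acq.axial_waist
    half = np.array([_BOX_HALF * w0, _BOX_HALF * w0, _BOX_HALF * z0])
    box_l = np.prod(2 * half) * 1e-24  # nm^3 -> litres
    n_particles = int(round(pop.total_concentration * 1e-12 * AVOGADRO
                            * box_l))
    if n_particles < 1:
        raise ValueError("concentration too low: no particles in the "
                         "simulation box; increase concentration")

    diam, bright = pop.draw_particles(n_particles, rng)
    # diffusion in nm^2/s
    d_coef = np.array([stokes_einstein_diffusion(d, acq.temperature,
                                                 acq.viscosity)
                       for d in diam]) * 1e18
    step_sigma = np.sqrt(2.0 * d_coef * acq.bin_width)  # nm per axis

    n_bins = acq.n_bins
    pos = rng.uniform(-half, half, size=(n_particles, 3))
    expected = np.empty(n_bins)
    amp = acq.brightness_scale * bright
    for start in range(0, n_bins, chunk_bins):
        stop = min(start + chunk_bins, n_bins)
        m = stop - start
        steps = rng.standard_normal((m, n_particles, 3)) \
            * step_sigma[None, :, None]
        walk = pos[None, :, :] + np.cumsum(steps, axis=0)
        # periodic wrap
        walk = (walk + half) % (2 * half) - half
        pos = walk[-1]
        w = np.exp(-2.0 * (walk[:, :, 0] ** 2 + walk[:, :, 1] ** 2) / w0 ** 2
                   - 2.0 * walk[:, :, 2] ** 2 / z0 ** 2)
        expected[start:stop] = (w * amp[None, :]).sum(axis=1) * acq.bin_width
    expected += acq.background_rate * acq.bin_width
    counts = rng.poisson(expected)
    times = np.arange(n_bins) * acq.bin_width
    return IntensityTrace(times=times, counts=counts, acq=acq)
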