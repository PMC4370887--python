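"""Fluorescence correlation spectroscopy: multi-tau autocorrelation and
single-component 3D diffusion fits.

G(tau) = <dF(t) dF(t+tau)> / <F>^2 is estimated on a multi-tau lag grid
(octave coarsening, 16 linear lags per octave). The fitted model is the
standard single-species 3D Gaussian-volume diffusion curve

    G(tau) = G0 * (1 + tau/tau_D)^-1 * (1 + tau/(kappa^2 tau_D))^-1/2

with the structure parameter kappa fixed from acquisition metadata.
G0 ~ 1/N reports the mean particle number in the effective volume and
tau_D = w0^2 / (4 D) the diffusion time, linear in hydrodynamic radius
through Stokes-Einstein.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lmfit import Model

from .params import AcquisitionParams, stokes_einstein_diffusion
from .trace import IntensityTrace

__all__ = ["FcsCurve", "FcsFit", "autocorrelate", "fit_diffusion",
           "diffusion_model", "expected_tau_d"]

LAGS_PER_OCTAVE = 16


@dataclass
class FcsCurve:
    """Autocorrelation amplitude vs lag time (quasi-log spacing)."""

    lags: np.ndarray    # seconds, strictly increasing, > 0
    G: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")


@dataclass(frozen=True)
class FcsFit:
    """Converged single-component diffusion fit."""

    G0: float
    tau_d: float       # s
    kappa: float
    residual_norm: float

    def __post_init__(self) -> None:
        if not (self.G0 > 0 and self.tau_d > 0):
            raise ValueError("G0 and tau_d must be > 0")


def _correlate_level(x: np.ndarray, lags: np.ndarray,
                     mean: float) -> np.ndarray:
    out = np.empty(len(lags))
    n = len(x)
    dx = x - x.mean()
    for i, lag in enumerate(lags):
        out[i] = np.dot(dx[:n - lag], dx[lag:]) / (n - lag) / mean ** 2
    return out


def _multi_tau(x: np.ndarray, bin_width: float, max_lag: float):
    lags_s, g = [], []
    level = 0
    x_level = x.astype(float)
    first = True
    while True:
        dt = bin_width * 2 ** level
        lag_bins = np.arange(1, 2 * LAGS_PER_OCTAVE + 1) if first \
            else np.arange(LAGS_PER_OCTAVE + 1, 2 * LAGS_PER_OCTAVE + 1)
        lag_bins = lag_bins[lag_bins * dt <= max_lag]
        if len(lag_bins) == 0 or len(x_level) < 4 * LAGS_PER_OCTAVE:
            break
        mean = x_level.mean()
        g.append(_correlate_level(x_level, lag_bins, mean))
        lags_s.append(lag_bins * dt)
        first = False
        level += 1
        m = (len(x_level) // 2) * 2
        x_level = x_level[:m].reshape(-1, 2).sum(axis=1)
    if not lags_s:
        raise ValueError("trace too short for the requested max_lag")
    return np.concatenate(lags_s), np.concatenate(g)


def autocorrelate(trace: IntensityTrace, max_lag: float,
                  n_segments: int = 8) -> FcsCurve:
    """Multi-tau normalized autocorrelation of a photon-count trace.

    The uncertainty per lag is estimated by splitting the trace into
    ``n_segments`` blocks, correlating each and taking the standard
    error over blocks.
    """
    if trace.duration < 10 * max_lag:
        raise ValueError("trace must be at least 10x max_lag long")
    counts = trace.counts.astype(float)
    if counts.std() == 0:
        raise ValueError("constant trace: zero variance")
    lags, g = _multi_tau(counts, trace.bin_width, max_lag)

    sigma = None
    if n_segments and n_segments > 1:
        seg_len = len(counts) // n_segments
        gs = []
        for s in range(n_segments):
            seg = counts[s * seg_len:(s + 1) * seg_len]
            if seg.std() == 0:
                continue
            try:
                lg, gg = _multi_tau(seg, trace.bin_width, max_lag)
            except ValueError:
                continue
            if len(gg) == len(g):
                gs.append(gg)
        if len(gs) >= 3:
            sigma = np.std(gs, axis=0, ddof=1) / np.sqrt(len(gs))
            sigma = np.where(sigma > 0, sigma, np.nan)
            sigma = np.where(np.isnan(sigma), np.nanmax(sigma), sigma)
    return FcsCurve(lags=lags, G=g, sigma=sigma)


def diffusion_model(tau, G0, tau_d, kappa):
    """Single-component 3D Gaussian-volume diffusion autocorrelation."""
    return G0 / ((1.0 + tau / tau_d)
                 * np.sqrt(1.0 + tau / (kappa ** 2 * tau_d)))


def fit_diffusion(curve: FcsCurve, kappa_fixed: float = 5.0,
                  weighted: bool = False) -> FcsFit:
    """Least-squares fit of the 3D diffusion model with fixed kappa.

    ``weighted=True`` uses 1/sigma weights from the curve's block
    estimates; on short traces those sigma estimates are themselves so
    noisy that they bias tau_D low, so unweighted residuals are the
    default.
    """
    model = Model(diffusion_model)
    g0_init = max(float(curve.G[0]), 1e-6)
    # initial tau_d: lag where G first drops below half its initial value
    below = np.flatnonzero(curve.G < 0.5 * g0_init)
    tau_init = float(curve.lags[below[0]]) if len(below) else \
        float(curve.lags[len(curve.lags) // 2])
    params = model.make_params(G0=g0_init, tau_d=tau_init,
                               kappa=kappa_fixed)
    params["kappa"].vary = False
    params["G0"].min = 0
    params["tau_d"].min = 0
    weights = None
    if weighted and curve.sigma is not None:
        weights = 1.0 / curve.sigma
    result = model.fit(curve.G, params, tau=curve.lags, weights=weights)
    if not result.success:
        raise RuntimeError("diffusion fit did not converge; residuals: "
                           f"{np.asarray(result.residual)}")
    tau_d = float(result.params["tau_d"].value)
    if tau_d <= curve.lags[0] or tau_d >= curve.lags[-1]:
        warnings.warn("fitted tau_d lies at the lag-grid boundary")
    return FcsFit(G0=float(result.params["G0"].value), tau_d=tau_d,
                  kappa=kappa_fixed,
                  residual_norm=float(np.linalg.norm(result.residual)))


def expected_tau_d(diameter_nm: float, acq: AcquisitionParams) -> float:
    """Stokes-Einstein diffusion time w0^2/(4D) for a sphere, seconds."""
    d_m2s = stokes_einstein_diffusion(diameter_nm, acq.temperature,
                                      acq.viscosity)
    w0_m = acq.beam_waist * 1e-9
    return w0_m ** 2 / (4.0 * d_m2s)
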