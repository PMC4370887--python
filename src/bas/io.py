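"""Plain-text readers/writers for traces, burst tables, histograms and
run configuration.

All artifacts are diff-able text: traces and tables as CSV, metadata as
JSON sidecars, configuration as YAML. ``write_trace_npz`` offers an
optional single-file binary container for long traces.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .bursts import BurstEvent
from .histogram import BasHistogram
from .params import AcquisitionParams, FissionParams
from .trace import IntensityTrace

__all__ = [
    "write_trace", "read_trace", "write_trace_npz", "read_trace_npz",
    "write_bursts", "read_bursts", "write_histogram", "read_histogram",
    "write_manifest", "read_manifest", "load_config", "save_config",
]

_BURST_COLUMNS = ["start_s", "end_s", "amplitude", "peak", "n_bins"]
_HIST_COLUMNS = ["bin_lo", "bin_hi", "mean_intensity",
                 "concentration_pM", "n_events", "valid"]


def _sidecar(path: Union[str, Path]) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_trace(path: Union[str, Path], trace: IntensityTrace) -> None:
    """Write a trace as two-column CSV plus a JSON sidecar of its
    acquisition parameters (and ground truth, if attached)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "counts": trace.counts})
    df.to_csv(path, index=False)
    meta = {"acquisition": trace.acq.to_dict()}
    if trace.ground_truth is not None and len(trace.ground_truth):
        meta["ground_truth"] = {
            c: trace.ground_truth[c].tolist()
            for c in trace.ground_truth.columns}
    _sidecar(path).write_text(json.dumps(meta))


def read_trace(path: Union[str, Path]) -> IntensityTrace:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "counts"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column '{col}': {path}")
    if (df["counts"] < 0).any():
        line = int(df.index[df["counts"] < 0][0]) + 2
        raise ValueError(f"negative counts at line {line} of {path}")
    sidecar = _sidecar(path)
    acq = AcquisitionParams()
    gt = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        acq = AcquisitionParams.from_dict(meta.get("acquisition", {}))
        if "ground_truth" in meta:
            gt = pd.DataFrame(meta["ground_truth"])
    return IntensityTrace(times=df["time_s"].to_numpy(),
                          counts=df["counts"].to_numpy(),
                          acq=acq, ground_truth=gt)


def write_trace_npz(path: Union[str, Path], trace: IntensityTrace) -> None:
    """Optional compact container for long traces (binary, not text)."""
    np.savez_compressed(
        path, times=trace.times, counts=trace.counts,
        acq=json.dumps(trace.acq.to_dict()))


def read_trace_npz(path: Union[str, Path]) -> IntensityTrace:
    with np.load(path, allow_pickle=False) as z:
        acq = AcquisitionParams.from_dict(json.loads(str(z["acq"])))
        return IntensityTrace(times=z["times"], counts=z["counts"],
                              acq=acq)


def write_bursts(path: Union[str, Path],
                 bursts: Sequence[BurstEvent]) -> None:
    df = pd.DataFrame(
        [(b.start, b.end, b.amplitude, b.peak, b.n_bins) for b in bursts],
        columns=_BURST_COLUMNS)
    df.to_csv(path, index=False)


def read_bursts(path: Union[str, Path]) -> List[BurstEvent]:
    df = pd.read_csv(Path(path))
    for col in _BURST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"burst CSV missing column '{col}': {path}")
    return [BurstEvent(start=r.start_s, end=r.end_s, amplitude=r.amplitude,
                       peak=r.peak, n_bins=int(r.n_bins))
            for r in df.itertuples()]


def write_histogram(path: Union[str, Path], h: BasHistogram) -> None:
    df = pd.DataFrame({
        "bin_lo": h.bin_edges[:-1],
        "bin_hi": h.bin_edges[1:],
        "mean_intensity": h.mean_bin_intensity,
        "concentration_pM": h.concentration,
        "n_events": h.n_events,
        "valid": h.valid.astype(int),
    })
    df.to_csv(path, index=False)
    meta = {"dilution_factor": h.dilution_factor}
    if h.acq is not None:
        meta["acquisition"] = h.acq.to_dict()
    _sidecar(Path(path)).write_text(json.dumps(meta))


def read_histogram(path: Union[str, Path]) -> BasHistogram:
    path = Path(path)
    df = pd.read_csv(path)
    for col in _HIST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"histogram CSV missing column '{col}': {path}")
    if (df["concentration_pM"] < 0).any():
        line = int(df.index[df["concentration_pM"] < 0][0]) + 2
        raise ValueError(
            f"negative concentration_pM at line {line} of {path}")
    edges = np.append(df["bin_lo"].to_numpy(), df["bin_hi"].iloc[-1])
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    acq = AcquisitionParams.from_dict(meta["acquisition"]) \
        if "acquisition" in meta else None
    return BasHistogram(
        bin_edges=edges,
        concentration=df["concentration_pM"].to_numpy(),
        mean_bin_intensity=df["mean_intensity"].to_numpy(),
        n_events=df["n_events"].to_numpy(),
        dilution_factor=float(meta.get("dilution_factor", 1.0)),
        acq=acq,
        valid=df["valid"].to_numpy().astype(bool),
    )


def write_manifest(path: Union[str, Path], files: dict) -> None:
    """Manifest mapping artifact names to relative file paths."""
    Path(path).write_text(json.dumps({"files": files}, indent=2))


def read_manifest(path: Union[str, Path]) -> dict:
    path = Path(path)
    manifest = json.loads(path.read_text())
    files = manifest.get("files", {})
    for name, rel in files.items():
        target = path.parent / rel
        if not target.exists():
            raise FileNotFoundError(
                f"manifest entry '{name}' references missing file: {target}")
    return files


def save_config(path: Union[str, Path], acq: AcquisitionParams,
                fission: Optional[FissionParams] = None,
                extra: Optional[dict] = None) -> None:
    doc = {"acquisition": acq.to_dict()}
    if fission is not None:
        doc["fission"] = fission.to_dict()
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: Union[str, Path]
                ) -> Tuple[AcquisitionParams, Optional[FissionParams], dict]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    acq = AcquisitionParams.from_dict(doc.get("acquisition", {}))
    fission = FissionParams.from_dict(doc["fission"]) \
        if "fission" in doc else None
    extra = {k: v for k, v in doc.items()
             if k not in ("acquisition", "fission")}
    return acq, fission, extra
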