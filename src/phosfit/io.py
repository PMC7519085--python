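"""File formats: CSV spectra/FIDs with JSON metadata sidecars.

A spectrum file is a CSV with columns ``ppm, real, imag`` (full float
precision) plus a sidecar ``<stem>.json`` holding the acquisition parameters
and metadata — including, for synthetic data, the ground-truth
concentrations, so every file carries its own oracle.  FIDs use
``time_s, real, imag``.  Round trips are lossless to the last stored digit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .core import AcquisitionParams, Spectrum
from .errors import ParameterError
from .spins import BasisSpectrum

__all__ = [
    "write_spectrum", "read_spectrum", "write_fid", "read_fid",
    "write_basis", "sidecar_path", "sanitize_json",
]

_FLOAT_FMT = "%.17g"


def sanitize_json(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): sanitize_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [sanitize_json(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def _write_sidecar(path: Path, acq: AcquisitionParams | None, meta: dict) -> None:
    payload = {
        "acq": acq.to_dict() if acq is not None else None,
        "meta": sanitize_json(meta),
    }
    sidecar_path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _read_sidecar(path: Path) -> tuple[AcquisitionParams | None, dict]:
    sc = sidecar_path(path)
    if not sc.exists():
        raise ParameterError(f"missing metadata sidecar {sc}")
    payload = json.loads(sc.read_text())
    acq = AcquisitionParams.from_dict(payload["acq"]) if payload.get("acq") else None
    return acq, payload.get("meta", {})


def write_spectrum(spec: Spectrum, path: str | Path) -> Path:
    """Write spectrum CSV (ppm, real, imag) + JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({"ppm": spec.axis, "real": spec.real, "imag": spec.values.imag})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _write_sidecar(path, spec.acq, spec.meta)
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum CSV + sidecar; validates columns and axis monotonicity."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParameterError(f"malformed spectrum CSV {path}: {exc}") from exc
    for col in ("ppm", "real", "imag"):
        if col not in df.columns:
            raise ParameterError(f"spectrum CSV {path} missing column '{col}'")
    acq, meta = _read_sidecar(path)
    values = df["real"].to_numpy(float) + 1j * df["imag"].to_numpy(float)
    return Spectrum(values, df["ppm"].to_numpy(float), acq, meta)


def write_fid(
    fid: np.ndarray, acq: AcquisitionParams, path: str | Path,
    meta: dict | None = None,
) -> Path:
    path = Path(path)
    fid = np.asarray(fid, dtype=complex)
    df = pd.DataFrame({"time_s": acq.time_axis(), "real": fid.real, "imag": fid.imag})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _write_sidecar(path, acq, dict(meta or {}))
    return path


def read_fid(path: str | Path) -> tuple[np.ndarray, AcquisitionParams, dict]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "real", "imag"):
        if col not in df.columns:
            raise ParameterError(f"FID CSV {path} missing column '{col}'")
    acq, meta = _read_sidecar(path)
    if acq is None:
        raise ParameterError(f"FID sidecar for {path} lacks acquisition parameters")
    return df["real"].to_numpy(float) + 1j * df["imag"].to_numpy(float), acq, meta


def write_basis(basis: Iterable[BasisSpectrum], outdir: str | Path) -> list[Path]:
    """Export a basis set: one CSV per metabolite plus sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for b in basis:
        safe = b.metabolite.replace("+", "plus")
        path = outdir / f"basis_{safe}.csv"
        df = pd.DataFrame({"ppm": b.axis, "real": b.values.real, "imag": b.values.imag})
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        _write_sidecar(path, b.acq, {"metabolite": b.metabolite, "lw_used": b.lw_used,
                                     "mixing_eta": b.shape.mixing_eta})
        paths.append(path)
    return paths
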