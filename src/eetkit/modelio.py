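"""File formats: LVC model files, TA maps and trajectory tables.

Everything is plain text for diff-ability.  Model files are JSON with a
schema version and explicit unit annotations; TA maps are delimited tables
(first row the probe energies in eV, first column the delays in fs) with a
JSON metadata sidecar; trajectories are delimited tables with one column
per observable.  Numbers are written with 12 significant digits, so a
write/read round trip reproduces the model to that precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .kinetics import TAMap
from .quantum_dynamics import Trajectory
from .vibronic_model import ModelValidationError, VibronicModel

__all__ = [
    "ModelFileError",
    "SCHEMA_VERSION",
    "read_model",
    "write_model",
    "read_ta_map",
    "write_ta_map",
    "write_trajectory",
    "read_trajectory",
]

SCHEMA_VERSION = "1"
_FLOAT_FMT = "%.12g"


class ModelFileError(ValueError):
    """Malformed or version-incompatible model file."""


def _round12(x):
    """Recursively round floats to 12 significant digits for emission."""
    if isinstance(x, float):
        return float(f"{x:.12g}")
    if isinstance(x, (list, tuple)):
        return [_round12(v) for v in x]
    return x


def write_model(model: VibronicModel, path: Union[str, Path]) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "units": {"energy": "eV", "frequency": "cm^-1",
                  "coordinates": "dimensionless mass-frequency-scaled"},
        "state_labels": list(model.state_labels),
        "E": _round12(model.E.tolist()),
        "omega": _round12(model.omega.tolist()),
        "kappa": _round12(model.kappa.tolist()),
        "lam": _round12(model.lam.tolist()),
        "V0": _round12(model.V0.tolist()),
        "ablation": list(model.ablation),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_model(path: Union[str, Path]) -> VibronicModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"{path}: not valid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise ModelFileError(f"{path}: top level must be an object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelFileError(
            f"{path}: schema_version {version!r} not supported (expected {SCHEMA_VERSION!r})")
    for fieldname in ("state_labels", "E", "omega", "kappa", "lam", "V0"):
        if fieldname not in doc:
            raise ModelFileError(f"{path}: missing required field {fieldname!r}")
    try:
        return VibronicModel(
            state_labels=tuple(doc["state_labels"]),
            E=np.asarray(doc["E"], dtype=float),
            omega=np.asarray(doc["omega"], dtype=float),
            kappa=np.asarray(doc["kappa"], dtype=float),
            lam=np.asarray(doc["lam"], dtype=float),
            V0=np.asarray(doc["V0"], dtype=float),
            ablation=tuple(doc.get("ablation", ())),
        )
    except (ModelValidationError, ValueError) as exc:
        raise ModelFileError(f"{path}: {exc}") from exc


def write_ta_map(tamap: TAMap, path: Union[str, Path]) -> None:
    """Delimited map plus a ``<path>.meta.json`` sidecar with IRF/pump."""
    path = Path(path)
    header = "delay_fs\t" + "\t".join(_FLOAT_FMT % e for e in tamap.probe)
    lines = [header]
    for d, row in zip(tamap.delays, tamap.dA):
        lines.append(_FLOAT_FMT % d + "\t" + "\t".join(_FLOAT_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")
    meta = {"irf_fwhm_fs": _round12(float(tamap.irf_fwhm)),
            "pump_ev": _round12(float(tamap.pump_ev)),
            "dA_units": "mOD"}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def read_ta_map(path: Union[str, Path]) -> TAMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "delay_fs":
        raise ModelFileError(f"{path}: first column must be 'delay_fs'")
    delays = df["delay_fs"].to_numpy(dtype=float)
    probe = np.array([float(c) for c in df.columns[1:]])
    dA = df.iloc[:, 1:].to_numpy(dtype=float)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    irf_fwhm, pump_ev = 0.0, math.nan
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        irf_fwhm = float(meta.get("irf_fwhm_fs", 0.0))
        pump_ev = float(meta.get("pump_ev", math.nan))
    return TAMap(delays, probe, dA, irf_fwhm=irf_fwhm, pump_ev=pump_ev)


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
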