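"""Readers, writers and provenance: CSV for tabular series, JSON for
parameter objects, atomic writes throughout (temp file + rename, so an
interrupted rerun never leaves a half-written output)."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .calibration import MODALITIES, RadiusObservation
from .errors import ObservationError
from .solver import Kinetics, RadialField

__all__ = ["read_observations", "write_observations", "read_kinetics",
           "write_kinetics", "write_field_csv", "read_field_csv",
           "atomic_write_text", "provenance"]

OBS_COLUMNS = ["patient_id", "t_days", "modality", "radius_mm"]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a sibling temp file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    """Reproducibility block attached to every written result."""
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "gliomapi",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }


def read_observations(path: str | Path) -> list[RadiusObservation]:
    """Load an observation table (patient_id, t_days, modality, radius_mm),
    validated row by row and sorted by time."""
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationError(f"{path}: missing column(s) {missing}")
    obs = []
    for idx, row in df.iterrows():
        if row["modality"] not in MODALITIES:
            raise ObservationError(
                f"{path} row {idx}: unknown modality {row['modality']!r}")
        if not row["radius_mm"] >= 0:
            raise ObservationError(
                f"{path} row {idx}: negative radius {row['radius_mm']}")
        obs.append(RadiusObservation(
            t=float(row["t_days"]), modality=str(row["modality"]),
            radius=float(row["radius_mm"]),
            patient_id=str(row["patient_id"])))
    obs.sort(key=lambda o: (o.t, o.modality))
    return obs


def write_observations(path: str | Path, obs: Sequence[RadiusObservation]) -> None:
    df = pd.DataFrame({
        "patient_id": [o.patient_id or "" for o in obs],
        "t_days": [o.t for o in obs],
        "modality": [o.modality for o in obs],
        "radius_mm": [o.radius for o in obs],
    })
    atomic_write_text(path, df.to_csv(index=False))


def write_kinetics(path: str | Path, kinetics: Kinetics,
                   extra: dict | None = None, seed: int | None = None) -> None:
    payload = {
        "D_mm2_per_year": kinetics.D,
        "rho_per_year": kinetics.rho,
        "K_cells_per_mm3": kinetics.K,
        "velocity_mm_per_year": kinetics.velocity,
        "gradient_length_mm": kinetics.gradient_length,
        "rho_over_D_per_mm2": kinetics.rho_over_D,
    }
    if extra:
        payload.update(extra)
    payload["_provenance"] = provenance(seed=seed, config=payload)
    atomic_write_text(path, json.dumps(payload, indent=2) + "\n")


def read_kinetics(path: str | Path) -> Kinetics:
    with open(path) as fh:
        data = json.load(fh)
    return Kinetics(D=data["D_mm2_per_year"], rho=data["rho_per_year"],
                    K=data["K_cells_per_mm3"])


def write_field_csv(path: str | Path, field: RadialField) -> None:
    """Snapshot export: columns r_mm, c_cells_per_mm3, t_days."""
    df = pd.DataFrame({
        "r_mm": field.grid,
        "c_cells_per_mm3": field.density,
        "t_days": field.time,
    })
    atomic_write_text(path, df.to_csv(index=False))


def read_field_csv(path: str | Path, K: float) -> RadialField:
    df = pd.read_csv(path)
    return RadialField(df["r_mm"].to_numpy(), df["c_cells_per_mm3"].to_numpy(),
                       float(df["t_days"].iloc[0]), K)
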