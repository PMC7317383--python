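"""File formats: NIfTI volumes, schedule files, YAML configurations.

Offsets are stored in ppm (scanner centre frequency lives in the pool
configuration); schedule files are plain-text two-column tables
``offset_ppm  sat_flip_deg`` with ``#`` comments, and are the single
source of truth for the acquisition — points at |offset| >= 800 ppm are
reference (S0) volumes.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .pools import PoolSystem
from .sequence import AcquisitionSchedule, SaturationScheme

__all__ = [
    "save_volume",
    "load_volume",
    "read_schedule",
    "write_schedule",
    "load_zspectrum_stack",
    "load_pool_system",
    "save_pool_system",
    "load_scheme",
    "save_scheme",
    "provenance_record",
]


def save_volume(path, data, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_volume(path):
    """Returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_schedule(path, schedule: AcquisitionSchedule) -> None:
    with open(path, "w") as fh:
        fh.write("# offset_ppm  sat_flip_deg\n")
        for off, flip in zip(schedule.offsets_ppm, schedule.sat_flips_deg):
            fh.write(f"{off:.6g}  {flip:.6g}\n")


def read_schedule(path, ref_threshold_ppm: float = 800.0) -> AcquisitionSchedule:
    rows = np.loadtxt(path, comments="#", ndmin=2)
    if rows.shape[1] != 2:
        raise ValueError(f"schedule {path}: expected two columns, got {rows.shape[1]}")
    return AcquisitionSchedule(rows[:, 0], rows[:, 1], ref_threshold_ppm)


def load_zspectrum_stack(nifti_path, schedule_path):
    """Load a 4D stack together with its schedule; the volume count must
    match the schedule row count."""
    data, affine = load_volume(nifti_path)
    schedule = read_schedule(schedule_path)
    n_vol = data.shape[-1] if data.ndim == 4 else 1
    if n_vol != len(schedule):
        raise ValueError(
            f"schedule has {len(schedule)} rows but stack has {n_vol} volumes"
        )
    return data, affine, schedule


def save_pool_system(path, system: PoolSystem) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system.to_dict(), fh, sort_keys=False)


def load_pool_system(path) -> PoolSystem:
    with open(path) as fh:
        return PoolSystem.from_dict(yaml.safe_load(fh))


_SCHEME_FIELDS = (
    "n_pulses", "pulse_dur", "duty_cycle", "pulse_shape",
    "sat_flip_deg", "exc_flip_deg", "shot_interval", "t_s",
)


def save_scheme(path, scheme: SaturationScheme) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(scheme, k) for k in _SCHEME_FIELDS}, fh,
                       sort_keys=False)


def load_scheme(path) -> SaturationScheme:
    with open(path) as fh:
        return SaturationScheme(**yaml.safe_load(fh))


def provenance_record(config: dict, seed: int | None = None) -> dict:
    """Reproducibility sidecar: config hash, seed, versions."""
    import cestqmt

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "cestqmt": cestqmt.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
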