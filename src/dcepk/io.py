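"""NIfTI + JSON-sidecar I/O and the shared 4-D series container."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from dcepk.physics import AcquisitionParams, PKMaps, TimeGrid

__all__ = ["DCESeries", "read_dce", "write_dce", "write_maps", "read_maps", "write_mask", "read_mask"]

SIDECAR_SCHEMA_VERSION = 1

_REQUIRED_SIDECAR = ("tr_s", "flip_deg", "r1", "t10_s", "dt_min", "n_baseline")


@dataclass
class DCESeries:
    """A 4-D DCE signal-intensity series with acquisition metadata.

    ``data`` is (x, y, z, t); the time axis length must equal the grid's frame
    count.  Geometry is carried by the RAS+ ``affine``.
    """

    data: np.ndarray
    grid: TimeGrid
    acq: AcquisitionParams
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = "subject-0"
    extra_sidecar: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DCE data must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[-1] != self.grid.n_frames:
            raise ValueError("time axis length does not match the time grid")

    @property
    def shape(self):
        return self.data.shape

    def sidecar(self) -> dict:
        sc = {
            "schema_version": SIDECAR_SCHEMA_VERSION,
            "tr_s": self.acq.tr_s,
            "flip_deg": self.acq.flip_deg,
            "r1": self.acq.r1,
            "t10_s": self.acq.t10_s,
            "s0_scale": self.acq.s0_scale,
            "dt_min": self.grid.dt,
            "n_baseline": self.grid.n_baseline,
            "subject_id": self.subject_id,
        }
        sc.update(self.extra_sidecar)  # unknown keys survive round-trips
        return sc


def _validate_sidecar(sc: dict, path) -> None:
    missing = [k for k in _REQUIRED_SIDECAR if k not in sc]
    if missing:
        raise ValueError(f"sidecar {path} missing keys: {missing}")
    for k in ("tr_s", "flip_deg", "r1", "t10_s", "dt_min"):
        if sc[k] <= 0:
            raise ValueError(f"sidecar {path}: {k} must be positive, got {sc[k]}")
    if sc["n_baseline"] < 1:
        raise ValueError(f"sidecar {path}: n_baseline must be >= 1")


def write_dce(series: DCESeries, path) -> Path:
    """Write ``<path>.nii.gz`` (or given suffix) plus ``<stem>.json`` sidecar."""
    path = Path(path)
    if not path.suffixes:
        path = path.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(series.data.astype(np.float32), series.affine), str(path))
    sidecar_path = path.parent / (path.name.split(".")[0] + ".json")
    sidecar_path.write_text(json.dumps(series.sidecar(), indent=2))
    return path


def read_dce(path) -> DCESeries:
    """Read a 4-D NIfTI and its JSON sidecar; validates before any computation."""
    path = Path(path)
    sidecar_path = path.parent / (path.name.split(".")[0] + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar not found for {path}: {sidecar_path}")
    sc = json.loads(sidecar_path.read_text())
    _validate_sidecar(sc, sidecar_path)
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got {img.ndim}-D")
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = TimeGrid.uniform(n_frames=data.shape[-1], dt=sc["dt_min"], n_baseline=sc["n_baseline"])
    acq = AcquisitionParams.from_sidecar(sc)
    known = set(_REQUIRED_SIDECAR) | {"schema_version", "s0_scale", "subject_id"}
    extra = {k: v for k, v in sc.items() if k not in known}
    return DCESeries(
        data=data,
        grid=grid,
        acq=acq,
        affine=img.affine,
        subject_id=sc.get("subject_id", path.name.split(".")[0]),
        extra_sidecar=extra,
    )


def write_maps(maps: PKMaps, out_dir, prefix: str = "", affine=None) -> dict:
    """Write the three parameter maps as ``<prefix><param>.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    paths = {}
    for name in PKMaps.PARAMS:
        p = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(maps[name].astype(np.float32), affine), str(p))
        paths[name] = p
    return paths


def read_maps(out_dir, prefix: str = "") -> PKMaps:
    out_dir = Path(out_dir)
    arrays = {}
    for name in PKMaps.PARAMS:
        arrays[name] = np.asarray(nib.load(str(out_dir / f"{prefix}{name}.nii.gz")).get_fdata())
    return PKMaps(**arrays)


def write_mask(mask: np.ndarray, path, affine=None) -> Path:
    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))
    return path


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5
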