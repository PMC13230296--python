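"""Volume/mask I/O and grid-geometry bookkeeping.

Volumes are NIfTI-1/2 with attenuation in Hounsfield units (HU); masks are
integer NIfTI grids aligned voxel-for-voxel with their volume (0 background,
1 foreground for binary masks, 1..6 branch codes for labelled masks), and
probability maps are float grids in [0, 1].  All downstream geometry is
computed in world millimetres through the affine; no axis reordering is
applied silently.  HU values are used as stored (NIfTI assumed pre-scaled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd

#: canonical branch codes for the six coronary segments under audit
BRANCH_CODES = {"LM": 1, "LAD": 2, "LCx": 3, "D1": 4, "OM1": 5, "RCA": 6}
BRANCH_NAMES = {v: k for k, v in BRANCH_CODES.items()}

_ALIGN_RTOL = 1e-4


@dataclass
class CTVolume:
    """A 3D CT attenuation field (HU) with voxel spacing and world affine."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"{self.id or 'volume'}: expected 3D volume, got rank {self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.id or 'volume'}: non-finite voxel values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"{self.id or 'volume'}: spacing must be positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world-mm coordinates via the affine."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ pts.T).T + inv[:3, 3]


@dataclass
class Mask:
    """Binary, branch-labelled or probability voxel grid on a CTVolume grid."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    kind: Literal["binary", "labelled", "probability"] = "binary"
    id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"{self.id or 'mask'}: expected 3D mask, got rank {self.labels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.kind == "probability":
            if self.labels.min() < 0 or self.labels.max() > 1:
                raise ValueError("probability mask values must lie in [0, 1]")
        else:
            if np.any(self.labels < 0):
                raise ValueError("mask labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        """Boolean foreground array (labels > 0, or probability >= 0.5)."""
        if self.kind == "probability":
            return self.labels >= 0.5
        return self.labels > 0

    def binarized(self) -> "Mask":
        return Mask(self.foreground().astype(np.uint8), self.spacing, self.affine, "binary", self.id)

    # convenience mirrors of CTVolume's coordinate maps
    voxel_to_world = CTVolume.voxel_to_world
    world_to_voxel = CTVolume.world_to_voxel


@dataclass
class CaseMeta:
    """Per-case metadata: sex, calcium score and cohort membership."""

    id: str
    sex: Literal["male", "female"]
    calcium_score: float = 0.0
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.id}: sex must be 'male' or 'female', got {self.sex!r}")
        if self.calcium_score < 0:
            raise ValueError(f"{self.id}: calcium_score must be >= 0")


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def read_volume(path: str | Path) -> CTVolume:
    """Read a 3D NIfTI volume as floating HU.

    Spacing is derived from the affine column norms.  4D inputs and
    non-finite voxels are rejected with a message naming the case.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected 3D volume, got rank {data.ndim}")
    affine = np.asarray(img.affine, dtype=float)
    return CTVolume(data.astype(np.float32, copy=False), _spacing_from_affine(affine), affine, id=_case_id(path))


def read_mask(path: str | Path, kind: str = "binary") -> Mask:
    """Read a NIfTI mask/probability map of the stated kind."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected 3D mask, got rank {data.ndim}")
    affine = np.asarray(img.affine, dtype=float)
    if kind == "probability":
        data = data.astype(np.float32, copy=False)
    else:
        data = np.rint(data).astype(np.uint16)
    return Mask(data, _spacing_from_affine(affine), affine, kind, id=_case_id(path))


def write_volume(vol: CTVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), vol.affine), str(path))


def write_mask(mask: Mask, path: str | Path) -> None:
    if mask.kind == "probability":
        data = mask.labels.astype(np.float32)
    else:
        data = mask.labels.astype(np.uint16 if mask.labels.max() > 255 else np.uint8)
    nib.save(nib.Nifti1Image(data, mask.affine), str(path))


def read_meta(path: str | Path) -> list[CaseMeta]:
    """Read per-case metadata CSV with columns id,sex,calcium_score,cohort."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "sex", "calcium_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    if "cohort" not in df.columns:
        df["cohort"] = ""
    return [
        CaseMeta(str(r.id), str(r.sex).lower(), float(r.calcium_score), str(r.cohort))
        for r in df.itertuples()
    ]


def write_meta(metas: list[CaseMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": m.id, "sex": m.sex, "calcium_score": m.calcium_score, "cohort": m.cohort} for m in metas]
    ).to_csv(path, index=False)


def check_aligned(a: CTVolume | Mask, b: CTVolume | Mask) -> None:
    """Raise unless the two grids share shape, spacing and affine.

    Spacing and affine are compared within 1e-4 relative tolerance; the
    error names the differing attribute.  Symmetric in its arguments.
    """
    sa = a.values.shape if isinstance(a, CTVolume) else a.labels.shape
    sb = b.values.shape if isinstance(b, CTVolume) else b.labels.shape
    if sa != sb:
        raise ValueError(f"shape mismatch: {sa} vs {sb}")
    if not np.allclose(a.spacing, b.spacing, rtol=_ALIGN_RTOL, atol=0):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    scale = max(1.0, float(np.abs(a.affine).max()), float(np.abs(b.affine).max()))
    if not np.allclose(a.affine, b.affine, rtol=_ALIGN_RTOL, atol=_ALIGN_RTOL * scale):
        raise ValueError("affine mismatch between image and mask")


def _case_id(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem
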