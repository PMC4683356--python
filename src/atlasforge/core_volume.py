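"""Volume data model, NIfTI I/O, and grid resampling.

Conventions shared by every other module:

* voxel indices are 0-based;
* world coordinates are RAS+ millimetres;
* the 4x4 voxel-to-world affine is the single source of geometry — no
  header side channels;
* inter-image operations require geometry agreement; callers resample
  explicitly, nothing resamples silently.

Displacement fields are stored as 4-D NIfTI volumes with the vector
dimension last (3 components, world-mm RAS+ displacement).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Raised when an image violates the data-model invariants."""


def _check_geometry(data: np.ndarray, affine: np.ndarray, ndim: int = 3) -> None:
    if data.ndim != ndim:
        raise VolumeError(f"expected a {ndim}-D grid, got shape {data.shape}")
    if any(s < 2 for s in data.shape[:3]):
        raise VolumeError(f"all grid dimensions must be >= 2, got {data.shape}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise VolumeError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeError("affine is singular")


@dataclass
class Volume:
    """A dense 3-D scalar grid with voxel-to-world geometry.

    Parameters
    ----------
    data
        3-D float array of intensities (arbitrary units).
    affine
        4x4 voxel-index -> world-mm (RAS+) map.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_geometry(self.data, self.affine)
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains NaN/Inf voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm: column norms of the affine's 3x3 block."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_grid_as(self, other: "Volume | LabelMap | BrainMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)


@dataclass
class LabelMap:
    """An integer-valued segmentation on a Volume grid; 0 is background."""

    data: np.ndarray
    affine: np.ndarray
    label_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise VolumeError("label map has non-integer values")
            arr = np.round(arr).astype(np.int32)
        if arr.min() < 0:
            raise VolumeError("label values must be non-negative")
        self.data = arr.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_geometry(self.data, self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def labels(self) -> np.ndarray:
        return np.unique(self.data)

    def same_grid_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)


@dataclass
class BrainMask:
    """A binary foreground mask; at least one foreground voxel."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise VolumeError("mask values must be 0/1")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_geometry(self.data, self.affine)
        if self.data.sum() == 0:
            raise VolumeError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def centroid_world(self) -> np.ndarray:
        """World-mm centroid of the foreground voxels."""
        ijk = np.mean(np.argwhere(self.data > 0), axis=0)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)


@dataclass
class SubjectRecord:
    """One cohort entry: a volume on disk plus demographics."""

    id: str
    age_years: float
    sex: str
    scanner: str
    volume_path: str
    mask_path: str | None = None
    labels_path: str | None = None
    # optional in-memory images (not serialized in the manifest)
    volume: "Volume | None" = None
    mask: "BrainMask | None" = None
    labels: "LabelMap | None" = None

    def load_volume(self) -> Volume:
        if self.volume is not None:
            return self.volume
        return read_volume(self.volume_path)

    def load_mask(self) -> BrainMask | None:
        if self.mask is not None:
            return self.mask
        if self.mask_path is None:
            return None
        lm = read_volume(self.mask_path, kind="label")
        return BrainMask((lm.data > 0).astype(np.uint8), lm.affine)

    def load_labels(self) -> LabelMap | None:
        if self.labels is not None:
            return self.labels
        if self.labels_path is None:
            return None
        return read_volume(self.labels_path, kind="label")


@dataclass
class Cohort:
    """A list of subject records plus the manifest location they came from."""

    subjects: list[SubjectRecord]
    manifest_path: str | None = None

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def ages(self) -> np.ndarray:
        return np.array([s.age_years for s in self.subjects], dtype=float)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, kind: str = "scalar") -> Volume | LabelMap:
    """Read a 3-D scalar NIfTI-1 file.

    Parameters
    ----------
    path
        A ``.nii`` / ``.nii.gz`` file.
    kind
        ``"scalar"`` returns a :class:`Volume`; ``"label"`` returns a
        :class:`LabelMap` (values must be non-negative integers).

    Raises
    ------
    VolumeError
        For missing files, non-3-D images, or NaN/Inf voxels; the message
        names the offending file.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3-D scalar image, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise VolumeError(f"{path}: volume contains NaN/Inf voxels")
    if kind == "label":
        return LabelMap(data, img.affine)
    return Volume(data.astype(np.float32), img.affine)


def write_volume(image: Volume | LabelMap | BrainMask, path: str | Path) -> None:
    """Write an image as NIfTI-1; dtype follows the in-memory container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, Volume):
        arr = image.data.astype(np.float32)
    else:
        arr = image.data.astype(np.int16)
    nib.save(nib.Nifti1Image(arr, image.affine), str(path))


def read_field(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a displacement field (4-D NIfTI, vector dim last, world mm).

    Returns ``(displacement[x,y,z,3], affine)``.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 4 or data.shape[-1] != 3:
        raise VolumeError(f"{path}: expected a 4-D displacement field with 3 components")
    if not np.all(np.isfinite(data)):
        raise VolumeError(f"{path}: field contains NaN/Inf")
    return data.astype(np.float64), img.affine


def write_field(displacement: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _check_geometry(np.asarray(displacement), affine, ndim=4)
    nib.save(nib.Nifti1Image(np.asarray(displacement, dtype=np.float32), affine), str(path))


def read_manifest(path: str | Path) -> Cohort:
    """Load a cohort manifest: a JSON array of subject records.

    Relative volume/mask/label paths are resolved against the manifest's
    directory.
    """
    path = Path(path)
    with open(path) as fh:
        entries = json.load(fh)
    base = path.parent
    subjects = []
    for e in entries:
        def _resolve(p):
            if p is None:
                return None
            q = Path(p)
            return str(q if q.is_absolute() else (base / q).resolve())

        subjects.append(
            SubjectRecord(
                id=str(e["id"]),
                age_years=float(e["age_years"]),
                sex=str(e.get("sex", "")),
                scanner=str(e.get("scanner", "")),
                volume_path=_resolve(e["volume_path"]),
                mask_path=_resolve(e.get("mask_path")),
                labels_path=_resolve(e.get("labels_path")),
            )
        )
    return Cohort(subjects, manifest_path=str(path))


def write_manifest(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        rows.append(
            {
                "id": s.id,
                "age_years": s.age_years,
                "sex": s.sex,
                "scanner": s.scanner,
                "volume_path": s.volume_path,
                "mask_path": s.mask_path,
                "labels_path": s.labels_path,
            }
        )
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _sample_at_world(data: np.ndarray, affine: np.ndarray, xyz: np.ndarray,
                     order: int, cval: float = 0.0, mode: str = "constant") -> np.ndarray:
    """Sample ``data`` (with voxel->world ``affine``) at world points ``xyz``."""
    inv = np.linalg.inv(affine)
    ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
    return ndimage.map_coordinates(
        np.asarray(data, dtype=np.float64), ijk.T, order=order,
        mode=mode, cval=cval, prefilter=False,
    )


def target_world_points(shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
    """World-mm coordinates of every voxel centre of a grid, shape (N, 3)."""
    idx = np.indices(shape[:3]).reshape(3, -1).T.astype(float)
    return idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def resample(image: Volume | LabelMap | BrainMask,
             target_shape: Sequence[int],
             target_affine: np.ndarray,
             interpolation: str = "linear"):
    """Resample an image onto a target grid.

    Out-of-field voxels are set to 0.  Label maps and masks must use
    nearest-neighbour interpolation so no label id is invented.
    """
    is_label = isinstance(image, (LabelMap, BrainMask))
    if is_label and interpolation != "nearest":
        raise VolumeError("label/mask images must be resampled with nearest interpolation")
    if interpolation not in ("linear", "nearest"):
        raise VolumeError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    xyz = target_world_points(target_shape, target_affine)
    out = _sample_at_world(image.data, image.affine, xyz, order=order)
    out = out.reshape(tuple(target_shape[:3]))
    if isinstance(image, LabelMap):
        return LabelMap(np.round(out).astype(np.int32), np.asarray(target_affine, float),
                        dict(image.label_table))
    if isinstance(image, BrainMask):
        arr = np.round(out).astype(np.uint8)
        if arr.sum() == 0:  # keep the invariant visible rather than erroring downstream
            raise VolumeError("resampled mask lost all foreground voxels")
        return BrainMask(arr, np.asarray(target_affine, float))
    return Volume(out.astype(np.float32), np.asarray(target_affine, float))
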