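"""Volume, mask and table I/O plus all voxel-grid geometry.

Conventions
-----------
* Voxel indices are 0-based; affines map voxel index -> scanner mm in the
  NIfTI sense (``world = A[:3, :3] @ ijk + A[:3, 3]``).
* The anatomical (1H) and fluorine (19F) slice stacks share field of view,
  stack centre and orientation, as prescribed at acquisition; they differ in
  matrix size and slice thickness/gap.  Slice gaps enter through the affine's
  slice-direction spacing (thickness + gap).
* All volumes are written/read as NIfTI via nibabel; tables as CSV; configs
  as YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GridSpec",
    "ANATOMICAL_GRID",
    "FLUORINE_GRID",
    "MagnitudeSeries",
    "RoiSet",
    "validate_design_table",
    "load_series",
    "save_series",
    "load_volume",
    "save_volume",
    "resample_between_grids",
    "resample_mask_nearest",
    "roi_centroids_world",
]

# Study acquisition geometry: shared FOV 39.2 x 51.2 mm, shared stack centre.
# 1H RARE: 196 x 256 in-plane, 20 slices of 1 mm with 0.2 mm gap.
# 19F saturation-recovery RARE: 64 x 84 in-plane, 8 slices of 2 mm with
# 0.4 mm gap.


@dataclass(frozen=True)
class GridSpec:
    """A regular voxel grid: matrix size and voxel spacing (mm).

    ``spacing`` along the slice axis is thickness + gap, so voxel centres of
    adjacent slices are one spacing apart.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def affine(self) -> np.ndarray:
        """Voxel-index -> world-mm affine placing the grid centre at
        ``center_mm``."""
        A = np.eye(4)
        A[0, 0], A[1, 1], A[2, 2] = self.spacing
        half = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        A[:3, 3] = np.asarray(self.center_mm) - np.asarray(self.spacing) * half
        return A

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinate arrays (broadcastable) of every voxel centre."""
        A = self.affine()
        axes = [np.arange(n, dtype=float) for n in self.shape]
        xs = A[0, 0] * axes[0] + A[0, 3]
        ys = A[1, 1] * axes[1] + A[1, 3]
        zs = A[2, 2] * axes[2] + A[2, 3]
        return (
            xs[:, None, None],
            ys[None, :, None],
            zs[None, None, :],
        )


ANATOMICAL_GRID = GridSpec(shape=(196, 256, 20), spacing=(39.2 / 196, 51.2 / 256, 1.2))
FLUORINE_GRID = GridSpec(shape=(64, 84, 8), spacing=(39.2 / 64, 51.2 / 84, 2.4))


@dataclass
class MagnitudeSeries:
    """Multi-TR magnitude volumes on one grid.

    Attributes
    ----------
    tr_ms : (n_tr,) float array, strictly increasing.
    volumes : (n_tr, nx, ny, nz) float array of nonnegative magnitudes.
    affine : (4, 4) voxel -> world-mm affine shared by all volumes.
    meta : free-form acquisition metadata (nucleus, matrix, thickness/gap...).
    """

    tr_ms: np.ndarray
    volumes: np.ndarray
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tr_ms = np.asarray(self.tr_ms, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.volumes.ndim != 4 or self.volumes.shape[0] != self.tr_ms.size:
            raise ValueError("volumes must be (n_tr, nx, ny, nz) matching tr_ms")
        if np.any(np.diff(self.tr_ms) <= 0):
            raise ValueError("TRs must be strictly increasing")
        if np.any(self.tr_ms <= 0):
            raise ValueError("TRs must be positive")
        if np.any(self.volumes < 0):
            raise ValueError("magnitude intensities must be >= 0")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    def volume_at(self, tr_ms: float) -> np.ndarray:
        """The 3-D volume acquired at the given TR (exact match, ms)."""
        idx = np.flatnonzero(np.isclose(self.tr_ms, tr_ms))
        if idx.size == 0:
            raise KeyError(f"no volume with TR = {tr_ms} ms")
        return self.volumes[idx[0]]


@dataclass
class RoiSet:
    """Integer label volume (anatomical grid) naming each placenta.

    ``label_map`` maps placenta label -> (mother_id, placenta_id);
    ``background_label``, if set, marks the signal-free noise ROI.  Label 0
    is unlabelled tissue; -1 is reserved and never used.
    """

    labels: np.ndarray
    affine: np.ndarray
    label_map: dict[int, tuple[str, str]]
    background_label: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("ROI labels must be integer")
        if np.any(self.labels == -1):
            raise ValueError("label -1 is reserved")
        for lab in self.label_map:
            if lab <= 0:
                raise ValueError("placenta labels must be positive integers")

    @property
    def placenta_labels(self) -> list[int]:
        return sorted(self.label_map)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def validate_design_table(design: pd.DataFrame) -> pd.DataFrame:
    """Check the study design table contract.

    One row per mother x oxygen condition; genotype in {WT, KO} and constant
    within mother; (mother_id, oxygen_percent) unique.
    """
    required = {"mother_id", "genotype", "oxygen_percent"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    bad = set(design["genotype"]) - {"WT", "KO"}
    if bad:
        raise ValueError(f"unknown genotype values: {sorted(bad)}")
    if design.duplicated(["mother_id", "oxygen_percent"]).any():
        raise ValueError("(mother_id, oxygen_percent) rows must be unique")
    per_mother = design.groupby("mother_id")["genotype"].nunique()
    if (per_mother > 1).any():
        raise ValueError("genotype must be constant within mother")
    return design


# ---------------------------------------------------------------------------
# NIfTI round-trips


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def save_series(series: MagnitudeSeries, directory: str | Path, stem: str) -> list[Path]:
    """Write one 3-D NIfTI per TR plus a JSON sidecar with TRs and metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr, vol in zip(series.tr_ms, series.volumes):
        p = directory / f"{stem}_tr-{int(round(tr)):04d}.nii.gz"
        save_volume(p, vol, series.affine)
        paths.append(p)
    sidecar = directory / f"{stem}_series.json"
    sidecar.write_text(
        json.dumps(
            {"tr_ms": list(map(float, series.tr_ms)), "meta": series.meta,
             "files": [p.name for p in paths]},
            indent=2,
        )
    )
    return paths


def load_series(
    paths: Sequence[str | Path],
    tr_list_ms: Sequence[float],
    affine_tol: float = 1e-4,
    meta: Mapping | None = None,
) -> MagnitudeSeries:
    """Load per-TR magnitude volumes into a validated series.

    Volumes are sorted by TR.  All files must share matrix size and affine
    (within ``affine_tol``); a mismatch is an error, not a warning, because
    downstream SNR maps assume one grid.
    """
    if len(paths) != len(tr_list_ms):
        raise ValueError("need exactly one TR per volume path")
    order = np.argsort(tr_list_ms)
    vols, affine = [], None
    for i in order:
        data, aff = load_volume(paths[i])
        if data.ndim != 3:
            raise ValueError(f"{paths[i]}: expected a 3-D volume")
        if affine is None:
            affine, shape = aff, data.shape
        else:
            if data.shape != shape:
                raise ValueError("matrix size differs between TR volumes")
            if np.max(np.abs(aff - affine)) > affine_tol:
                raise ValueError("affine differs between TR volumes")
        vols.append(data)
    return MagnitudeSeries(
        tr_ms=np.asarray(tr_list_ms, dtype=float)[order],
        volumes=np.stack(vols),
        affine=affine,
        meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# Resampling between the 19F and anatomical grids


def _check_invertible(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("singular affine")
    return affine


def resample_between_grids(
    volume: np.ndarray,
    source_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    order: int = 3,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``volume`` onto a target grid through world coordinates.

    ``order=3`` is the default (cubic spline, the "bicubic" interpolation of
    the original analysis); ``order=0`` gives nearest-neighbour for mask
    transport.  Voxels mapping outside the source grid take ``cval``.
    """
    source_affine = _check_invertible(source_affine)
    target_affine = _check_invertible(target_affine)
    M = np.linalg.inv(source_affine) @ target_affine
    return ndimage.affine_transform(
        np.asarray(volume, dtype=float),
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=cval,
    )


def resample_mask_nearest(
    mask: np.ndarray,
    source_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> np.ndarray:
    """Nearest-neighbour transport of an integer/boolean mask between grids."""
    out = resample_between_grids(
        np.asarray(mask, dtype=float), source_affine, target_shape,
        target_affine, order=0, cval=0.0,
    )
    return out.astype(np.asarray(mask).dtype)


def roi_centroids_world(labels: np.ndarray, affine: np.ndarray) -> dict[int, np.ndarray]:
    """World-mm centroid of every positive label in a label volume."""
    affine = np.asarray(affine, dtype=float)
    out = {}
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        ijk = np.mean(np.argwhere(labels == lab), axis=0)
        out[int(lab)] = affine[:3, :3] @ ijk + affine[:3, 3]
    return out
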