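"""Volume, mask and seed I/O with grid-consistency contracts.

All images are 3D lattices addressed by 0-based voxel indices ``(i, j, k)``
in array order. World/affine coordinates are carried only as metadata and
never enter any computation: the segmentation algorithm is purely
lattice-based. Every downstream stage rejects grid-inconsistent inputs;
there is no silent resampling anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "SwiVolume",
    "SegmentationMask",
    "SeedSet",
    "GridConsistencyError",
    "read_volume",
    "read_mask",
    "write_mask",
    "write_volume",
    "read_seeds",
    "write_seeds",
    "default_slice_axis",
]


class GridConsistencyError(ValueError):
    """Two grids that must match (shape and spacing) do not."""


def _validate_grid(data: np.ndarray, spacing: tuple, slice_axis: int) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected 3D data, got {data.ndim}D")
    if any(s < 1 for s in data.shape):
        raise ValueError(f"every axis must have extent >= 1, got shape {data.shape}")
    if len(spacing) != 3:
        raise ValueError("spacing must have three components (dx, dy, dz)")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive and finite, got {spacing}")
    if slice_axis not in (0, 1, 2):
        raise ValueError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")


@dataclass
class SwiVolume:
    """A 3D susceptibility-weighted magnitude image.

    Parameters
    ----------
    data
        3D scalar intensity array (arbitrary units).
    spacing
        Voxel spacing ``(dx, dy, dz)`` in millimetres, all strictly positive.
    slice_axis
        Index of the through-plane axis; 2D filtering operates on slices
        taken perpendicular to this axis.
    meta
        Free-form provenance (source path, description, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        _validate_grid(self.data, self.spacing, self.slice_axis)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class SegmentationMask:
    """A binary mask on the same lattice as the volume it derives from."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(
                    "mask values must be strictly binary; "
                    f"found values {uniq[:10]}"
                )
            data = data.astype(bool)
        self.data = data
        self.spacing = tuple(float(s) for s in self.spacing)
        _validate_grid(self.data, self.spacing, self.slice_axis)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def count(self) -> int:
        return int(self.data.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentationMask):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and bool(np.array_equal(self.data, other.data))
        )


@dataclass
class SeedSet:
    """0-based voxel coordinates marking where region growing starts."""

    seeds: list[tuple[int, int, int]]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        clean = []
        for s in self.seeds:
            if len(s) != 3:
                raise ValueError(f"seed must be an (i, j, k) triple, got {s}")
            for c in s:
                if float(c) != int(c):
                    raise ValueError(f"seed coordinates must be integers, got {s}")
            clean.append(tuple(int(c) for c in s))
        self.seeds = clean
        if self.labels is not None and len(self.labels) != len(self.seeds):
            raise ValueError("labels must be co-indexed with seeds")

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def validate_against(self, shape: Sequence[int]) -> "SeedSet":
        for s in self.seeds:
            if any(c < 0 or c >= n for c, n in zip(s, shape)):
                raise IndexError(
                    f"seed {s} is out of bounds for grid of shape {tuple(shape)}"
                )
        return self


def check_same_grid(a, b, what: str = "input") -> None:
    """Raise :class:`GridConsistencyError` unless a and b share shape & spacing."""
    if a.shape != b.shape:
        raise GridConsistencyError(
            f"{what}: shape {b.shape} does not match reference {a.shape}"
        )
    if not np.allclose(a.spacing, b.spacing, rtol=1e-5):
        raise GridConsistencyError(
            f"{what}: spacing {b.spacing} does not match reference {a.spacing}"
        )


def default_slice_axis(spacing: Sequence[float]) -> int:
    """The through-plane axis, by convention the axis of coarsest spacing.

    Clinical SWI is acquired with the coarsest spacing along the slice
    direction (e.g. 0.6 x 0.6 mm in-plane, 1 mm through-plane). Ties break
    toward the last axis, the conventional slice direction in NIfTI.
    """
    spacing = np.asarray(spacing, dtype=float)
    return int(2 - np.argmax(spacing[::-1]))


def _header_spacing(img, path) -> tuple[float, float, float]:
    """Voxel spacing from a NIfTI header, canonicalised to 6 significant
    digits: the format stores pixdim as float32, and without rounding a
    0.6 mm spacing would come back as 0.60000002..., breaking bit-exact
    round-trips and clean voxel-volume arithmetic."""
    zooms = img.header.get_zooms()[:3]
    if not all(np.isfinite(z) and z > 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing in header: {zooms}")
    return tuple(float(f"{z:.6g}") for z in zooms)


def _squeeze_3d(data: np.ndarray, path) -> np.ndarray:
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected 3D image data (or 4D with singleton), got shape {data.shape}"
        )
    return data


def read_volume(path, slice_axis: int | None = None) -> SwiVolume:
    """Read a NIfTI-1 volume; spacing comes from the header.

    ``slice_axis`` defaults to the coarsest-spacing axis (see
    :func:`default_slice_axis`); pass it explicitly to override.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = _squeeze_3d(np.asanyarray(img.dataobj), path)
    spacing = _header_spacing(img, path)
    if slice_axis is None:
        slice_axis = default_slice_axis(spacing)
    return SwiVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        slice_axis=slice_axis,
        meta={"source": str(path), "affine": img.affine.tolist()},
    )


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: SwiVolume, path) -> None:
    """Write a volume as NIfTI-1 with spacing in the header."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path, reference: SwiVolume | SegmentationMask) -> SegmentationMask:
    """Read a binary mask and enforce grid consistency with ``reference``.

    Any non-zero voxel value is a member: rater-exported masks frequently
    use 255 or label integers for membership.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = _squeeze_3d(np.asanyarray(img.dataobj), path)
    mask = SegmentationMask(
        data=data != 0,
        spacing=_header_spacing(img, path),
        slice_axis=reference.slice_axis,
        meta={"source": str(path)},
    )
    check_same_grid(reference, mask, what=str(path))
    return mask


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a mask as uint8 {0,1} NIfTI-1; round-trips bit-exactly."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_seeds(path, reference: SwiVolume | SegmentationMask) -> SeedSet:
    """Read seeds from CSV (columns i,j,k) or JSON (array of triples)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        raw = json.loads(text)
        triples = [tuple(t) for t in raw]
        labels = None
    else:
        import pandas as pd

        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if not {"i", "j", "k"}.issubset(cols):
            raise ValueError(f"{path}: seed CSV must have columns i,j,k")
        triples = list(zip(df["i"], df["j"], df["k"]))
        labels = list(df["label"].astype(str)) if "label" in cols else None
    seeds = SeedSet(seeds=[tuple(int(c) for c in _int_triple(t, path)) for t in triples],
                    labels=labels)
    return seeds.validate_against(reference.shape)


def _int_triple(t, path):
    if len(t) != 3:
        raise ValueError(f"{path}: seed {t} is not an (i, j, k) triple")
    for c in t:
        if float(c) != int(c):
            raise ValueError(f"{path}: non-integer seed coordinate in {t}")
    return t


def write_seeds(seeds: SeedSet, path) -> None:
    """Write seeds as CSV with columns i,j,k (and label when present)."""
    import pandas as pd

    df = pd.DataFrame(seeds.seeds, columns=["i", "j", "k"])
    if seeds.labels is not None:
        df["label"] = seeds.labels
    df.to_csv(path, index=False)
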