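"""Scalar volume container, file IO, resampling and phantom segmentation.

``DensityVolume`` is the package's in-memory image: a 3D array indexed
(x, y, z) with per-axis spacing and origin in millimetres, plus a unit tag
(``HU``, ``mg/cm3``, ``label`` or ``dimensionless``).  File IO goes through
SimpleITK, which covers NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "DensityVolume", "read_volume", "write_volume", "resample",
    "segment_phantom", "dice", "FormatError",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


class FormatError(ValueError):
    """Unsupported or unreadable image container."""


@dataclass
class DensityVolume:
    """3D scalar grid with world geometry.

    values are indexed ``[ix, iy, iz]``; world = origin + index * spacing.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    unit: str = "dimensionless"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        self.origin = np.asarray(self.origin, float).reshape(3).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    # geometry --------------------------------------------------------------
    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_extent(self) -> np.ndarray:
        """Physical size along each axis, mm."""
        return self.spacing * np.asarray(self.shape)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.origin) / self.spacing

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def copy(self, **changes) -> "DensityVolume":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out

    # SimpleITK bridge ------------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T))
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, unit: str = "dimensionless") -> "DensityVolume":
        arr = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
        return cls(arr, np.array(img.GetSpacing()), np.array(img.GetOrigin()), unit)


def _check_ext(path: str):
    p = str(path)
    if not any(p.endswith(e) for e in _SUPPORTED_EXT):
        raise FormatError(f"unsupported image container: {p} (expected one of {_SUPPORTED_EXT})")


def read_volume(path, unit: str = "dimensionless") -> DensityVolume:
    """Read a NIfTI or MetaImage volume. Units are not stored in the headers
    and must be supplied by the caller."""
    _check_ext(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    return DensityVolume.from_sitk(img, unit=unit)


def write_volume(v: DensityVolume, path) -> None:
    _check_ext(path)
    sitk.WriteImage(v.to_sitk(), str(path))


_INTERP = {0: sitk.sitkNearestNeighbor, 1: sitk.sitkLinear, 3: sitk.sitkBSpline}


def resample(v: DensityVolume, new_spacing, order: int = 3) -> DensityVolume:
    """Resample onto an isotropic-or-not grid with the given spline order.

    Order 0 (nearest neighbour) is intended for label volumes; orders 1 and 3
    for scalar data.  The world extent is preserved to within one output voxel.
    """
    if order not in _INTERP:
        raise ValueError("order must be 0, 1 or 3")
    new_spacing = np.broadcast_to(np.asarray(new_spacing, float), (3,))
    img = v.to_sitk()
    if order == 0:
        img = sitk.Cast(img, sitk.sitkFloat32)
    new_size = np.maximum(1, np.round(v.world_extent() / new_spacing)).astype(int)
    out = sitk.Resample(
        img, [int(n) for n in new_size], sitk.Transform(), _INTERP[order],
        tuple(float(o) for o in v.origin), tuple(float(s) for s in new_spacing),
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0), 0.0, sitk.sitkFloat64)
    res = DensityVolume.from_sitk(out, unit=v.unit)
    if order == 0:
        res.values = np.round(res.values).astype(v.values.dtype)
    return res


def mean_pool_downsample(v: DensityVolume, new_spacing: float) -> DensityVolume:
    """Block-mean (mass preserving) downsampling to an integer multiple of the
    input spacing; used for the 3 mm difference/damage grids."""
    factors = np.maximum(1, np.round(new_spacing / v.spacing)).astype(int)
    pad = [(0, (-v.shape[i]) % factors[i]) for i in range(3)]
    arr = np.pad(np.asarray(v.values, float), pad)
    sh = []
    for i in range(3):
        sh += [arr.shape[i] // factors[i], factors[i]]
    pooled = arr.reshape(sh).mean(axis=(1, 3, 5))
    return DensityVolume(pooled, v.spacing * factors, v.origin.copy(), v.unit)


def segment_phantom(v: DensityVolume, threshold: float) -> DensityVolume:
    """Threshold + morphology segmentation valid for phantom images.

    Keeps the largest 6-connected component above ``threshold``, closes it
    morphologically, and trims partial-volume surface voxels below half the
    local surface density so the boundary tracks the half-occupancy
    iso-surface rather than the raw threshold.  Returns a binary (0/1) label
    volume on the same grid.
    """
    if v.values.size == 0 or not np.any(v.values > threshold):
        raise ValueError("no voxels above threshold: nothing to segment")
    binary = v.values > threshold
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        raise ValueError("segmentation is empty")
    counts = np.bincount(labels.ravel())[1:]
    largest = binary & (labels == (1 + int(np.argmax(counts))))
    closed = ndimage.binary_closing(largest, structure=np.ones((3, 3, 3), bool))
    closed |= largest
    closed = ndimage.binary_fill_holes(closed)
    # boundary refinement: surface voxels are partial-volume fractions of the
    # (dense) cortical shell; the half-occupancy surface sits where the value
    # falls to half the density just inside the boundary
    for _ in range(2):
        interior = ndimage.binary_erosion(closed, structure)
        rim = interior & ~ndimage.binary_erosion(interior, structure)
        if not rim.any():
            break
        surface_density = float(np.median(v.values[rim]))
        boundary = closed & ~interior
        drop = boundary & (v.values < 0.5 * surface_density)
        if not drop.any():
            break
        closed &= ~drop
    closed = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(closed, structure=structure)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        closed = labels == (1 + int(np.argmax(counts)))
    return DensityVolume(closed.astype(np.uint8), v.spacing, v.origin, unit="label")


def _as_bool(mask) -> np.ndarray:
    arr = mask.values if isinstance(mask, DensityVolume) else np.asarray(mask)
    return arr > 0


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks on the same grid."""
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise ValueError("both masks empty: Dice undefined")
    return 2.0 * int((a & b).sum()) / (sa + sb)
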