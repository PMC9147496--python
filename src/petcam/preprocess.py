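"""Volume normalization, maximum intensity projections and prior points.

Axis convention (fixed throughout the package): volume arrays are indexed
``data[x, y, z]`` with x = left-right, y = anterior-posterior,
z = inferior-superior, 0-based.  A coronal MIP collapses y and is stored
as a (z rows, x cols) image; a sagittal MIP collapses x and is stored as
(z rows, y cols).  Anatomically this is forced: a sagittal projection
looks along the left-right axis, so x cannot survive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

SUV_CEILING = 30.0  # SUV clip level before rescaling to [0, 1]

VIEWS = ("coronal", "sagittal")
#: 3D axis collapsed by each view and the (row, col) axes it retains.
COLLAPSED_AXIS = {"coronal": 1, "sagittal": 0}
RETAINED_AXES = {"coronal": ("z", "x"), "sagittal": ("z", "y")}


@dataclass
class PetVolume:
    """A 3D PET image in SUV-like units with voxel spacing in mm."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    #: True once intensities have been mapped from SUV to [0, 1]
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"PetVolume data must be 3D, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class MipImage:
    """A 2D maximum intensity projection with its axis bookkeeping."""

    data: np.ndarray
    view: str
    retained_axes: tuple[str, str] = field(init=False)
    collapsed_axis: str = field(init=False)

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        self.retained_axes = RETAINED_AXES[self.view]
        self.collapsed_axis = "xyz"[COLLAPSED_AXIS[self.view]]


@dataclass(frozen=True)
class PriorPoint:
    """A single annotated voxel at the tumor center (the only localization
    supervision the method uses), with its per-view 2D projections."""

    voxel: tuple[int, int, int]

    @property
    def p_cor(self):
        x, _, z = self.voxel
        return (z, x)

    @property
    def p_sag(self):
        _, y, z = self.voxel
        return (z, y)

    def project(self, view):
        if view == "coronal":
            return self.p_cor
        if view == "sagittal":
            return self.p_sag
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")


def resample_isotropic(volume: PetVolume, target_mm: float) -> PetVolume:
    """Resample to isotropic ``target_mm`` spacing with cubic spline
    interpolation; output shape is ceil(physical extent / target) per axis
    and intensities are clipped at zero (splines can overshoot)."""
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    in_shape = np.array(volume.shape, dtype=float)
    extent = in_shape * np.array(volume.spacing_mm, dtype=float)
    out_shape = np.ceil(extent / target_mm).astype(int)
    if np.array_equal(out_shape, volume.shape) and all(
        abs(s - target_mm) < 1e-12 for s in volume.spacing_mm
    ):
        return PetVolume(volume.data.copy(), (target_mm,) * 3)
    zoom = out_shape / in_shape
    data = ndimage.zoom(
        volume.data.astype(np.float64), zoom, order=3, mode="nearest",
        grid_mode=True,
    )
    return PetVolume(np.maximum(data, 0.0), (target_mm,) * 3)


def resample_mask_isotropic(mask: np.ndarray, spacing_mm, target_mm: float) -> np.ndarray:
    """Nearest-neighbor resampling for binary masks (preserves binarity)."""
    vol = PetVolume(mask.astype(np.float64), tuple(spacing_mm))
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    out_shape = np.ceil(
        np.array(vol.shape) * np.array(spacing_mm, dtype=float) / target_mm
    ).astype(int)
    zoom = out_shape / np.array(vol.shape, dtype=float)
    out = ndimage.zoom(vol.data, zoom, order=0, mode="nearest", grid_mode=True)
    return out > 0.5


def normalize_suv(volume: PetVolume) -> PetVolume:
    """Clip SUV values to [0, 30] then rescale to [0, 1].

    Idempotent: a volume already carrying the ``normalized`` flag is
    returned unchanged.
    """
    if volume.normalized:
        return volume
    data = np.clip(volume.data, 0.0, SUV_CEILING) / SUV_CEILING
    return PetVolume(data, volume.spacing_mm, normalized=True)


def compute_mip(volume: PetVolume, view: str) -> MipImage:
    """Project the volume along the view's collapsed axis by voxelwise max.

    Coronal: pixel (z, x) = max over y.  Sagittal: pixel (z, y) = max over x.
    """
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
    axis = COLLAPSED_AXIS[view]
    return MipImage(volume.data.max(axis=axis).T, view)


def project_prior(voxel, view: str, volume_shape) -> tuple[int, int]:
    """Drop the view's collapsed axis from a 3D voxel coordinate.

    Returns (row, col) in the MIP convention: coronal -> (z, x),
    sagittal -> (z, y).
    """
    voxel = tuple(int(v) for v in voxel)
    if len(voxel) != 3:
        raise ValueError(f"prior voxel must be 3D, got {voxel}")
    for v, n in zip(voxel, volume_shape):
        if not (0 <= v < n):
            raise ValueError(f"prior point {voxel} outside volume bounds {tuple(volume_shape)}")
    return PriorPoint(voxel).project(view)
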