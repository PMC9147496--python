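"""3D tumor mask from the two orthogonal 2D heat maps.

The coronal heat map fixes the tumor's (x, z) extent and the sagittal
one its (y, z) extent; back-projecting each binarized map along its
collapsed axis gives a prism, and the voxelwise intersection of the two
prisms is the 3D mask: voxel (x, y, z) is tumor iff coronal(z, x) and
sagittal(z, y) are both set.  The intersection is conservative for
convex tumors — it always contains the true shape when the 2D masks
contain the true projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cam import compute_cam
from .preprocess import PetVolume, compute_mip, normalize_suv

DEFAULT_REL_THRESHOLD = 0.4  # mirrors the clinical 40%-of-SUVmax convention


@dataclass
class TumorMask3D:
    """Binary voxel mask with the provenance of its construction."""

    data: np.ndarray
    rel_threshold: float | None = None
    views: tuple[str, ...] = ("coronal", "sagittal")

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")


def binarize_heatmap(heatmap, rel_threshold=DEFAULT_REL_THRESHOLD, keep_largest=True):
    """Threshold a heat map at ``rel_threshold`` times its maximum and
    (by default) keep only the largest connected component, suppressing
    residual decoy activations."""
    h = np.asarray(getattr(heatmap, "data", heatmap), dtype=np.float64)
    if not 0 < rel_threshold < 1:
        raise ValueError(f"rel_threshold must be in (0, 1), got {rel_threshold}")
    peak = h.max()
    if peak <= 0:
        warnings.warn("all-zero heat map: returning an empty mask", stacklevel=2)
        return np.zeros(h.shape, dtype=bool)
    mask = h >= rel_threshold * peak
    if keep_largest:
        labeled, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
            mask = labeled == (1 + int(np.argmax(sizes)))
    return mask


def reconstruct_3d(mask_cor, mask_sag, volume_shape) -> TumorMask3D:
    """Intersect the back-projected coronal (z, x) and sagittal (z, y)
    masks into a (x, y, z) voxel mask."""
    mask_cor = np.asarray(mask_cor, dtype=bool)
    mask_sag = np.asarray(mask_sag, dtype=bool)
    nx, ny, nz = volume_shape
    if mask_cor.shape != (nz, nx):
        raise ValueError(
            f"coronal mask shape {mask_cor.shape} inconsistent with volume "
            f"{tuple(volume_shape)} (expected {(nz, nx)})"
        )
    if mask_sag.shape != (nz, ny):
        raise ValueError(
            f"sagittal mask shape {mask_sag.shape} inconsistent with volume "
            f"{tuple(volume_shape)} (expected {(nz, ny)})"
        )
    # (x, 1, z) AND (1, y, z)
    data = mask_cor.T[:, None, :] & mask_sag.T[None, :, :]
    return TumorMask3D(data=data)


def refine_by_suv(mask: TumorMask3D, volume: PetVolume, frac=0.4) -> TumorMask3D:
    """Optionally re-threshold inside the prism intersection at ``frac``
    of the maximum intensity it contains (the clinical MTV protocol
    transferred to the predicted region); idempotent."""
    m = mask.data
    if not m.any():
        warnings.warn("empty mask passed to refine_by_suv; returned unchanged",
                      stacklevel=2)
        return mask
    vals = np.where(m, volume.data, -np.inf)
    peak = vals.max()
    refined = m & (volume.data >= frac * peak)
    return TumorMask3D(data=refined, rel_threshold=mask.rel_threshold, views=mask.views)


def segment_patient(
    model,
    volume: PetVolume,
    rel_threshold=DEFAULT_REL_THRESHOLD,
    class_index=None,
    keep_largest=True,
    suv_refine=False,
) -> TumorMask3D:
    """End-to-end segmentation of one (SUV-scale) volume: normalize,
    project both MIPs, compute per-view CAMs, binarize, intersect."""
    vol = normalize_suv(volume)
    masks = {}
    for view in ("coronal", "sagittal"):
        mip = compute_mip(vol, view)
        heat = compute_cam(model, mip.data, class_index=class_index)
        masks[view] = binarize_heatmap(heat, rel_threshold, keep_largest=keep_largest)
    out = reconstruct_3d(masks["coronal"], masks["sagittal"], vol.shape)
    out.rel_threshold = rel_threshold
    if suv_refine and out.data.any():
        out = refine_by_suv(out, vol, frac=0.4)
    return out
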