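"""Gradient-weighted class activation maps for MIP images.

Given the last-layer feature maps f_i (shape J x Z, i = 1..D) and the
influence of each element on the class response, I_i(j,z) = dy^C/df_i(j,z):

* each map's weight is the mean influence, w_i^C = (1/N) sum_{j,z} I_i(j,z)
  with N = J*Z;
* the pre-heat map is sum_i w_i^C f_i;
* a ReLU keeps only positively contributing regions;
* the raw J x Z map is upsampled to MIP resolution with corner-aligned
  bilinear interpolation and rescaled to [0, 1] by its maximum (scale
  does not affect the distance constraint, which is a ratio, but a fixed
  range makes thresholds comparable across patients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .net import CLASS_NAMES, MipClassifier


@dataclass
class HeatMap:
    """A nonnegative 2D class response aligned to its MIP image."""

    data: np.ndarray  # upsampled, max-normalized to [0, 1]
    raw: np.ndarray  # (J, Z) pre-upsampling map
    class_name: str
    weights: np.ndarray  # w_i^C actually used

    def __post_init__(self):
        if np.any(self.data < 0) or np.any(self.raw < 0):
            raise ValueError("heat maps must be nonnegative")


def cam_weights(influence: np.ndarray, j: int | None = None, z: int | None = None):
    """w_i = mean over the J x Z positions of the influence of map i."""
    influence = np.asarray(influence)
    if influence.ndim != 3:
        raise ValueError(f"influence must be (D, J, Z), got shape {influence.shape}")
    if j is not None and influence.shape[1] != j:
        raise ValueError(f"influence has J={influence.shape[1]}, expected {j}")
    if z is not None and influence.shape[2] != z:
        raise ValueError(f"influence has Z={influence.shape[2]}, expected {z}")
    return influence.mean(axis=(1, 2))


def pre_heatmap(features: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """sum_i w_i f_i, elementwise over the J x Z grid."""
    features = np.asarray(features)
    weights = np.asarray(weights)
    if features.ndim != 3 or weights.ndim != 1 or features.shape[0] != weights.shape[0]:
        raise ValueError(
            f"need (D, J, Z) features and (D,) weights, got {features.shape} and {weights.shape}"
        )
    return np.einsum("d,djz->jz", weights, features)


def relu_heatmap(pre: np.ndarray) -> np.ndarray:
    """Keep only positive class evidence."""
    return np.maximum(np.asarray(pre), 0.0)


@lru_cache(maxsize=32)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Corner-aligned linear interpolation as an (n_out, n_in) matrix."""
    mat = np.zeros((n_out, n_in))
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.minimum(pos.astype(int), n_in - 2)
    frac = pos - lo
    mat[np.arange(n_out), lo] = 1.0 - frac
    mat[np.arange(n_out), lo + 1] = frac
    return mat


def upsample_heatmap(raw: np.ndarray, target_shape) -> np.ndarray:
    """Bilinear, corner-aligned upsampling of a raw J x Z map.

    Being a separable linear operator (A @ raw @ B.T), its transpose is
    the exact gradient used during training.
    """
    raw = np.asarray(raw, dtype=np.float64)
    j, z = raw.shape
    ht, wt = target_shape
    if ht < j or wt < z:
        raise ValueError(f"target shape {target_shape} smaller than raw {raw.shape}")
    a = _interp_matrix(j, ht)
    b = _interp_matrix(z, wt)
    return np.maximum(a @ raw @ b.T, 0.0)


def downsample_gradient(dout: np.ndarray, raw_shape) -> np.ndarray:
    """Transpose of :func:`upsample_heatmap` (before the clip)."""
    j, z = raw_shape
    a = _interp_matrix(j, dout.shape[0])
    b = _interp_matrix(z, dout.shape[1])
    return a.T @ dout @ b


def compute_cam(
    model,
    mip_data: np.ndarray,
    class_index: int | None = None,
) -> HeatMap:
    """Full CAM pipeline for one MIP image (evaluation mode).

    ``model`` may be a single :class:`~petcam.net.MipClassifier` or a
    :class:`~petcam.net.CamEnsemble` (member maps are max-normalized
    then averaged).  ``class_index`` 1 = lung, 0 = esophageal; ``None``
    uses the predicted class.
    """
    mip_data = np.asarray(mip_data, dtype=np.float64)
    members = getattr(model, "members", [model])
    preds = [m.forward(mip_data[None], train=False) for m in members]
    if class_index is None:
        class_index = int(np.mean([p.y_hat[0] for p in preds]) >= 0.5)
    maps, raws, weights = [], [], []
    for member, pred in zip(members, preds):
        influence = member.influence(class_index=class_index)[0]
        w = cam_weights(influence)
        raw = relu_heatmap(pre_heatmap(pred.feature_maps[0], w))
        up = upsample_heatmap(raw, mip_data.shape)
        peak = up.max()
        if peak > 0:
            up = up / peak
        maps.append(up)
        raws.append(raw / raw.max() if len(members) > 1 and raw.max() > 0 else raw)
        weights.append(w)
    data = np.mean(maps, axis=0)
    peak = data.max()
    if peak > 0:
        data = data / peak
    else:
        warnings.warn("all-zero heat map: no positive class evidence", stacklevel=2)
    raw = raws[0] if len(raws) == 1 else np.mean(raws, axis=0)
    w = weights[0] if len(weights) == 1 else np.stack(weights)
    return HeatMap(data=data, raw=raw, class_name=CLASS_NAMES[class_index], weights=w)
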