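"""Treatment-outcome prediction from the segmented tumor region.

A small 3D CNN (two 3x3x3 convolutional layers each followed by 2x2x2
max pooling, then two dense layers ending in a sigmoid) classifies a
fixed-size intensity patch cropped around the tumor-mask centroid.
The same network can be trained on ground-truth masks or on masks
produced by the weakly supervised segmentation, which is how the two
segmentation sources are compared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from . import _nn
from ._nn import Adam, sigmoid


@dataclass
class TumorCrop:
    """Fixed-size 3D intensity patch centered on the tumor."""

    data: np.ndarray  # (cx, cy, cz), intensities in [0, 1]
    outcome_label: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"crop must be 3D, got ndim={self.data.ndim}")


def crop_tumor(volume, mask, crop_shape=(48, 48, 48), masked=False) -> TumorCrop:
    """Extract a ``crop_shape`` patch centered on the mask centroid,
    zero-padded where it overruns the volume; with ``masked=True``
    intensities outside the mask are zeroed."""
    data = np.asarray(getattr(volume, "data", volume), dtype=np.float64)
    m = np.asarray(getattr(mask, "data", mask)).astype(bool)
    if m.shape != data.shape:
        raise ValueError(f"mask shape {m.shape} != volume shape {data.shape}")
    if not m.any():
        raise ValueError(
            "empty tumor mask: nothing to crop (check the segmentation output)"
        )
    if masked:
        data = np.where(m, data, 0.0)
    centroid = np.round(ndimage.center_of_mass(m)).astype(int)
    out = np.zeros(crop_shape)
    for_src, for_dst = [], []
    for c, n_src, n_crop in zip(centroid, data.shape, crop_shape):
        start = c - n_crop // 2
        src_lo, src_hi = max(0, start), min(n_src, start + n_crop)
        dst_lo = src_lo - start
        for_src.append(slice(src_lo, src_hi))
        for_dst.append(slice(dst_lo, dst_lo + (src_hi - src_lo)))
    out[tuple(for_dst)] = data[tuple(for_src)]
    return TumorCrop(data=out)


@dataclass(frozen=True)
class OutcomeConfig:
    """Architecture + training knobs for the 3D outcome classifier."""

    crop_shape: tuple[int, int, int] = (48, 48, 48)
    channels: tuple[int, int] = (32, 64)
    dense_width: int = 128
    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    seed: int = 0
    #: zero intensities outside the tumor mask before cropping
    masked: bool = False

    def __post_init__(self):
        if any(n % 4 for n in self.crop_shape):
            raise ValueError(
                f"crop_shape dims must be divisible by 4 (two poolings), got {self.crop_shape}"
            )


class OutcomeNet:
    """conv(3^3)-pool(2^3)-conv(3^3)-pool(2^3)-dense-dense(1, sigmoid)."""

    def __init__(self, config: OutcomeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.channels
        flat = c2 * int(np.prod([n // 4 for n in config.crop_shape]))
        self.net = _nn.Sequential(
            [
                _nn.Conv3d(1, c1, rng=rng),
                _nn.ReLU(),
                _nn.MaxPool3d(),
                _nn.Conv3d(c1, c2, rng=rng),
                _nn.ReLU(),
                _nn.MaxPool3d(),
                _nn.Flatten(),
                _nn.Dense(flat, config.dense_width, rng=rng),
                _nn.ReLU(),
                _nn.Dense(config.dense_width, 1, rng=rng, init_scale=0.01),
            ]
        )
        self._logit = None

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != self.config.crop_shape:
            raise ValueError(
                f"crops are {x.shape[2:]}, network expects {self.config.crop_shape}"
            )
        self._logit = self.net.forward(x, train=train)[:, 0]
        return np.clip(sigmoid(self._logit), 1e-12, 1 - 1e-12)

    def parameters(self):
        return self.net.parameters()

    def zero_grad(self):
        self.net.zero_grad()

    def save(self, path):
        arrays = {
            f"param_{i}_{name}": layer.params[name]
            for i, (layer, name) in enumerate(self.parameters())
        }
        with open(path, "wb") as fh:
            np.savez(fh, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "OutcomeNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["config"]))
            for key in ("crop_shape", "channels"):
                cfg[key] = tuple(cfg[key])
            model = cls(OutcomeConfig(**cfg))
            for i, (layer, name) in enumerate(model.parameters()):
                layer.params[name] = data[f"param_{i}_{name}"]
        return model


def outcome_forward(crop, model: OutcomeNet) -> float:
    """Probability of a positive outcome for one crop (evaluation mode)."""
    data = np.asarray(getattr(crop, "data", crop), dtype=np.float64)
    return float(model.forward(data[None], train=False)[0])


def train_outcome(crops, labels, config: OutcomeConfig | None = None):
    """Train the 3D outcome classifier on a cohort of crops.

    Returns ``(model, history)``; history holds one dict per epoch with
    the mean training cross entropy.
    """
    if config is None:
        config = OutcomeConfig()
    labels = np.asarray(labels, dtype=np.float64)
    x = np.stack([np.asarray(getattr(c, "data", c), dtype=np.float64) for c in crops])
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            f"outcome training needs both classes present, got labels {classes}"
        )
    model = OutcomeNet(config)
    optimizer = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(labels))
        total, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            model.zero_grad()
            p = model.forward(x[idx], train=True)
            y = labels[idx]
            pc = np.clip(p, 1e-7, 1 - 1e-7)
            loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log1p(-pc)))
            dlogit = (p - y) / len(idx)
            model.net.backward(dlogit[:, None], accumulate=True)
            optimizer.step()
            total += loss
            n_batches += 1
        history.append({"epoch": epoch, "l_class": total / n_batches})
    return model, history
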