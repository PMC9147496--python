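"""The MIP classifier.

An eight-layer convolutional feature extractor ends in D feature maps
f_i (i = 1..D) of shape J x Z; these are flattened into a vector V and
passed through a dense head (128 -> 64 -> 1 sigmoid, ELU activations,
dropout 0.5) that outputs the probability y_hat that the patient has
lung cancer (label 1) rather than esophageal cancer (label 0).

With the default input size of 416 x 160 the stride plan halves the
resolution five times, giving 13 x 5 feature maps at depth D = 128.
Both MIP views (coronal and sagittal) share this one network; each MIP
is a separate sample.

``influence`` returns the partial derivatives of the class response
with respect to every feature-map element — the quantity the class
activation map is built from — by back-propagating through the dense
head only, without touching training gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _nn
from ._nn import sigmoid

CLASS_NAMES = ("esophageal", "lung")


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture of the MIP classifier.

    ``input_shape`` is (rows, cols) of the MIP images.  ``strides``
    places the stride-2 downsamplings; the default plan (an initial
    stride-2 layer plus one after each conv pair) reduces 416 x 160
    inputs to 13 x 5 feature maps of depth 128.
    """

    input_shape: tuple[int, int] = (416, 160)
    channels: tuple[int, ...] = (16, 16, 32, 32, 64, 64, 128, 128)
    strides: tuple[int, ...] = (2, 2, 1, 2, 1, 2, 1, 2)
    dense_widths: tuple[int, int] = (128, 64)
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if min(self.channels) < 1:
            raise ValueError("channel counts must be positive")

    @property
    def n_conv_layers(self) -> int:
        return len(self.channels)

    @property
    def feature_depth(self) -> int:
        """D, the number of feature maps in the last conv layer."""
        return self.channels[-1]

    @property
    def featuremap_shape(self) -> tuple[int, int]:
        """(J, Z) shape of the last conv layer's feature maps."""
        h, w = self.input_shape
        for s in self.strides:
            h = (h + 2 - 3) // s + 1
            w = (w + 2 - 3) // s + 1
        return (h, w)

    @classmethod
    def small(cls, input_shape=(128, 64), seed=0) -> "ClassifierConfig":
        """Reduced plan for desk-scale phantoms: 3 downsamplings, D=32;
        128 x 64 MIPs give 16 x 8 feature maps."""
        return cls(
            input_shape=tuple(input_shape),
            channels=(8, 16, 16, 32, 32, 32, 32, 32),
            strides=(2, 2, 2, 1, 1, 1, 1, 1),
            seed=seed,
        )


@dataclass
class Prediction:
    """Output of a classifier forward pass (evaluation or training mode)."""

    y_hat: np.ndarray  # (B,) probability of the lung class
    logit: np.ndarray  # (B,) pre-sigmoid activation
    feature_maps: np.ndarray  # (B, D, J, Z) last conv layer
    hidden: np.ndarray  # (B, H) first dense-layer activation

    def __post_init__(self):
        if not np.all((self.y_hat > 0) & (self.y_hat < 1)):
            raise ValueError("y_hat must lie strictly inside (0, 1)")


class MipClassifier:
    """Shared-weight CNN classifying single-channel MIP images."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        layers = []
        c_in = 1
        for c_out, s in zip(config.channels, config.strides):
            layers.append(_nn.Conv2d(c_in, c_out, stride=s, rng=rng))
            layers.append(_nn.ReLU())
            c_in = c_out
        self.conv = _nn.Sequential(layers)
        j, z = config.featuremap_shape
        if j < 1 or z < 1:
            raise ValueError(
                f"input_shape {config.input_shape} collapses to {j}x{z} feature maps"
            )
        k = config.feature_depth * j * z
        h1, h2 = config.dense_widths
        self.head = _nn.Sequential(
            [
                _nn.Flatten(),
                _nn.Dense(k, h1, rng=rng),
                _nn.ELU(),
                _nn.Dropout(config.dropout, rng=rng),
                _nn.Dense(h1, h2, rng=rng),
                _nn.ELU(),
                _nn.Dropout(config.dropout, rng=rng),
                _nn.Dense(h2, 1, rng=rng, init_scale=0.01),
            ]
        )
        self._last: Prediction | None = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> Prediction:
        """Run a batch of MIPs; ``x`` is (B, H, W) or (B, 1, H, W)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        expected = self.config.input_shape
        if x.shape[2:] != expected:
            raise ValueError(
                f"input MIPs are {x.shape[2:]}, classifier expects {expected}"
            )
        f = self.conv.forward(x, train=train)
        logit = self.head.forward(f, train=train)[:, 0]
        hidden = self.head.layers[1]._x @ self.head.layers[1].params["W"] + (
            self.head.layers[1].params["b"]
        )
        y_hat = np.clip(sigmoid(logit), 1e-12, 1 - 1e-12)
        self._last = Prediction(y_hat=y_hat, logit=logit, feature_maps=f, hidden=hidden)
        return self._last

    def influence(self, class_index=1) -> np.ndarray:
        """d y_hat^C / d f for the cached forward pass, shape (B, D, J, Z).

        ``class_index`` selects the class response: 1 (lung) uses y_hat,
        0 (esophageal) uses 1 - y_hat (sign flip).  May be a scalar or a
        per-sample array.
        """
        if self._last is None:
            raise RuntimeError("influence requires a preceding forward pass")
        pred = self._last
        sign = np.where(np.asarray(class_index) == 1, 1.0, -1.0)
        seed = (sign * pred.y_hat * (1.0 - pred.y_hat))[:, None]
        return self.head.backward(seed, accumulate=False)

    def score_influence(self, class_index=1) -> np.ndarray:
        """d logit^C / d f for the cached forward pass, shape (B, D, J, Z).

        The class-score analogue of :meth:`influence` (seed +/-1 instead
        of the sigmoid derivative); identical up to the positive factor
        sigma'(logit), so it yields the same max-normalized heat map but
        stays well scaled when the classifier saturates.
        """
        if self._last is None:
            raise RuntimeError("score_influence requires a preceding forward pass")
        sign = np.where(np.asarray(class_index) == 1, 1.0, -1.0)
        seed = np.broadcast_to(sign, self._last.y_hat.shape).astype(float)[:, None]
        return self.head.backward(seed, accumulate=False)

    def backward_from_head(self, dlogit: np.ndarray) -> np.ndarray:
        """Accumulate head parameter gradients; return dLoss/dFeatureMaps."""
        return self.head.backward(np.asarray(dlogit)[:, None], accumulate=True)

    def backward_conv(self, dfeatures: np.ndarray) -> None:
        self.conv.backward(dfeatures, accumulate=True)

    # -- bookkeeping --------------------------------------------------------

    def parameters(self):
        return self.conv.parameters() + self.head.parameters()

    def zero_grad(self):
        self.conv.zero_grad()
        self.head.zero_grad()

    def predict_proba(self, x) -> np.ndarray:
        return self.forward(x, train=False).y_hat

    def save(self, path):
        """Single-file checkpoint: config JSON + flat parameter arrays."""
        arrays = {}
        for i, (layer, name) in enumerate(self.parameters()):
            arrays[f"param_{i}_{name}"] = layer.params[name]
        with open(path, "wb") as fh:
            np.savez(fh, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "MipClassifier":
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["config"]))
            for key in ("input_shape", "channels", "strides", "dense_widths"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ClassifierConfig(**cfg_dict))
            for i, (layer, name) in enumerate(model.parameters()):
                layer.params[name] = data[f"param_{i}_{name}"]
        return model


class CamEnsemble:
    """A bag of independently trained MIP classifiers.

    Class probabilities are the members' mean; heat maps are averaged
    after per-member max-normalization (see :func:`petcam.cam.compute_cam`),
    which suppresses activations only one run believes in.
    """

    def __init__(self, members):
        if not members:
            raise ValueError("ensemble needs at least one member")
        shapes = {m.config.input_shape for m in members}
        if len(shapes) != 1:
            raise ValueError(f"members disagree on input shape: {shapes}")
        self.members = list(members)
        self.config = self.members[0].config

    def predict_proba(self, x) -> np.ndarray:
        return np.mean([m.predict_proba(x) for m in self.members], axis=0)

    def save(self, path):
        arrays = {"n_members": np.array(len(self.members))}
        configs = []
        for k, member in enumerate(self.members):
            configs.append(json.dumps(asdict(member.config)))
            for i, (layer, name) in enumerate(member.parameters()):
                arrays[f"m{k}_param_{i}_{name}"] = layer.params[name]
        with open(path, "wb") as fh:
            np.savez(fh, configs=json.dumps(configs), **arrays)

    @classmethod
    def load(cls, path) -> "CamEnsemble":
        with np.load(path, allow_pickle=False) as data:
            configs = json.loads(str(data["configs"]))
            members = []
            for k, cfg_json in enumerate(configs):
                cfg_dict = json.loads(cfg_json)
                for key in ("input_shape", "channels", "strides", "dense_widths"):
                    cfg_dict[key] = tuple(cfg_dict[key])
                member = MipClassifier(ClassifierConfig(**cfg_dict))
                for i, (layer, name) in enumerate(member.parameters()):
                    layer.params[name] = data[f"m{k}_param_{i}_{name}"]
                members.append(member)
        return cls(members)
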