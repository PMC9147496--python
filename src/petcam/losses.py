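"""Multitask objective and training loop for the MIP classifier.

The objective couples two terms:

* ``L_class`` — binary cross entropy between the cancer-type label and
  the sigmoid output;
* ``L_distance`` — the prior-knowledge constraint: the activation-
  weighted mean Euclidean pixel distance between the class activation
  map and the projected tumor-center point p,

      L_distance = sum_i h(q_i) d(q_i, p) / max(sum_i h(q_i), eps),

  taken over all m pixels q_i of the upsampled heat map and averaged
  over the images of the batch and both MIP views.  The weighting by
  h(q_i) is what lets the gradient flow into the network: activation
  far from the prior point raises the loss, so back-propagation pushes
  class evidence toward the tumor.

* ``loss_glob = L_class + alpha * L_distance`` with alpha = 1 by
  default; alpha = 0 is exactly the no-prior ablation (plain CAM
  training).

Inside the training graph the distance term is computed as the expected
distance under a softmax attention distribution over the (per-sample
scale-normalized) pre-heat map, with distances measured as a fraction
of the MIP diagonal: a smooth, bounded surrogate of the ReLU-weighted
ratio that can neither collapse to an untrainable all-zero map nor
overwhelm the classification gradient (see docs/methods.md for the
reasoning).  The public :func:`distance_loss` operation keeps the plain
activation-weighted pixel-unit form.

During the distance backward pass the CAM weights w_i — themselves
gradients of the class response — are treated as constants
(stop-gradient), so the update needs first-order derivatives only;
gradients reach the convolutional stack through the feature maps f_i.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from . import cam as _cam
from ._nn import Adam
from .net import ClassifierConfig, MipClassifier
from .preprocess import compute_mip, normalize_suv, project_prior

EPS_PROB = 1e-7  # probability clamp inside the cross entropy
EPS_MASS = 1e-8  # heat-map mass floor in the distance ratio
ATTENTION_TEMPERATURE = 0.2  # softmax sharpness for the in-graph distance term


@dataclass
class LossReport:
    """One training step's loss components; the sum identity is exact."""

    l_class: float
    l_distance: float
    alpha: float = 1.0
    loss_glob: float = field(init=False)

    def __post_init__(self):
        if self.l_class < 0 or self.l_distance < 0:
            raise ValueError("loss components must be nonnegative")
        self.loss_glob = self.l_class + self.alpha * self.l_distance


def classification_loss(y, y_hat) -> float:
    """Binary cross entropy, -(1/n) sum [y log p + (1-y) log(1-p)];
    probabilities are clamped to [1e-7, 1 - 1e-7]."""
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_hat, dtype=np.float64), EPS_PROB, 1.0 - EPS_PROB)
    if y.shape != p.shape:
        raise ValueError(f"labels {y.shape} and predictions {p.shape} differ in shape")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _distance_grid(shape, p2d):
    rows = np.arange(shape[0])[:, None] - p2d[0]
    cols = np.arange(shape[1])[None, :] - p2d[1]
    return np.sqrt(rows**2 + cols**2)


def distance_loss(heatmap, p2d) -> float:
    """Activation-weighted mean pixel distance from the heat map to the
    projected prior point; an all-zero map contributes 0 by convention."""
    h = np.asarray(getattr(heatmap, "data", heatmap), dtype=np.float64)
    if h.ndim != 2:
        raise ValueError(f"heat map must be 2D, got shape {h.shape}")
    r, c = p2d
    if not (0 <= r < h.shape[0] and 0 <= c < h.shape[1]):
        raise ValueError(f"prior projection {p2d} outside heat map bounds {h.shape}")
    mass = h.sum()
    if mass <= EPS_MASS:
        return 0.0
    return float((h * _distance_grid(h.shape, p2d)).sum() / mass)


def global_loss(l_class: float, l_distance: float, alpha: float = 1.0) -> float:
    """loss_glob = L_class + alpha * L_distance (alpha = 1 by default)."""
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    if not (np.isfinite(l_class) and np.isfinite(l_distance)):
        raise ValueError("loss components must be finite")
    return l_class + alpha * l_distance


# ---------------------------------------------------------------------------
# dataset plumbing


@dataclass
class MipDataset:
    """Per-patient coronal+sagittal MIPs with labels and prior projections."""

    x: np.ndarray  # (n, 2, H, W), views ordered (coronal, sagittal)
    labels: np.ndarray  # (n,)
    priors: np.ndarray  # (n, 2, 2) (row, col) per view
    ids: list[str]

    def __len__(self):
        return len(self.ids)

    @classmethod
    def from_patients(cls, patients) -> "MipDataset":
        xs, labels, priors, ids = [], [], [], []
        for p in patients:
            vol = normalize_suv(p.volume)
            cor = compute_mip(vol, "coronal").data
            sag = compute_mip(vol, "sagittal").data
            if cor.shape != sag.shape:
                raise ValueError(
                    "coronal and sagittal MIPs differ in shape "
                    f"({cor.shape} vs {sag.shape}); use volumes with nx == ny"
                )
            xs.append(np.stack([cor, sag]))
            labels.append(p.class_label)
            priors.append(
                [
                    project_prior(p.prior_point.voxel, "coronal", vol.shape),
                    project_prior(p.prior_point.voxel, "sagittal", vol.shape),
                ]
            )
            ids.append(p.id)
        return cls(
            x=np.asarray(xs, dtype=np.float64),
            labels=np.asarray(labels, dtype=np.int64),
            priors=np.asarray(priors, dtype=np.int64),
            ids=ids,
        )


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (alpha = 1 and mini-batches of eight
    patients by default; Adam with early stopping on validation loss)."""

    alpha: float = 1.0
    batch_size: int = 8
    lr: float = 1e-4
    epochs: int = 100
    patience: int = 10
    seed: int = 0
    #: optionally mirror coronal MIPs left-right during training (the
    #: body is laterally symmetric, so the flip is label-preserving)
    flip_augment: bool = False
    #: independent training restarts; the run with the lowest validation
    #: loss is kept (guards against unlucky initializations)
    restarts: int = 1
    #: epochs at which the learning rate is multiplied by ``lr_gamma``
    lr_milestones: tuple[int, ...] = ()
    lr_gamma: float = 0.3

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


def _flatten_views(x, labels, priors):
    """(n, 2, H, W) -> (2n, H, W) with per-view labels and priors."""
    n = x.shape[0]
    mips = x.reshape(n * 2, *x.shape[2:])
    lab = np.repeat(labels, 2)
    pri = priors.reshape(n * 2, 2)
    return mips, lab, pri


def _cam_losses_and_grad(model, pred, labels, priors, want_grad):
    """In-graph CAM distance loss for every sample of a forward pass.

    Returns (mean distance loss, dL/df or None).  The CAM weights are
    stop-gradient; the upsampling operator's transpose propagates pixel
    gradients back to the raw J x Z map.
    """
    f = pred.feature_maps  # (B, D, J, Z)
    b = f.shape[0]
    # class-score influence: seeding the head backward with +/-1 (the
    # logit gradient) instead of dy_hat/df keeps the CAM weights well
    # scaled when the classifier saturates (sigma' -> 0); after peak
    # normalization the resulting map is identical to the
    # probability-based one.
    infl = model.score_influence(class_index=labels)
    w = infl.mean(axis=(2, 3))  # (B, D), treated as constant
    pre = np.einsum("bd,bdjz->bjz", w, f)
    h = np.maximum(pre, 0.0)
    target = model.config.input_shape
    a_mat = _cam._interp_matrix(h.shape[1], target[0])
    b_mat = _cam._interp_matrix(h.shape[2], target[1])
    diag = float(np.hypot(*target))  # distances as a fraction of the MIP diagonal
    total = 0.0
    df = np.zeros_like(f) if want_grad else None
    for i in range(b):
        up = a_mat @ pre[i] @ b_mat.T  # signed pre-heat map at MIP scale
        # softmax attention: strictly positive weights that sum to one,
        # so the distance term can neither die (zero mass) nor blow up
        # (1/mass); the per-sample scale normalization keeps the
        # attention sharpness independent of the map's magnitude.
        scale = max(np.abs(up).max(), EPS_MASS)
        logits = up / (ATTENTION_TEMPERATURE * scale)
        logits -= logits.max()
        att = np.exp(logits)
        att /= att.sum()
        dist = _distance_grid(target, priors[i]) / diag
        ld = (att * dist).sum()
        total += ld
        if want_grad:
            dup = att * (dist - ld) / (ATTENTION_TEMPERATURE * scale) / b
            dpre = a_mat.T @ dup @ b_mat
            df[i] = w[i][:, None, None] * dpre
    return total / b, df


def train_step(model, optimizer, mips, labels, priors, alpha=1.0) -> LossReport:
    """One optimizer step on a mini-batch of MIPs (views already
    flattened into samples); returns the loss report."""
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    model.zero_grad()
    pred = model.forward(mips, train=True)
    n = mips.shape[0]
    l_class = classification_loss(labels, pred.y_hat)
    dlogit = (pred.y_hat - labels) / n
    grad_f = model.backward_from_head(dlogit)
    l_dist = 0.0
    if alpha > 0:
        l_dist, df = _cam_losses_and_grad(model, pred, labels, priors, want_grad=True)
        grad_f = grad_f + alpha * df
    report = LossReport(l_class=l_class, l_distance=l_dist, alpha=alpha)
    if not np.isfinite(report.loss_glob):
        raise FloatingPointError(
            f"non-finite loss (L_class={l_class}, L_distance={l_dist}); "
            "lower the learning rate or inspect the input scaling"
        )
    model.backward_conv(grad_f)
    optimizer.step()
    return report


def train_cam_ensemble(
    train_set: MipDataset,
    config: TrainConfig,
    val_set: MipDataset | None = None,
    classifier_config: ClassifierConfig | None = None,
    members: int = 2,
):
    """Train ``members`` independently initialized classifiers and bundle
    them into a :class:`~petcam.net.CamEnsemble` whose heat maps are the
    average of the members' normalized maps (consensus suppresses
    spurious single-run activations).  Returns (ensemble, histories).
    """
    from .net import CamEnsemble

    models, histories = [], []
    for r in range(members):
        cfg_r = replace(config, seed=config.seed + 101 * r, restarts=1)
        clf_r = classifier_config
        if clf_r is not None and r > 0:
            clf_r = dataclasses.replace(clf_r, seed=clf_r.seed + 101 * r)
        model, history = _train_classifier_once(train_set, cfg_r, val_set, clf_r)
        models.append(model)
        histories.append(history)
    return CamEnsemble(models), histories


def evaluate_losses(model, dataset: MipDataset, alpha: float) -> LossReport:
    """Evaluation-mode losses over a whole dataset (no dropout, no update)."""
    mips, labels, priors = _flatten_views(dataset.x, dataset.labels, dataset.priors)
    pred = model.forward(mips, train=False)
    l_class = classification_loss(labels, pred.y_hat)
    l_dist = 0.0
    if alpha > 0:
        l_dist, _ = _cam_losses_and_grad(model, pred, labels, priors, want_grad=False)
    return LossReport(l_class=l_class, l_distance=l_dist, alpha=alpha)


def _snapshot(model):
    return [layer.params[name].copy() for layer, name in model.parameters()]


def _restore(model, snap):
    for (layer, name), value in zip(model.parameters(), snap):
        layer.params[name] = value.copy()


def train_classifier(
    train_set: MipDataset,
    config: TrainConfig,
    val_set: MipDataset | None = None,
    classifier_config: ClassifierConfig | None = None,
):
    """Train the MIP classifier with the multitask objective.

    Returns ``(model, history)`` where history is a list of per-epoch
    dicts (train/validation loss components) suitable for a CSV log.
    Early stopping restores the parameters of the best validation epoch;
    with ``config.restarts > 1`` the restart with the lowest selection
    loss (validation if available, else final training loss) wins.
    """
    best = None
    for r in range(max(1, config.restarts)):
        cfg_r = replace(config, seed=config.seed + 101 * r, restarts=1)
        clf_r = classifier_config
        if clf_r is not None and r > 0:
            clf_r = dataclasses.replace(clf_r, seed=clf_r.seed + 101 * r)
        model, history = _train_classifier_once(train_set, cfg_r, val_set, clf_r)
        if val_set is not None:
            score = evaluate_losses(model, val_set, alpha=config.alpha).loss_glob
        else:
            score = history[-1]["loss_glob"]
        if best is None or score < best[0]:
            best = (score, model, history)
    return best[1], best[2]


def _train_classifier_once(
    train_set: MipDataset,
    config: TrainConfig,
    val_set: MipDataset | None = None,
    classifier_config: ClassifierConfig | None = None,
):
    if classifier_config is None:
        classifier_config = ClassifierConfig.small(
            input_shape=train_set.x.shape[2:], seed=config.seed
        )
    model = MipClassifier(classifier_config)
    optimizer = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    best_val, best_snap, stale = np.inf, None, 0
    for epoch in range(config.epochs):
        if epoch in config.lr_milestones:
            optimizer.lr *= config.lr_gamma
        order = rng.permutation(len(train_set))
        l_class_sum = l_dist_sum = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            mips, labels, priors = _flatten_views(
                train_set.x[idx], train_set.labels[idx], train_set.priors[idx]
            )
            if config.flip_augment:
                mips = mips.copy()
                priors = priors.copy()
                width = mips.shape[2]
                for i in range(0, mips.shape[0], 2):  # coronal samples only
                    if rng.random() < 0.5:
                        mips[i] = mips[i, :, ::-1]
                        priors[i, 1] = width - 1 - priors[i, 1]
            report = train_step(
                model, optimizer, mips, labels, priors, alpha=config.alpha
            )
            l_class_sum += report.l_class
            l_dist_sum += report.l_distance
            n_batches += 1
        row = {
            "epoch": epoch,
            "l_class": l_class_sum / n_batches,
            "l_distance": l_dist_sum / n_batches,
        }
        row["loss_glob"] = row["l_class"] + config.alpha * row["l_distance"]
        if val_set is not None:
            val = evaluate_losses(model, val_set, alpha=config.alpha)
            row.update(
                val_l_class=val.l_class,
                val_l_distance=val.l_distance,
                val_loss_glob=val.loss_glob,
            )
            if val.loss_glob < best_val - 1e-9:
                best_val, best_snap, stale = val.loss_glob, _snapshot(model), 0
            else:
                stale += 1
        history.append(row)
        if val_set is not None and stale > config.patience:
            break
    if best_snap is not None:
        _restore(model, best_snap)
    return model, history
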