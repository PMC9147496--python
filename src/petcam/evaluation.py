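"""Segmentation/classification metrics and the cross-validation harness.

Overlap metrics (dice, IoU), confusion-matrix rates (sensitivity,
specificity, accuracy), rank-based AUC, stratified k-fold splitting
with a nested train/validation partition, and an end-to-end pipeline
evaluator that trains the multitask classifier per fold, segments the
held-out patients, and optionally trains the 3D outcome network on
ground-truth or predicted masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .losses import MipDataset, TrainConfig, train_classifier
from .net import ClassifierConfig
from .outcome import OutcomeConfig, crop_tumor, train_outcome
from .preprocess import normalize_suv
from .reconstruct import segment_patient


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero, so the value is undefined."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self):
        return self.tp + self.fn + self.tn + self.fp


def confusion_from_predictions(labels, predictions) -> ConfusionCounts:
    labels = np.asarray(labels).astype(bool)
    predictions = np.asarray(predictions).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(labels & predictions)),
        fn=int(np.sum(labels & ~predictions)),
        tn=int(np.sum(~labels & ~predictions)),
        fp=int(np.sum(~labels & predictions)),
    )


def _check_masks(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(mask_a, mask_b) -> float:
    """2|A n B| / (|A| + |B|); two empty masks agree perfectly (1.0)."""
    a, b = _check_masks(mask_a, mask_b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int(np.sum(a & b)) / (sa + sb)


def iou(mask_a, mask_b) -> float:
    """|A n B| / |A u B|; equals dice / (2 - dice)."""
    a, b = _check_masks(mask_a, mask_b)
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return int(np.sum(a & b)) / union


def sens_spec_acc(c: ConfusionCounts):
    """(sensitivity, specificity, accuracy) from confusion counts;
    raises :class:`UndefinedMetricError` naming any zero denominator."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: TP + FN = 0")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: TN + FP = 0")
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty cohort")
    return (
        c.tp / (c.tp + c.fn),
        c.tn / (c.tn + c.fp),
        (c.tp + c.tn) / c.total,
    )


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; tied scores
    receive half credit."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# cross-validation splits


@dataclass
class FoldSplit:
    train: list
    val: list
    test: list


def make_folds(ids, labels, k=5, seed=0, val_fraction=40 / 155) -> list[FoldSplit]:
    """Stratified k-fold splits with a nested stratified train/validation
    partition of the non-test portion (defaults mimic a 115/40/40 split
    of 195 patients)."""
    ids = list(ids)
    labels = np.asarray(labels)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds cohort size {len(ids)}")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    fold_members = [[] for _ in range(k)]
    offset = 0  # rotates which folds receive each class's remainder
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} members, fewer than k={k} folds"
            )
        rng.shuffle(idx)
        base, rem = divmod(idx.size, k)
        sizes = np.full(k, base)
        for r in range(rem):
            sizes[(offset + r) % k] += 1
        offset += rem
        cursor = 0
        for f in range(k):
            fold_members[f].extend(idx[cursor : cursor + sizes[f]])
            cursor += sizes[f]
    splits = []
    for f in range(k):
        test_idx = np.array(sorted(fold_members[f]))
        rest = np.array(
            sorted(i for g in range(k) if g != f for i in fold_members[g])
        )
        val_idx = []
        for cls in classes:
            cls_rest = rest[labels[rest] == cls]
            n_val = int(round(val_fraction * cls_rest.size))
            perm = rng.permutation(cls_rest)
            val_idx.extend(perm[:n_val])
        val_idx = set(int(i) for i in val_idx)
        splits.append(
            FoldSplit(
                train=[ids[i] for i in rest if i not in val_idx],
                val=[ids[i] for i in sorted(val_idx)],
                test=[ids[i] for i in test_idx],
            )
        )
    return splits


# ---------------------------------------------------------------------------
# end-to-end evaluation


@dataclass
class PipelineConfig:
    """Everything :func:`evaluate_pipeline` needs for one experiment."""

    k: int = 5
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    classifier: ClassifierConfig | None = None
    rel_threshold: float = 0.4
    ablation: bool = False  # additionally run the alpha=0 (no-prior) arm
    outcome: OutcomeConfig | None = None
    outcome_masks: str = "gt"  # "gt" or "predicted"


def _patient_level_probs(model, dataset: MipDataset) -> np.ndarray:
    """Mean of the two per-view lung probabilities for each patient."""
    n = len(dataset)
    mips = dataset.x.reshape(n * 2, *dataset.x.shape[2:])
    probs = model.predict_proba(mips)
    return probs.reshape(n, 2).mean(axis=1)


def _segmentation_metrics(model, patients, rel_threshold):
    rows = []
    for p in patients:
        pred = segment_patient(model, p.volume, rel_threshold=rel_threshold)
        rows.append((dice(pred.data, p.gt_mask), iou(pred.data, p.gt_mask)))
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1]


def _outcome_arm(train_patients, test_patients, model, config: PipelineConfig):
    """Train the outcome net on crops from the chosen mask source and
    score the held-out patients; returns (labels, scores) or None."""
    ocfg = config.outcome
    crops, labels = [], []

    def mask_for(p):
        if config.outcome_masks == "predicted":
            seg = segment_patient(model, p.volume, rel_threshold=config.rel_threshold)
            if seg.data.any():
                return seg.data
            warnings.warn(f"empty predicted mask for {p.id}; using ground truth")
        return p.gt_mask

    for p in train_patients:
        if p.outcome_label is None:
            continue
        vol = normalize_suv(p.volume)
        crops.append(crop_tumor(vol, mask_for(p), crop_shape=ocfg.crop_shape,
                                masked=ocfg.masked))
        labels.append(p.outcome_label)
    if len(set(labels)) < 2:
        warnings.warn("outcome arm skipped: single-class training labels")
        return None
    net, _ = train_outcome(crops, labels, ocfg)
    test_labels, scores = [], []
    for p in test_patients:
        if p.outcome_label is None:
            continue
        vol = normalize_suv(p.volume)
        crop = crop_tumor(vol, mask_for(p), crop_shape=ocfg.crop_shape,
                          masked=ocfg.masked)
        scores.append(float(net.forward(crop.data[None], train=False)[0]))
        test_labels.append(p.outcome_label)
    return np.asarray(test_labels), np.asarray(scores)


def _aggregate(folds: list[dict]) -> dict:
    keys = {k for f in folds for k in f if isinstance(f[k], (int, float))}
    out = {"folds": folds, "mean": {}, "sd": {}}
    for k in sorted(keys):
        vals = np.array([f[k] for f in folds if k in f], dtype=float)
        out["mean"][k] = float(vals.mean())
        out["sd"][k] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return out


def evaluate_pipeline(patients, config: PipelineConfig) -> dict:
    """Cross-validated end-to-end evaluation of the weakly supervised
    pipeline; returns per-fold metrics plus mean and standard deviation
    across folds."""
    by_id = {p.id: p for p in patients}
    labels = [p.class_label for p in patients]
    splits = make_folds([p.id for p in patients], labels, k=config.k, seed=config.seed)
    fold_rows = []
    for f, split in enumerate(splits):
        train_p = [by_id[i] for i in split.train]
        val_p = [by_id[i] for i in split.val]
        test_p = [by_id[i] for i in split.test]
        train_set = MipDataset.from_patients(train_p)
        val_set = MipDataset.from_patients(val_p)
        test_set = MipDataset.from_patients(test_p)
        tc = replace(config.train, seed=config.train.seed + f)
        model, _ = train_classifier(
            train_set, tc, val_set=val_set, classifier_config=config.classifier
        )
        row = {"fold": f}
        probs = _patient_level_probs(model, test_set)
        row["class_accuracy"] = float(
            np.mean((probs >= 0.5).astype(int) == test_set.labels)
        )
        missing_gt = any(p.gt_mask is None for p in test_p)
        if missing_gt:
            warnings.warn("missing ground-truth masks: segmentation metrics skipped")
        else:
            d, j = _segmentation_metrics(model, test_p, config.rel_threshold)
            row["dice"] = float(d.mean())
            row["iou"] = float(j.mean())
        if config.ablation:
            abl_model, _ = train_classifier(
                train_set,
                replace(tc, alpha=0.0),
                val_set=val_set,
                classifier_config=config.classifier,
            )
            if not missing_gt:
                d0, j0 = _segmentation_metrics(abl_model, test_p, config.rel_threshold)
                row["dice_noprior"] = float(d0.mean())
                row["iou_noprior"] = float(j0.mean())
        if config.outcome is not None:
            arm = _outcome_arm(train_p, test_p, model, config)
            if arm is not None:
                y, s = arm
                preds = s >= 0.5
                row["outcome_accuracy"] = float(np.mean(preds == y.astype(bool)))
                if len(np.unique(y)) == 2:
                    row["outcome_auc"] = auc(y, s)
        fold_rows.append(row)
    return _aggregate(fold_rows)
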