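"""End-to-end synthetic benchmark of the weakly supervised pipeline.

Generates a seeded phantom cohort, splits it into train / validation /
test in the proportions of a five-fold protocol (~60/20/20), trains the
multitask classifier with the distance constraint (alpha = 1) and its
no-prior ablation (alpha = 0) under identical budgets, segments the
held-out patients with each arm, and trains the 3D outcome network on
tumor crops.  Problem sizes (60 patients, 64x64x128-voxel volumes,
128x64 MIPs, a reduced stride plan with 32 feature maps, two ensemble
members per arm) are chosen so the whole benchmark runs in minutes on
one CPU while preserving the study's structure.

Both the acceptance tests and ``scripts/acceptance.py`` run this module,
so the reported numbers always come from a fresh computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import auc, dice, iou, make_folds
from .losses import MipDataset, TrainConfig, train_cam_ensemble
from .net import ClassifierConfig
from .outcome import OutcomeConfig, crop_tumor, train_outcome
from .phantom import PhantomSpec, generate_cohort
from .preprocess import normalize_suv
from .reconstruct import refine_by_suv, segment_patient


@dataclass(frozen=True)
class BenchmarkConfig:
    """Reduced-size study conditions for the synthetic benchmark."""

    n_patients: int = 60
    members: int = 2  # ensemble members per training arm
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            alpha=1.0,
            lr=1e-3,
            epochs=200,
            lr_milestones=(120, 170),
            patience=10_000,  # rely on best-validation-epoch restore
            seed=0,
        )
    )
    rel_threshold: float = 0.4
    suv_refine: bool = True  # apply the 40%-of-max protocol inside the prism
    outcome: OutcomeConfig = field(
        default_factory=lambda: OutcomeConfig(
            crop_shape=(24, 24, 24),
            channels=(8, 16),
            dense_width=64,
            lr=3e-3,
            epochs=80,
            seed=0,
            masked=True,  # the volume-rule label is a property of the mask
        )
    )


def _split_cohort(patients, seed):
    """First fold of a stratified five-fold protocol: ~36/12/12 at n=60."""
    labels = [p.class_label for p in patients]
    fold = make_folds([p.id for p in patients], labels, k=5, seed=seed,
                      val_fraction=0.25)[0]
    by_id = {p.id: p for p in patients}
    return ([by_id[i] for i in fold.train],
            [by_id[i] for i in fold.val],
            [by_id[i] for i in fold.test])


def _segmentation_scores(model, patients, config):
    dices, ious = [], []
    for p in patients:
        mask = segment_patient(model, p.volume, rel_threshold=config.rel_threshold)
        if config.suv_refine and mask.data.any():
            mask = refine_by_suv(mask, normalize_suv(p.volume))
        dices.append(dice(mask.data, p.gt_mask))
        ious.append(iou(mask.data, p.gt_mask))
    return float(np.mean(dices)), float(np.mean(ious))


def _patient_accuracy(model, patients):
    ds = MipDataset.from_patients(patients)
    n = len(ds)
    probs = model.predict_proba(ds.x.reshape(n * 2, *ds.x.shape[2:]))
    pred = (probs.reshape(n, 2).mean(axis=1) >= 0.5).astype(int)
    return float(np.mean(pred == ds.labels))


def _outcome_arm(train_patients, test_patients, config, mask_of):
    ocfg = config.outcome
    crops, labels = [], []
    for p in train_patients:
        vol = normalize_suv(p.volume)
        crops.append(crop_tumor(vol, mask_of(p), crop_shape=ocfg.crop_shape,
                                masked=ocfg.masked))
        labels.append(p.outcome_label)
    net, _ = train_outcome(crops, labels, ocfg)
    y, scores = [], []
    for p in test_patients:
        vol = normalize_suv(p.volume)
        crop = crop_tumor(vol, mask_of(p), crop_shape=ocfg.crop_shape,
                          masked=ocfg.masked)
        scores.append(float(net.forward(crop.data[None], train=False)[0]))
        y.append(p.outcome_label)
    y, scores = np.asarray(y), np.asarray(scores)
    out = {"accuracy": float(np.mean((scores >= 0.5) == (y == 1)))}
    if len(np.unique(y)) == 2:
        out["auc"] = auc(y, scores)
    return out


def run_synthetic_benchmark(seed: int = 0, config: BenchmarkConfig | None = None) -> dict:
    """Run the full reduced-size study; returns a flat dict of metrics.

    Keys include ``dice_petcam`` / ``dice_noprior`` (held-out mean dice
    of the distance-constrained arm and the alpha = 0 ablation),
    ``class_accuracy``, and ``outcome_accuracy`` / ``outcome_auc`` for
    the 3D outcome network trained on ground-truth masks (plus
    ``outcome_*_predicted`` for crops from the predicted masks).
    """
    if config is None:
        config = BenchmarkConfig()
    # outcome labels follow the volume-median rule without label flips,
    # so the outcome network's ceiling is set by the data, not by noise
    spec = PhantomSpec(n_patients=config.n_patients, seed=seed, outcome_flip_prob=0.0)
    cohort = generate_cohort(spec)
    train_p, val_p, test_p = _split_cohort(cohort, seed)
    train_set = MipDataset.from_patients(train_p)
    val_set = MipDataset.from_patients(val_p)

    clf_config = ClassifierConfig.small(
        input_shape=train_set.x.shape[2:], seed=config.train.seed + seed
    )
    arms = {}
    for name, alpha in (("petcam", config.train.alpha), ("noprior", 0.0)):
        tc = replace(config.train, alpha=alpha, seed=config.train.seed + seed)
        model, _ = train_cam_ensemble(
            train_set, tc, val_set=val_set,
            classifier_config=clf_config, members=config.members,
        )
        arms[name] = model

    results = {}
    for name, model in arms.items():
        d, j = _segmentation_scores(model, test_p, config)
        results[f"dice_{name}"] = d
        results[f"iou_{name}"] = j
    results["class_accuracy"] = _patient_accuracy(arms["petcam"], test_p)

    ocfg = replace(config.outcome, seed=config.outcome.seed + seed)
    config_o = replace(config, outcome=ocfg)
    gt = _outcome_arm(train_p + val_p, test_p, config_o, lambda p: p.gt_mask)
    results["outcome_accuracy"] = gt["accuracy"]
    if "auc" in gt:
        results["outcome_auc"] = gt["auc"]

    def predicted_mask(p):
        mask = segment_patient(arms["petcam"], p.volume,
                               rel_threshold=config.rel_threshold)
        if config.suv_refine and mask.data.any():
            mask = refine_by_suv(mask, normalize_suv(p.volume))
        if not mask.data.any():
            return p.gt_mask  # fall back rather than crash on a rare miss
        return mask.data

    pred = _outcome_arm(train_p + val_p, test_p, config_o, predicted_mask)
    results["outcome_accuracy_predicted"] = pred["accuracy"]
    if "auc" in pred:
        results["outcome_auc_predicted"] = pred["auc"]
    results["n_patients"] = config.n_patients
    results["n_test"] = len(test_p)
    return results
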