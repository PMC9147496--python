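"""Synthetic PET-like phantom cohorts.

Real FDG-PET exams mix pathological uptake (the tumor) with bright
physiological uptake (brain, bladder, myocardium).  A classifier-derived
activation map cannot tell these apart on intensity alone — which is
precisely why the training objective carries a tumor-center distance
constraint.  The phantom reproduces that statistical structure:

* a low-uptake elliptical body envelope;
* fixed-position high-uptake decoys ("brain" at the top of the volume,
  "bladder" at the bottom, a "heart" offset laterally) whose intensity
  range overlaps the tumor's, so decoys may outshine the tumor;
* exactly one anisotropic Gaussian tumor blob per patient whose position
  encodes the cancer class — esophageal tumors sit on the posterior
  midline, lung tumors in an anterior lateral lobe — making the classes
  separable by tumor x-position by construction;
* a ground-truth mask obtained exactly like the clinical protocol the
  method is evaluated against: a 40%-of-SUVmax threshold of the
  (noise-free) tumor component inside its bounding cuboid;
* one prior point at the tumor center voxel;
* a binary outcome label tied to a tumor property (default: metabolic
  tumor volume above the cohort median) with optional label-flip noise.

Intensities are in SUV-like units; downstream preprocessing clips to
[0, 30] and rescales to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import PetVolume, PriorPoint

GT_THRESHOLD_FRAC = 0.4  # clinical MTV protocol: 40% of SUVmax in the cuboid

OUTCOME_RULES = ("volume-median", "none")


class PhantomSpecError(ValueError):
    """Raised when a phantom specification field is invalid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a synthetic cohort.

    Defaults give 64x64x128-voxel volumes at 2 mm isotropic spacing, so
    the coronal and sagittal MIPs are 128x64 images.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 128)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_patients: int = 20
    class_balance: float = 0.5  # fraction lung
    tumor_intensity_range: tuple[float, float] = (8.0, 20.0)
    decoy_intensity_range: tuple[float, float] = (6.0, 14.0)
    background_intensity: float = 2.0
    noise_sigma: float = 0.5
    outcome_rule: str = "volume-median"
    outcome_flip_prob: float = 0.1
    seed: int = 0

    def validate(self):
        if len(self.volume_shape) != 3 or any(
            int(n) != n or n < 16 for n in self.volume_shape
        ):
            raise PhantomSpecError(
                f"volume_shape must be three integers >= 16, got {self.volume_shape}"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomSpecError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.n_patients < 1:
            raise PhantomSpecError(f"n_patients must be positive, got {self.n_patients}")
        if not 0.0 <= self.class_balance <= 1.0:
            raise PhantomSpecError(
                f"class_balance must be in [0, 1], got {self.class_balance}"
            )
        for name in ("tumor_intensity_range", "decoy_intensity_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise PhantomSpecError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        if self.background_intensity < 0:
            raise PhantomSpecError(
                f"background_intensity must be >= 0, got {self.background_intensity}"
            )
        if self.noise_sigma < 0:
            raise PhantomSpecError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.outcome_rule not in OUTCOME_RULES:
            raise PhantomSpecError(
                f"outcome_rule must be one of {OUTCOME_RULES}, got {self.outcome_rule!r}"
            )
        if not 0.0 <= self.outcome_flip_prob <= 0.5:
            raise PhantomSpecError(
                f"outcome_flip_prob must be in [0, 0.5], got {self.outcome_flip_prob}"
            )


@dataclass
class PhantomPatient:
    """One synthetic patient: volume, class, prior point, truth, outcome."""

    id: str
    volume: PetVolume
    class_label: int  # 0 = esophageal, 1 = lung
    prior_point: PriorPoint
    gt_mask: np.ndarray
    outcome_label: int | None = None
    tumor_center: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))


def _gaussian_blob(shape, center, sigma, amplitude, truncate_cuboid=None):
    """Anisotropic Gaussian uptake blob on the voxel grid; optionally
    truncated to zero outside a bounding cuboid (pairs of index bounds)."""
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = (
        (x - center[0]) ** 2 / (2 * sigma[0] ** 2)
        + (y - center[1]) ** 2 / (2 * sigma[1] ** 2)
        + (z - center[2]) ** 2 / (2 * sigma[2] ** 2)
    )
    blob = amplitude * np.exp(-q)
    if truncate_cuboid is not None:
        (x0, x1), (y0, y1), (z0, z1) = truncate_cuboid
        keep = np.zeros(shape, dtype=bool)
        keep[x0:x1, y0:y1, z0:z1] = True
        blob = np.where(keep, blob, 0.0)
    return blob


def tumor_bounding_cuboid(center, sigma, shape, n_sigma=3.0):
    """Axis-aligned cuboid (index bounds) enclosing the tumor, as a
    physician would draw one around the lesion."""
    bounds = []
    for c, s, n in zip(center, sigma, shape):
        lo = max(0, int(np.floor(c - n_sigma * s)))
        hi = min(n, int(np.ceil(c + n_sigma * s)) + 1)
        bounds.append((lo, hi))
    return tuple(bounds)


def gt_mask_from_component(tumor_component, cuboid, frac=GT_THRESHOLD_FRAC):
    """Mask = voxels inside the cuboid whose (noise-free) tumor uptake is
    at least ``frac`` of the maximum uptake inside the cuboid."""
    (x0, x1), (y0, y1), (z0, z1) = cuboid
    inside = np.zeros(tumor_component.shape, dtype=bool)
    inside[x0:x1, y0:y1, z0:z1] = True
    region = np.where(inside, tumor_component, 0.0)
    peak = region.max()
    if peak <= 0:
        return np.zeros_like(inside)
    return region >= frac * peak


def _sample_tumor_geometry(rng, spec, is_lung):
    nx, ny, nz = spec.volume_shape
    sigma = rng.uniform(3.0, 5.5, size=3)
    z = rng.uniform(0.45, 0.72) * nz
    if is_lung:
        side = rng.integers(0, 2)
        x = rng.uniform(0.18, 0.30) * nx if side == 0 else rng.uniform(0.70, 0.82) * nx
        y = rng.uniform(0.24, 0.40) * ny  # anterior lobe
    else:
        x = (0.5 + rng.uniform(-0.03, 0.03)) * nx  # posterior midline
        y = rng.uniform(0.55, 0.68) * ny
    return (x, y, z), tuple(sigma)


def _body_and_decoys(spec, rng):
    nx, ny, nz = spec.volume_shape
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    x, y, z = np.ogrid[:nx, :ny, :nz]
    envelope = ((x - cx) / (0.45 * nx)) ** 2 + ((y - cy) / (0.38 * ny)) ** 2 <= 1.0
    envelope = envelope & (z >= 1) & (z <= nz - 2)
    body = spec.background_intensity * envelope
    lo, hi = spec.decoy_intensity_range
    shape = spec.volume_shape
    decoys = np.zeros(shape)
    # fixed anatomical-analogue positions, intensity redrawn per patient
    for center, size in (
        ((cx, cy, 0.92 * nz), 3.5),            # brain
        ((cx, cy, 0.08 * nz), 3.0),            # bladder
        ((0.36 * nx, 0.42 * ny, 0.66 * nz), 3.0),  # heart
    ):
        amp = rng.uniform(lo, hi)
        decoys += _gaussian_blob(shape, center, (size, size, size), amp)
    return body, decoys * envelope


def generate_patient(spec: PhantomSpec, rng: np.random.Generator, index: int) -> PhantomPatient:
    """Generate one patient; outcome label is assigned later at cohort level."""
    is_lung = rng.random() < spec.class_balance
    body, decoys = _body_and_decoys(spec, rng)
    center, sigma = _sample_tumor_geometry(rng, spec, is_lung)
    amp = rng.uniform(*spec.tumor_intensity_range)
    cuboid = tumor_bounding_cuboid(center, sigma, spec.volume_shape)
    tumor = _gaussian_blob(spec.volume_shape, center, sigma, amp, truncate_cuboid=cuboid)
    gt = gt_mask_from_component(tumor, cuboid)
    data = body + decoys + tumor
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=spec.volume_shape)
    data = np.maximum(data, 0.0).astype(np.float32)
    prior = PriorPoint(tuple(int(round(c)) for c in center))
    return PhantomPatient(
        id=f"p{index:04d}",
        volume=PetVolume(data, spec.spacing_mm),
        class_label=int(is_lung),
        prior_point=prior,
        gt_mask=gt,
        tumor_center=tuple(float(c) for c in center),
    )


def generate_cohort(spec: PhantomSpec) -> list[PhantomPatient]:
    """Generate a seeded, reproducible cohort of phantom patients."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    patients = [generate_patient(spec, rng, i) for i in range(spec.n_patients)]
    if spec.outcome_rule == "volume-median":
        volumes = np.array([p.gt_mask.sum() for p in patients], dtype=float)
        median = np.median(volumes)
        for p, v in zip(patients, volumes):
            label = int(v > median)
            if spec.outcome_flip_prob > 0 and rng.random() < spec.outcome_flip_prob:
                label = 1 - label
            p.outcome_label = label
    return patients


def _affine(spacing_mm):
    return np.diag(list(spacing_mm) + [1.0])


def write_cohort(patients, directory) -> Path:
    """Write one NIfTI volume + mask per patient and a CSV manifest with
    columns id,class,outcome,px,py,pz (0-based voxel indices).  Returns
    the manifest path."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc
    rows = []
    for p in patients:
        affine = _affine(p.volume.spacing_mm)
        nib.save(
            nib.Nifti1Image(p.volume.data.astype(np.float32), affine),
            directory / f"{p.id}_pet.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(p.gt_mask.astype(np.uint8), affine),
            directory / f"{p.id}_mask.nii.gz",
        )
        px, py, pz = p.prior_point.voxel
        rows.append(
            {
                "id": p.id,
                "class": p.class_label,
                "outcome": -1 if p.outcome_label is None else p.outcome_label,
                "px": px,
                "py": py,
                "pz": pz,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(directory) -> list[PhantomPatient]:
    """Round-trip loader for :func:`write_cohort` output."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    table = pd.read_csv(manifest).rename(columns={"class": "class_label"})
    patients = []
    for row in table.itertuples():
        img = nib.load(directory / f"{row.id}_pet.nii.gz")
        mask = nib.load(directory / f"{row.id}_mask.nii.gz")
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        outcome = None if row.outcome == -1 else int(row.outcome)
        patients.append(
            PhantomPatient(
                id=row.id,
                volume=PetVolume(np.asarray(img.dataobj, dtype=np.float32), spacing),
                class_label=int(row.class_label),
                prior_point=PriorPoint((int(row.px), int(row.py), int(row.pz))),
                gt_mask=np.asarray(mask.dataobj) > 0,
                outcome_label=outcome,
            )
        )
    return patients
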