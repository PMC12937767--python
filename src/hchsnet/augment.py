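"""Leakage-safe splitting and offline augmentation.

The dataset is split patient-level BEFORE any augmentation: all images
of one patient land on the same side, the test side holds only genuine
(unaugmented) images, and augmentation then expands each training class
to a common target count (default 2500 per class, so the six classes
balance to 15,000 records when starting from the full clinical set).

Augmented replicas cycle uniformly over the parents of their class and
each replica draws its transform parameters from a private RNG stream
derived from (seed, parent id, replica index), so regeneration under a
fixed seed is bit-identical regardless of processing order.

Transform composition order is fixed: horizontal flip (p = 0.5),
vertical flip (p = 0.5), rotation theta ~ U[-30, 30] degrees (always),
brightness factor ~ U[0.8, 1.2] (always, clamped to [0, 255]), then an
affine jitter (p = 0.5) with translation up to 10% of the side and
scale ~ U[0.9, 1.1]. Exposed borders are filled by reflection, matching
the preprocessing border policy.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, rotate as _sk_rotate, warp as _sk_warp

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ["image_id", "patient_id", "label", "origin", "parent_image_id"]


@dataclass
class AugmentationPolicy:
    """Transform set and draw probabilities for offline augmentation."""

    hflip_p: float = 0.5
    vflip_p: float = 0.5
    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    rotation_p: float = 1.0
    brightness_range: tuple[float, float] = (0.8, 1.2)
    brightness_p: float = 1.0
    affine_translate_frac: float = 0.10
    affine_scale_range: tuple[float, float] = (0.9, 1.1)
    affine_p: float = 0.5

    def __post_init__(self):
        for p in (self.hflip_p, self.vflip_p, self.rotation_p,
                  self.brightness_p, self.affine_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.rotation_deg, self.brightness_range, self.affine_scale_range):
            if hi < lo:
                raise ValueError(f"range ({lo}, {hi}) not ordered")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitSpec:
    """Patient-disjoint train/test image-id partition."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def side_of(self, image_id: str) -> str:
        if image_id in set(self.train_ids):
            return "train"
        if image_id in set(self.test_ids):
            return "test"
        raise KeyError(image_id)


def stratified_patient_split(
    index: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> SplitSpec:
    """Patient-level stratified split of an original-image index.

    Patients are assigned greedily, class by class, so the test side
    approaches ``test_fraction`` of each class's images while keeping
    patients strictly on one side. A class contributed by a single
    patient goes wholly to train with a warning.
    """
    idx = index.reset_index(drop=True)
    if "origin" in idx.columns and (idx["origin"] != "original").any():
        raise ValueError("split must be computed on original records only")
    if idx["patient_id"].isna().any():
        raise ValueError("every record needs a patient_id")
    rng = np.random.default_rng(seed)

    # each patient stratified by its most frequent class (ties: lexicographic)
    pat_class = (
        idx.groupby("patient_id")["label"]
        .agg(lambda s: s.value_counts().sort_index().idxmax())
    )
    class_counts = idx["label"].value_counts().to_dict()
    imgs_per_patient = idx.groupby("patient_id").size().to_dict()

    test_patients: set[str] = set()
    for label in sorted(class_counts):
        patients = sorted(pat_class[pat_class == label].index)
        if len(patients) <= 1:
            logger.warning(
                "class %s has a single patient; assigned wholly to train", label
            )
            continue
        target = test_fraction * class_counts[label]
        order = rng.permutation(len(patients))
        taken = 0.0
        for k in order:
            if taken >= target:
                break
            p = patients[k]
            n = imgs_per_patient[p]
            # greedy: accept while it brings us closer to the target
            if abs(taken + n - target) <= abs(taken - target):
                test_patients.add(p)
                taken += n
    test_mask = idx["patient_id"].isin(test_patients)
    return SplitSpec(
        train_ids=idx.loc[~test_mask, "image_id"].tolist(),
        test_ids=idx.loc[test_mask, "image_id"].tolist(),
        seed=seed,
    )


def _record_rng(seed: int, parent_id: str, replica: int) -> np.random.Generator:
    """Private, order-independent RNG stream for one augmented record."""
    key = zlib.crc32(str(parent_id).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, key, replica]))


def apply_transform(
    image: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to an image."""
    out = np.asarray(image, dtype=float)
    if rng.random() < policy.hflip_p:
        out = out[:, ::-1, :]
    if rng.random() < policy.vflip_p:
        out = out[::-1, :, :]
    if rng.random() < policy.rotation_p:
        theta = rng.uniform(*policy.rotation_deg)
        if theta != 0.0:
            out = _sk_rotate(out, theta, mode="reflect", order=1, preserve_range=True)
    if rng.random() < policy.brightness_p:
        factor = rng.uniform(*policy.brightness_range)
        out = np.clip(out * factor, 0.0, 255.0)
    if rng.random() < policy.affine_p:
        h, w = out.shape[:2]
        tx = rng.uniform(-policy.affine_translate_frac, policy.affine_translate_frac) * w
        ty = rng.uniform(-policy.affine_translate_frac, policy.affine_translate_frac) * h
        scale = rng.uniform(*policy.affine_scale_range)
        if (tx, ty, scale) != (0.0, 0.0, 1.0):
            tf = AffineTransform(scale=(scale, scale), translation=(tx, ty))
            out = _sk_warp(out, tf.inverse, mode="reflect", order=1, preserve_range=True)
    return np.clip(out, 0.0, 255.0)


def augment_to_target(
    train_index: pd.DataFrame,
    images: dict[str, np.ndarray] | None = None,
    target_per_class: int = 2500,
    policy: AugmentationPolicy | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand every training class to exactly ``target_per_class`` records.

    Returns the augmented index (originals plus replica records). When
    ``images`` is given it must map image_id -> standardized array for
    every parent; augmented arrays are added to it in place. With
    ``images=None`` only the manifest is produced, which is enough for
    bookkeeping and split-integrity checks.
    """
    policy = policy or AugmentationPolicy()
    idx = train_index.reset_index(drop=True)
    new_rows = []
    for label, group in idx.groupby("label", sort=True):
        parents = group.loc[group["origin"] == "original", "image_id"].tolist()
        if not parents:
            raise ValueError(f"class {label!r} has no original training images")
        deficit = target_per_class - len(group)
        if deficit < 0:
            raise ValueError(
                f"class {label!r} already exceeds target ({len(group)} > {target_per_class})"
            )
        pid_of = dict(zip(group["image_id"], group["patient_id"]))
        for k in range(deficit):
            parent = parents[k % len(parents)]
            replica = k // len(parents)
            image_id = f"{parent}_aug{replica:04d}"
            new_rows.append(
                dict(
                    image_id=image_id,
                    patient_id=pid_of[parent],
                    label=label,
                    origin="augmented",
                    parent_image_id=parent,
                )
            )
            if images is not None:
                rng = _record_rng(seed, parent, replica)
                images[image_id] = apply_transform(images[parent], policy, rng)
    if new_rows:
        out = pd.concat([idx, pd.DataFrame(new_rows)], ignore_index=True)
    else:
        out = idx.copy()
    return out


def check_no_leakage(index: pd.DataFrame, split: SplitSpec) -> None:
    """Exhaustive scan asserting the split invariants.

    Raises if a patient spans both sides, an augmented record sits on a
    different side from its parent, or the test side contains anything
    but original images.
    """
    idx = index.reset_index(drop=True)
    side = {i: "train" for i in split.train_ids}
    side.update({i: "test" for i in split.test_ids})
    per_patient: dict[str, set[str]] = {}
    for _, row in idx.iterrows():
        s = side.get(row["image_id"])
        if s is None:
            s = side.get(row["parent_image_id"])
        if s is None:
            raise AssertionError(f"record {row['image_id']} not covered by split")
        per_patient.setdefault(row["patient_id"], set()).add(s)
        if s == "test" and row["origin"] != "original":
            raise AssertionError(f"augmented record {row['image_id']} in test side")
        if row["origin"] == "augmented":
            ps = side.get(row["parent_image_id"])
            if ps != s:
                raise AssertionError(
                    f"augmented record {row['image_id']} crosses the split boundary"
                )
    for patient, sides in per_patient.items():
        if len(sides) > 1:
            raise AssertionError(f"patient {patient} appears on both sides")
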