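"""End-to-end orchestration: images + metadata -> fitted ensemble + report.

Ties the stages together in the leakage-safe order: patient-level split
first, metadata statistics fitted on the training side only, optional
offline augmentation of the training side, feature extraction, ensemble
training, evaluation on genuine test images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy, SplitSpec, augment_to_target, stratified_patient_split
from .ensemble import BoosterConfig, LesionEnsembleModel, LesionEnsembleResults, default_configs
from .features import feature_names, fuse
from .color import extract_color
from .metadata import MetadataStats, encode, fit_stats
from .metrics import MetricsReport
from .preprocess import preprocess
from .shape import extract_shape
from .texture import extract_texture


def visual_feature_table(
    std_images: dict[str, np.ndarray], image_ids=None, levels: int = 256
) -> pd.DataFrame:
    """116-d visual descriptors for standardized images, one row per id."""
    ids = list(image_ids) if image_ids is not None else list(std_images)
    rows = [
        fuse(extract_color(std_images[i]),
             extract_texture(std_images[i], levels=levels),
             extract_shape(std_images[i]), None)
        for i in ids
    ]
    return pd.DataFrame(rows, index=ids, columns=feature_names("chs"))


def feature_table(
    std_images: dict[str, np.ndarray],
    manifest: pd.DataFrame,
    stats: MetadataStats,
    levels: int = 256,
) -> pd.DataFrame:
    """Full 128-d fused feature table aligned with the manifest rows."""
    visual = visual_feature_table(std_images, manifest["image_id"], levels=levels)
    meta = np.vstack([encode(row, stats) for _, row in manifest.iterrows()])
    out = pd.concat(
        [visual.reset_index(drop=True),
         pd.DataFrame(meta, columns=feature_names("m"))],
        axis=1,
    )
    out.index = list(manifest["image_id"])
    return out


@dataclass
class PipelineResult:
    """Everything a pipeline run produced."""

    results: LesionEnsembleResults
    report: MetricsReport
    split: SplitSpec
    stats: MetadataStats
    train_features: pd.DataFrame
    test_features: pd.DataFrame
    train_labels: pd.Series
    test_labels: pd.Series


def run_pipeline(
    images: dict[str, np.ndarray],
    manifest: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    vote: str = "soft",
    iterations: int = 500,
    levels: int = 256,
    augment_target: int | None = None,
    policy: AugmentationPolicy | None = None,
    with_ci: bool = False,
    kernel_size: int = 5,
    sigma: float = 1.0,
) -> PipelineResult:
    """Run the full classification pipeline on raw images + metadata.

    ``augment_target`` expands every training class to that count by
    offline augmentation before feature extraction; None disables
    augmentation (appropriate when classes are already balanced).
    """
    manifest = manifest.reset_index(drop=True).copy()
    if "origin" not in manifest.columns:
        manifest["origin"] = "original"
        manifest["parent_image_id"] = None

    split = stratified_patient_split(manifest, test_fraction=test_fraction, seed=seed)
    train_mask = manifest["image_id"].isin(set(split.train_ids))
    train_manifest = manifest[train_mask].reset_index(drop=True)
    test_manifest = manifest[~train_mask].reset_index(drop=True)

    stats = fit_stats(train_manifest, eps=1e-8)

    std = {i: preprocess(images[i], kernel_size=kernel_size, sigma=sigma)
           for i in manifest["image_id"]}

    if augment_target is not None:
        idx_cols = ["image_id", "patient_id", "label", "origin", "parent_image_id"]
        aug_index = augment_to_target(
            train_manifest[idx_cols], images=std,
            target_per_class=augment_target, policy=policy, seed=seed,
        )
        # augmented records inherit the parent's clinical record
        meta_cols = [c for c in train_manifest.columns if c not in idx_cols]
        parent_meta = train_manifest.set_index("image_id")[meta_cols]
        filled = []
        for _, row in aug_index.iterrows():
            src = row["image_id"] if row["origin"] == "original" else row["parent_image_id"]
            filled.append(parent_meta.loc[src])
        train_manifest = pd.concat(
            [aug_index.reset_index(drop=True),
             pd.DataFrame(filled).reset_index(drop=True)], axis=1,
        )

    train_X = feature_table(std, train_manifest, stats, levels=levels)
    test_X = feature_table(std, test_manifest, stats, levels=levels)

    model = LesionEnsembleModel(
        train_X, train_manifest["label"],
        configs=default_configs(seed=seed, iterations=iterations),
        vote=vote, feature_names=list(train_X.columns),
    )
    results = model.fit()
    report = results.evaluate(test_X, test_manifest["label"], with_ci=with_ci, seed=seed)
    return PipelineResult(
        results=results, report=report, split=split, stats=stats,
        train_features=train_X, test_features=test_X,
        train_labels=train_manifest["label"], test_labels=test_manifest["label"],
    )
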