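"""Feature fusion: [color 96 | texture 13 | shape 7 | metadata 12] = 128.

The three visual blocks concatenate to a 116-d visual descriptor; the
12-d clinical-metadata encoding appends to give the 128-d fused vector.
No scaling is applied at fusion — each block carries its own
normalization (L2 for color histograms, signed-log for Hu, z-score for
continuous metadata) and the tree ensembles downstream are insensitive
to monotone per-feature scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .color import COLOR_FEATURE_NAMES, extract_color
from .metadata import MetadataStats, encode
from .shape import SHAPE_FEATURE_NAMES, extract_shape
from .texture import TEXTURE_FEATURE_NAMES, extract_texture

BLOCK_SIZES = {"color": 96, "texture": 13, "shape": 7, "meta": 12}
VISUAL_DIM = 116
FUSED_DIM = 128

#: Block membership of each fused-feature column, for importance reports.
FEATURE_BLOCKS = (
    ["color"] * 96 + ["haralick"] * 13 + ["hu"] * 7 + ["meta"] * 12
)

META_FEATURE_NAMES = [
    "meta_age_z", "meta_gender", "meta_d1_z", "meta_d2_z",
    "meta_smoke", "meta_drink", "meta_itch", "meta_grew",
    "meta_hurt", "meta_changed", "meta_bleed", "meta_elevation",
]


def feature_names(blocks: str = "chsm") -> list[str]:
    """Column names for a feature-block selection.

    ``blocks`` is any subset of the letters c (color), h (haralick
    texture), s (shape) and m (metadata), e.g. "chs" for visual-only.
    """
    names: list[str] = []
    if "c" in blocks:
        names += COLOR_FEATURE_NAMES
    if "h" in blocks:
        names += TEXTURE_FEATURE_NAMES
    if "s" in blocks:
        names += SHAPE_FEATURE_NAMES
    if "m" in blocks:
        names += META_FEATURE_NAMES
    return names


def fuse(
    color: np.ndarray | None,
    texture: np.ndarray | None,
    shape: np.ndarray | None,
    meta: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate feature blocks in the fixed order color|texture|shape|meta.

    Blocks passed as None are omitted (ablation configurations); blocks
    present must have their exact nominal length.
    """
    parts = []
    for name, block, size in [
        ("color", color, 96), ("texture", texture, 13),
        ("shape", shape, 7), ("meta", meta, 12),
    ]:
        if block is None:
            continue
        block = np.asarray(block, dtype=float)
        if block.shape != (size,):
            raise ValueError(
                f"{name} block has shape {block.shape}, expected ({size},)"
            )
        parts.append(block)
    if not parts:
        raise ValueError("at least one feature block required")
    return np.concatenate(parts)


def extract_visual(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """116-d visual descriptor of one standardized image."""
    return fuse(
        extract_color(image), extract_texture(image, levels=levels),
        extract_shape(image), None,
    )


def extract_hchs(
    image: np.ndarray,
    record: dict | pd.Series,
    stats: MetadataStats,
    levels: int = 256,
) -> np.ndarray:
    """Full 128-d fused descriptor for one image + clinical record."""
    return fuse(
        extract_color(image),
        extract_texture(image, levels=levels),
        extract_shape(image),
        encode(record, stats),
    )
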