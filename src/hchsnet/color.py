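"""HSV color-histogram features (96 dimensions).

Lesion chromaticity is a primary diagnostic cue: melanomas are
variegated (browns, blacks, reds, blues) while benign nevi are more
uniform. The image is converted to HSV so chroma decouples from
intensity, each channel is summarised by a 32-bin histogram, and each
histogram is L2-normalized for brightness invariance.

Canonical channel ranges are H in [0, 360), S in [0, 1], V in [0, 1]
with 32 equal-width bins per channel; the last bin is closed on the
right so the bins partition the pixels exactly. Pixels with zero
saturation have undefined hue and are assigned H = 0.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv

N_BINS = 32

#: Exported feature column names, colorH_00 ... colorV_31.
COLOR_FEATURE_NAMES = [
    f"color{ch}_{k:02d}" for ch in ("H", "S", "V") for k in range(N_BINS)
]


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert a standardized RGB image (values in [0, 255]) to HSV.

    Returns an HxWx3 float array with H in degrees [0, 360), S and V in
    [0, 1]. Zero-saturation pixels get H = 0.
    """
    arr = np.asarray(image, dtype=float) / 255.0
    hsv = rgb2hsv(arr)
    hsv[..., 0] *= 360.0
    # rgb2hsv already maps achromatic pixels to H = 0
    return hsv


def channel_histogram(
    plane: np.ndarray, range_lo: float, range_hi: float, bins: int = N_BINS
) -> np.ndarray:
    """Equal-width histogram counts over [range_lo, range_hi].

    Bins are half-open [b_k, b_{k+1}) except the last, which is closed,
    so the counts always sum to the pixel count.
    """
    if range_hi <= range_lo:
        raise ValueError(f"empty range [{range_lo}, {range_hi}]")
    counts, _ = np.histogram(
        np.asarray(plane, dtype=float).ravel(), bins=bins, range=(range_lo, range_hi)
    )
    return counts.astype(float)


def l2_normalize(vec: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Divide by (||vec||_2 + eps); the zero vector maps to itself."""
    vec = np.asarray(vec, dtype=float)
    return vec / (np.linalg.norm(vec) + eps)


def extract_color(image: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """96-d color descriptor: L2-normalized 32-bin histograms of H, S, V."""
    hsv = rgb_to_hsv(image)
    blocks = [
        l2_normalize(channel_histogram(hsv[..., 0], 0.0, 360.0), eps),
        l2_normalize(channel_histogram(hsv[..., 1], 0.0, 1.0), eps),
        l2_normalize(channel_histogram(hsv[..., 2], 0.0, 1.0), eps),
    ]
    return np.concatenate(blocks)
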