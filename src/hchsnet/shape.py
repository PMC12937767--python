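"""Hu moment shape features (7 dimensions).

The seven Hu invariants are polynomial combinations of normalized
central image moments and are invariant to translation, rotation and
scale — a mathematical analogue of the asymmetry/border components of
the dermatological ABCD rule. Moments are computed directly on the
grayscale intensity image (no binarization or segmentation), so the
descriptors reflect the intensity mass distribution of the whole frame.

Because raw Hu values span many orders of magnitude, each is mapped to
a signed log scale, h~ = -sign(h) * log10(|h| + eps) with eps = 1e-10,
before classification. sign(0) := 0, so an exactly-zero invariant maps
to 0 rather than +-10.

Coordinate convention: x is the column index, y the row index, both
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .texture import to_gray

SHAPE_FEATURE_NAMES = [f"hu_{i}" for i in range(1, 8)]


@dataclass
class MomentSet:
    """Raw, central and normalized central moments through order 3."""

    m: dict[tuple[int, int], float] = field(default_factory=dict)
    mu: dict[tuple[int, int], float] = field(default_factory=dict)
    eta: dict[tuple[int, int], float] = field(default_factory=dict)
    centroid: tuple[float, float] = (0.0, 0.0)  # (x_bar, y_bar)


def central_moments(gray: np.ndarray) -> MomentSet:
    """Raw moments m_pq, central moments mu_pq and normalized moments
    eta_pq = mu_pq / mu_00^((p+q)/2 + 1) for all orders p + q <= 3.

    Raises on an all-zero image, whose centroid is undefined.
    """
    arr = np.asarray(gray, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {arr.shape}")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero image: centroid undefined")
    ys, xs = np.mgrid[0 : arr.shape[0], 0 : arr.shape[1]]
    xs = xs.astype(float)
    ys = ys.astype(float)

    ms = MomentSet()
    for p in range(4):
        for q in range(4):
            if p + q <= 3:
                ms.m[(p, q)] = float((xs**p * ys**q * arr).sum())
    x_bar = ms.m[(1, 0)] / ms.m[(0, 0)]
    y_bar = ms.m[(0, 1)] / ms.m[(0, 0)]
    ms.centroid = (x_bar, y_bar)
    dx = xs - x_bar
    dy = ys - y_bar
    for p in range(4):
        for q in range(4):
            if p + q <= 3:
                ms.mu[(p, q)] = float((dx**p * dy**q * arr).sum())
    mu00 = ms.mu[(0, 0)]
    for (p, q), mu in ms.mu.items():
        if 2 <= p + q <= 3:
            ms.eta[(p, q)] = mu / mu00 ** ((p + q) / 2.0 + 1.0)
    return ms


def hu_invariants(moments: MomentSet) -> np.ndarray:
    """The classic seven Hu invariants from normalized central moments."""
    e = moments.eta
    n20, n02, n11 = e[(2, 0)], e[(0, 2)], e[(1, 1)]
    n30, n03 = e[(3, 0)], e[(0, 3)]
    n21, n12 = e[(2, 1)], e[(1, 2)]

    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    h7 = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def log_stabilize(h: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Signed log compression: -sign(h) * log10(|h| + eps), sign(0) = 0."""
    h = np.asarray(h, dtype=float)
    return -np.sign(h) * np.log10(np.abs(h) + eps)


def extract_shape(image: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """7-d shape descriptor: grayscale -> moments -> Hu -> signed log."""
    gray = to_gray(image)
    return log_stabilize(hu_invariants(central_moments(gray)), eps=eps)
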