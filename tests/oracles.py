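"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities from first principles with naive
loops — no shared code paths with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def convolve2d_reflect(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct nested-loop 2-D convolution with reflect (symmetric) padding."""
    h, w = plane.shape
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    # edge-inclusive reflection: (d c b a | a b c d), matching the
    # package's border policy
    padded = np.pad(plane, ((rh, rh), (rw, rw)), mode="symmetric")
    out = np.zeros_like(plane, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    acc += kernel[i, j] * padded[r + i, c + j]
            out[r, c] = acc
    return out


_OFFSETS = {0.0: (0, 1), 45.0: (-1, 1), 90.0: (-1, 0), 135.0: (-1, -1)}


def glcm_pairs(gray: np.ndarray, d: int, theta: float, levels: int) -> np.ndarray:
    """Symmetric normalized GLCM by explicit pair enumeration."""
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = gray.shape
    counts = np.zeros((levels, levels), dtype=float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = int(gray[r, c]), int(gray[r2, c2])
                counts[i, j] += 1
                counts[j, i] += 1
    return counts / counts.sum()


def _log2(x: float) -> float:
    return math.log2(x) if x > 0 else 0.0


def haralick_literal(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics, every sum written out from scratch."""
    g = P.shape[0]
    px = [sum(P[i, j] for j in range(g)) for i in range(g)]
    py = [sum(P[i, j] for i in range(g)) for j in range(g)]
    mu_x = sum(i * px[i] for i in range(g))
    mu_y = sum(j * py[j] for j in range(g))
    sx = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(g)))
    sy = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(g)))
    p_sum = [0.0] * (2 * g - 1)
    p_diff = [0.0] * g
    for i in range(g):
        for j in range(g):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    asm = sum(P[i, j] ** 2 for i in range(g) for j in range(g))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(g) for j in range(g))
    if sx * sy > 0:
        correlation = sum(
            (i - mu_x) * (j - mu_y) * P[i, j] for i in range(g) for j in range(g)
        ) / (sx * sy)
    else:
        correlation = 0.0
    variance = sum((i - mu_x) ** 2 * P[i, j] for i in range(g) for j in range(g))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    sum_avg = sum(k * p_sum[k] for k in range(2 * g - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * g - 1))
    sum_ent = -sum(p * _log2(p) for p in p_sum)
    entropy = -sum(P[i, j] * _log2(P[i, j]) for i in range(g) for j in range(g))
    mu_d = sum(k * p_diff[k] for k in range(g))
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(g))
    diff_ent = -sum(p * _log2(p) for p in p_diff)
    hx = -sum(p * _log2(p) for p in px)
    hy = -sum(p * _log2(p) for p in py)
    hxy1 = -sum(
        P[i, j] * _log2(px[i] * py[j]) for i in range(g) for j in range(g)
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j]) for i in range(g) for j in range(g)
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    return np.array([
        asm, contrast, correlation, variance, idm,
        sum_avg, sum_var, sum_ent, entropy,
        diff_var, diff_ent, imc1, imc2,
    ])


def moments_loops(gray: np.ndarray):
    """Central and normalized moments by explicit double loops.

    Returns (mu, eta) dicts keyed by (p, q); x = column, y = row.
    """
    h, w = gray.shape
    m = {}
    for p in range(4):
        for q in range(4):
            if p + q <= 3:
                m[(p, q)] = sum(
                    (c**p) * (r**q) * float(gray[r, c])
                    for r in range(h) for c in range(w)
                )
    xb = m[(1, 0)] / m[(0, 0)]
    yb = m[(0, 1)] / m[(0, 0)]
    mu = {}
    for p in range(4):
        for q in range(4):
            if p + q <= 3:
                mu[(p, q)] = sum(
                    ((c - xb) ** p) * ((r - yb) ** q) * float(gray[r, c])
                    for r in range(h) for c in range(w)
                )
    eta = {
        k: v / mu[(0, 0)] ** ((k[0] + k[1]) / 2.0 + 1.0)
        for k, v in mu.items() if 2 <= k[0] + k[1] <= 3
    }
    return mu, eta


def histogram_tally(plane: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    """Per-pixel bin tally with last-bin-closed convention."""
    counts = np.zeros(bins)
    width = (hi - lo) / bins
    for v in np.asarray(plane, dtype=float).ravel():
        k = int((v - lo) // width)
        if k == bins:  # v == hi lands in the last (closed) bin
            k = bins - 1
        counts[k] += 1
    return counts
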