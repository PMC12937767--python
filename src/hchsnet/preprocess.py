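"""Image preprocessing: Gaussian smoothing and spatial normalization.

Every raw clinical photograph, whatever its resolution, is denoised with
a small Gaussian kernel (default 5x5, sigma = 1.0) and resampled to a
fixed 224x224 grid by bilinear interpolation. All three feature
extractors consume this standardized image.

Arithmetic stays in floating point throughout; quantization back to
8-bit happens only on file export, so no rounding error is introduced
before feature extraction.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import convolve
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

#: Side length of the standardized image.
STANDARD_SIZE = 224


def make_gaussian_kernel(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Discrete 2-D Gaussian kernel, normalized to unit sum.

    Weights are proportional to exp(-(x^2 + y^2) / (2 sigma^2)) with
    (x, y) integer offsets from the kernel center, then renormalized so
    the kernel conserves intensity on constant images.

    Parameters
    ----------
    size : odd int
        Kernel side length.
    sigma : float
        Standard deviation in pixels; must be positive.
    """
    if not isinstance(size, (int, np.integer)) or size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {size!r}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    half = size // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(offsets, offsets)
    weights = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return weights / weights.sum()


def _check_raw(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        warnings.warn("single-channel image replicated to 3 channels")
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {image.shape}")
    return image.astype(float)


def smooth(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-channel 2-D convolution with reflected-border padding.

    The kernel sums to one, so the output is a convex combination of
    input pixels and never leaves the input intensity range.
    """
    image = _check_raw(image)
    out = np.empty_like(image)
    for c in range(3):
        out[..., c] = convolve(image[..., c], kernel, mode="reflect")
    return out


def resize_to_standard(image: np.ndarray, size: int = STANDARD_SIZE) -> np.ndarray:
    """Bilinear resample onto the standard size x size grid.

    Uses the half-pixel-center convention (align_corners = false): the
    output pixel at index i samples the input at (i + 0.5) * scale - 0.5.
    A native-resolution input passes through unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError(f"cannot resize degenerate image of shape {image.shape}")
    if image.shape[0] == size and image.shape[1] == size:
        return image.copy()
    out = _sk_resize(
        image, (size, size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0.0, 255.0)


def preprocess(
    image: np.ndarray,
    kernel_size: int = 5,
    sigma: float = 1.0,
    size: int = STANDARD_SIZE,
) -> np.ndarray:
    """Smooth then resize a raw RGB image to the standard representation."""
    kernel = make_gaussian_kernel(kernel_size, sigma)
    return resize_to_standard(smooth(image, kernel), size=size)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file into an HxWx3 uint8 array.

    Grayscale files are replicated to three channels with a warning;
    alpha channels are dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB") if im.mode not in ("L", "RGB") else im)
    except OSError as exc:
        raise OSError(f"cannot read image file {path}") from exc
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: grayscale input replicated to 3 channels")
        arr = np.stack([arr] * 3, axis=-1)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Quantize a float image to 8 bits and write it as PNG."""
    arr = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path))
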