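"""Shared 2-D filtering helpers with a package-wide boundary-mode convention.

Every stage of the pipeline (transform, feature maps, region energy, PCNN
linking) filters through :func:`conv2d` so that a single ``boundary`` switch
makes the whole pipeline either symmetric-padded (the default for image data)
or periodic (circular), in which case each stage commutes exactly with
circular shifts.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: boundary-mode names accepted throughout the package -> scipy.ndimage modes
_MODES = {
    "symmetric": "reflect",   # (d c b a | a b c d) half-sample symmetric
    "periodic": "wrap",
    "zero": "constant",
    "replicate": "nearest",
}


def conv2d(image: np.ndarray, kernel: np.ndarray, boundary: str = "symmetric") -> np.ndarray:
    """Zero-phase 2-D convolution of ``image`` with a centred ``kernel``.

    Kernels may have even extent after upsampling; scipy's origin convention
    keeps the result centred for odd-sized kernels, which all kernels here are
    (odd sizes are enforced by the filter constructors).
    """
    if boundary not in _MODES:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    image = np.asarray(image, dtype=np.float64)
    return ndimage.convolve(image, kernel, mode=_MODES[boundary], cval=0.0)


def check_image(image: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate a single-channel 2-D raster and return it as float64."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def center_weighted_template(window: int) -> np.ndarray:
    """Normalized centre-weighted template W(a,b) ∝ window − |a| − |b|.

    For ``window == 3`` this is exactly (1/15)·[[1,2,1],[2,3,2],[1,2,1]], the
    template used by the sum-modified-Laplacian feature; larger odd windows
    extend the same pyramid profile.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    r = window // 2
    a = np.abs(np.arange(-r, r + 1))
    w = (window - (a[:, None] + a[None, :])).astype(np.float64)
    w = np.clip(w, 1.0, None)
    return w / w.sum()
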