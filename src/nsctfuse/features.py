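"""External-input feature maps for the PCNN.

Two clarity/edge features drive the network instead of raw coefficients:

* NSML — the (novel) sum-modified Laplacian, a window-weighted sum of squared
  absolute second differences; used on the low-pass subband, where it picks up
  residual edge detail.
* EOE — energy of edge, the weighted local sum of squared responses to three
  directional operators (horizontal, vertical, diagonal); used on each
  high-pass directional subband.

Both are non-negative, translation covariant and quadratic under intensity
scaling (``feature(kC) = k² feature(C)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._filters import center_weighted_template, check_image, conv2d

__all__ = ["FeatureMap", "nsml_map", "eoe_map", "EOE_OPERATORS"]

#: the three directional filtering operators of the EOE feature
EOE_OPERATORS = (
    np.array([[-1.0, -1.0, -1.0], [2.0, 2.0, 2.0], [-1.0, -1.0, -1.0]]),   # horizontal
    np.array([[-1.0, 2.0, -1.0], [-1.0, 2.0, -1.0], [-1.0, 2.0, -1.0]]),   # vertical
    np.array([[-1.0, 0.0, -1.0], [0.0, 4.0, 0.0], [-1.0, 0.0, -1.0]]),     # diagonal
)


@dataclass(frozen=True)
class FeatureMap:
    values: np.ndarray
    kind: str  # {"NSML", "EOE"}


def nsml_map(C: np.ndarray, window: int = 3, boundary: str = "symmetric") -> FeatureMap:
    """Novel sum-modified Laplacian of a (low-pass) coefficient image.

    ``M(i,j) = |2C - C(i-1,j) - C(i+1,j)| + |2C - C(i,j-1) - C(i,j+1)|`` and
    ``NSML = Σ W(a,b) M(i+a, j+b)²`` with the centre-weighted template
    ``W = (1/15)[[1,2,1],[2,3,2],[1,2,1]]`` for ``window=3`` (window 5 or 7
    extend the same pyramid profile).
    """
    C = check_image(C, "C")
    if window not in (3, 5, 7):
        raise ValueError(f"window must be one of 3, 5, 7, got {window}")
    lap_v = np.array([[-1.0], [2.0], [-1.0]])
    lap_h = lap_v.T
    M = np.abs(conv2d(C, lap_v, boundary)) + np.abs(conv2d(C, lap_h, boundary))
    W = center_weighted_template(window)
    return FeatureMap(conv2d(M**2, W, boundary), "NSML")


def eoe_map(
    C: np.ndarray, W: np.ndarray | None = None, boundary: str = "symmetric"
) -> FeatureMap:
    """Energy of edge of a (high-pass) coefficient image.

    ``LE = (E1*C)² + (E2*C)² + (E3*C)²`` with the three directional operators,
    then ``EOE = Σ W(a,b) LE(i+a, j+b)`` over the 3×3 neighbourhood.  ``W``
    defaults to the same normalized centre-weighted template as NSML.
    """
    C = check_image(C, "C")
    W = center_weighted_template(3) if W is None else np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1] or W.shape[0] % 2 == 0:
        raise ValueError(f"W must be a square odd-sized template, got shape {W.shape}")
    LE = np.zeros_like(C)
    for E in EOE_OPERATORS:
        LE += conv2d(C, E, boundary) ** 2
    return FeatureMap(conv2d(LE, W, boundary), "EOE")
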