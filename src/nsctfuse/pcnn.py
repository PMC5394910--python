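"""Simplified pulse-coupled neural network (PCNN) with adaptive linking.

One neuron per pixel.  Per iteration ``n = 1..n_iter``::

    F[n]     = S                                   (feeding = external input)
    L[n]     = exp(-alpha_L) L[n-1] + V_L (W ⊛ Y[n-1])
    U[n]     = F[n] (1 + beta L[n])
    theta'   = exp(-alpha_theta) theta[n-1]
    Y[n]     = 1  if U[n] >= theta'  else 0
    theta[n] = theta' + V_theta Y[n]

i.e. the feeding channel has no memory, the dynamic threshold decays
geometrically and is recharged by ``V_theta`` on firing.  The firing map is
the cumulative count of firing events over all iterations — a stable ordinal
signal of how early/often each neuron ignites, which is what the fusion rules
compare.

The linking strength ``beta`` is not a global constant here: it is the region
average gradient of the stimulus image (:func:`linking_strength_map`), so
neurons in high-clarity regions link more strongly and ignite earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._filters import _MODES, check_image

__all__ = ["PCNNParams", "linking_strength_map", "run_pcnn"]


def _default_link_kernel() -> np.ndarray:
    # inverse Euclidean distance to the 8 neighbours; no self-linking
    s = 1.0 / np.sqrt(2.0)
    return np.array([[s, 1.0, s], [1.0, 0.0, 1.0], [s, 1.0, s]])


@dataclass
class PCNNParams:
    """Constants of the simplified PCNN.

    All decay/normalizing constants are per-iteration and dimensionless.
    Defaults are conventional simplified-PCNN settings; they are deliberately
    conservative (``n_iter = 200`` lets even weak stimuli fire a few times
    under ``alpha_theta = 0.2``, ``V_theta = 20``).
    """

    alpha_L: float = 0.06931
    alpha_theta: float = 0.2
    V_L: float = 1.0
    V_theta: float = 20.0
    link_kernel: np.ndarray = field(default_factory=_default_link_kernel)
    n_iter: int = 200
    theta_init: float = 1.0

    def __post_init__(self):
        self.link_kernel = np.asarray(self.link_kernel, dtype=np.float64)
        for name in ("alpha_L", "alpha_theta", "V_L", "V_theta", "theta_init"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.link_kernel.shape != (3, 3) or np.any(self.link_kernel < 0):
            raise ValueError("link_kernel must be a non-negative 3x3 array")
        if self.link_kernel[1, 1] != 0:
            raise ValueError("link_kernel centre must be 0 (no self-linking)")


def linking_strength_map(C: np.ndarray, boundary: str = "replicate") -> np.ndarray:
    """Region average gradient, used as the per-pixel linking strength β.

    ``β(i,j)`` averages ``sqrt((g1 + g2) / 2)`` over the 3×3 neighbourhood,
    where ``g1``/``g2`` are squared forward differences down/right.  At the
    last row/column the forward difference is taken against a replicated edge
    (hence zero) in the default mode; ``boundary='periodic'`` wraps instead so
    the map commutes with circular shifts.
    """
    C = check_image(C, "C")
    if boundary == "periodic":
        g1 = (C - np.roll(C, -1, axis=0)) ** 2
        g2 = (C - np.roll(C, -1, axis=1)) ** 2
    else:
        g1 = np.zeros_like(C)
        g1[:-1, :] = (C[:-1, :] - C[1:, :]) ** 2
        g2 = np.zeros_like(C)
        g2[:, :-1] = (C[:, :-1] - C[:, 1:]) ** 2
    g = np.sqrt((g1 + g2) / 2.0)
    mode = _MODES["periodic" if boundary == "periodic" else "replicate"]
    # (1/9) Σ over the 3x3 window == uniform mean; clamp the filter's tiny
    # negative rounding residues so beta stays non-negative
    return np.clip(ndimage.uniform_filter(g, size=3, mode=mode), 0.0, None)


def run_pcnn(S: np.ndarray, beta: np.ndarray | float, params: PCNNParams | None = None,
             boundary: str = "zero") -> np.ndarray:
    """Iterate the PCNN and return the cumulative firing-count map.

    Parameters
    ----------
    S : stimulus in [0, 1] (the caller normalizes; out-of-range input beyond
        1e-9 raises, guarding against a missed normalization).
    beta : per-pixel linking strength (or a scalar), >= 0.
    boundary : padding for the linking convolution; ``'zero'`` by default so
        border neurons simply have fewer neighbours, ``'periodic'`` for exact
        shift covariance.

    Returns
    -------
    counts : integer array, ``0 <= counts <= n_iter``.
    """
    S = check_image(S, "S")
    if np.min(S) < -1e-9 or np.max(S) > 1.0 + 1e-9:
        raise ValueError(
            f"stimulus must be normalized to [0, 1]; got range "
            f"[{np.min(S):.6g}, {np.max(S):.6g}]"
        )
    params = PCNNParams() if params is None else params
    beta = np.broadcast_to(np.asarray(beta, dtype=np.float64), S.shape)
    if np.any(beta < 0):
        raise ValueError("beta must be non-negative")

    decay_L = np.exp(-params.alpha_L)
    decay_T = np.exp(-params.alpha_theta)
    mode = _MODES["periodic" if boundary == "periodic" else "zero"]

    L = np.zeros_like(S)
    Y = np.zeros_like(S)
    theta = np.full_like(S, params.theta_init)
    counts = np.zeros(S.shape, dtype=np.int64)
    for _ in range(params.n_iter):
        L = decay_L * L + params.V_L * ndimage.correlate(
            Y, params.link_kernel, mode=mode, cval=0.0
        )
        U = S * (1.0 + beta * L)
        theta = decay_T * theta
        Y = (U >= theta).astype(np.float64)
        theta = theta + params.V_theta * Y
        counts += Y.astype(np.int64)
    return counts
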