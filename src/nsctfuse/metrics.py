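"""Fusion-quality metrics for a source pair (A, B) and fused image F.

Seven scalar metrics, following the conventions of the fusion-metric
literature:

==========  =================================================================
AG          average gradient — mean RMS forward-difference magnitude; clarity.
EN          Shannon entropy of the 256-level histogram; information content.
JE          joint entropy — mean of H(F,A) and H(F,B); similarity to sources.
CE          cross entropy — mean KL divergence D(h_A‖h_F), D(h_B‖h_F); lower
            is better.
IQI         universal image quality index (Wang–Bovik), 8×8 sliding windows,
            averaged over F-vs-A and F-vs-B.
Q_E         edge-dependent quality: saliency-weighted windowed IQI on the
            intensity images times the same on Sobel edge-magnitude images.
Q_ABF       edge-information preservation (Petrović–Xydeas): sigmoid-mapped
            edge strength and orientation preservation from each source into
            F, weighted by source edge strength.
==========  =================================================================

Histogram metrics quantize each image independently by min–max rescaling to
0..L-1 and rounding (a constant image maps to level 0).  Windowed metrics use
8×8 windows with stride 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from ._filters import check_image

__all__ = [
    "MetricsReport",
    "average_gradient",
    "shannon_entropy",
    "joint_entropy",
    "cross_entropy",
    "iqi",
    "iqi_triple",
    "q_e",
    "q_abf",
    "evaluate_all",
    "psnr",
]

_EPS_CE = 1e-12  # floor on q-bins of the KL divergence
_WINDOW = 8      # sliding-window size of the IQI-family metrics

# sigmoid constants of the edge-preservation metric
_GAMMA_G, _KAPPA_G, _SIGMA_G = 0.9994, -15.0, 0.5
_GAMMA_A, _KAPPA_A, _SIGMA_A = 0.9879, -22.0, 0.8


@dataclass(frozen=True)
class MetricsReport:
    AG: float
    EN: float
    JE: float
    CE: float
    IQI: float
    Q_E: float
    Q_ABF: float

    def as_dict(self) -> dict[str, float]:
        return {
            "AG": self.AG, "EN": self.EN, "JE": self.JE, "CE": self.CE,
            "IQI": self.IQI, "Q_E": self.Q_E, "Q_ABF": self.Q_ABF,
        }


def average_gradient(C: np.ndarray) -> float:
    """Mean of sqrt((Δ_row² + Δ_col²)/2) over pixels with both forward diffs."""
    C = check_image(C, "C")
    if C.shape[0] < 2 or C.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got {C.shape}")
    dr = C[:-1, :-1] - C[1:, :-1]
    dc = C[:-1, :-1] - C[:-1, 1:]
    return float(np.mean(np.sqrt((dr**2 + dc**2) / 2.0)))


def quantize(C: np.ndarray, L: int = 256) -> np.ndarray:
    """Min–max rescale to 0..L-1 and round; constant images map to level 0."""
    C = check_image(C, "C")
    lo, hi = float(np.min(C)), float(np.max(C))
    if hi == lo:
        return np.zeros(C.shape, dtype=np.int64)
    return np.rint((C - lo) / (hi - lo) * (L - 1)).astype(np.int64)


def _hist(q: np.ndarray, L: int) -> np.ndarray:
    return np.bincount(q.ravel(), minlength=L) / q.size


def shannon_entropy(C: np.ndarray, L: int = 256) -> float:
    p = _hist(quantize(C, L), L)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def joint_entropy(F: np.ndarray, A: np.ndarray, L: int = 256) -> float:
    """H(F, A) of the joint gray-level histogram."""
    qF, qA = quantize(F, L), quantize(A, L)
    if qF.shape != qA.shape:
        raise ValueError(f"shape mismatch: {qF.shape} vs {qA.shape}")
    joint = np.bincount(qF.ravel() * L + qA.ravel(), minlength=L * L) / qF.size
    joint = joint[joint > 0]
    return float(-np.sum(joint * np.log2(joint)))


def joint_entropy_triple(A: np.ndarray, B: np.ndarray, F: np.ndarray, L: int = 256) -> float:
    return 0.5 * (joint_entropy(F, A, L) + joint_entropy(F, B, L))


def cross_entropy(A: np.ndarray, B: np.ndarray, F: np.ndarray, L: int = 256) -> float:
    """Mean relative entropy of the source histograms w.r.t. the fused one.

    ``D(p‖q) = Σ p_i log2(p_i / q_i)``; zero-mass p-bins contribute 0 and
    q-bins are floored at 1e-12 so the divergence stays finite.
    """
    qA, qB, qF = (quantize(x, L) for x in (A, B, F))
    if not (qA.shape == qB.shape == qF.shape):
        raise ValueError("A, B, F must share a shape")
    hF = np.maximum(_hist(qF, L), _EPS_CE)

    def kl(p: np.ndarray) -> float:
        nz = p > 0
        return float(np.sum(p[nz] * np.log2(p[nz] / hF[nz])))

    return 0.5 * (kl(_hist(qA, L)) + kl(_hist(qB, L)))


# ---------------------------------------------------------------------------
# windowed IQI family


def _window_stats(x: np.ndarray, y: np.ndarray):
    """Per-window means, variances and covariance (8x8, stride 1)."""
    wx = sliding_window_view(x, (_WINDOW, _WINDOW))
    wy = sliding_window_view(y, (_WINDOW, _WINDOW))
    mx = wx.mean(axis=(-2, -1))
    my = wy.mean(axis=(-2, -1))
    vx = wx.var(axis=(-2, -1))
    vy = wy.var(axis=(-2, -1))
    cxy = (wx * wy).mean(axis=(-2, -1)) - mx * my
    return mx, my, vx, vy, cxy


def _iqi_map(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-window Wang–Bovik index Q = 4 σ_xy x̄ȳ / ((σ_x²+σ_y²)(x̄²+ȳ²)).

    Degenerate windows follow the reference implementation: when only the
    variance term vanishes the luminance factor survives; identical constant
    windows score 1.
    """
    mx, my, vx, vy, cxy = _window_stats(x, y)
    lum_den = mx**2 + my**2
    con_den = vx + vy
    q = np.ones_like(mx)
    full = (lum_den > 0) & (con_den > 0)
    q[full] = 4.0 * cxy[full] * mx[full] * my[full] / (lum_den[full] * con_den[full])
    lum_only = (lum_den > 0) & (con_den == 0)
    q[lum_only] = 2.0 * mx[lum_only] * my[lum_only] / lum_den[lum_only]
    return q


def iqi(x: np.ndarray, y: np.ndarray) -> float:
    """Universal image quality index between two images, in [-1, 1]."""
    x, y = check_image(x, "x"), check_image(y, "y")
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape) < _WINDOW:
        raise ValueError(f"images must be at least {_WINDOW}x{_WINDOW}")
    return float(np.mean(_iqi_map(x, y)))


def iqi_triple(A: np.ndarray, B: np.ndarray, F: np.ndarray) -> float:
    return 0.5 * (iqi(A, F) + iqi(B, F))


def _sobel_magnitude(x: np.ndarray) -> np.ndarray:
    gx = ndimage.sobel(x, axis=1, mode="reflect")
    gy = ndimage.sobel(x, axis=0, mode="reflect")
    return np.sqrt(gx**2 + gy**2)


def _q_w(A: np.ndarray, B: np.ndarray, F: np.ndarray) -> float:
    """Saliency-weighted windowed IQI: Σ_w c(w)[λ(w)·IQI(A,F|w) + (1-λ)·IQI(B,F|w)].

    Saliency s(·|w) is the window variance; λ = s_A/(s_A+s_B) (0.5 where both
    vanish); c(w) ∝ max(s_A, s_B) (uniform if all windows are flat).
    """
    qA = _iqi_map(A, F)
    qB = _iqi_map(B, F)
    sA = sliding_window_view(A, (_WINDOW, _WINDOW)).var(axis=(-2, -1))
    sB = sliding_window_view(B, (_WINDOW, _WINDOW)).var(axis=(-2, -1))
    tot = sA + sB
    lam = np.full_like(sA, 0.5)
    np.divide(sA, tot, out=lam, where=tot > 0)
    Cw = np.maximum(sA, sB)
    csum = Cw.sum()
    c = Cw / csum if csum > 0 else np.full_like(Cw, 1.0 / Cw.size)
    return float(np.sum(c * (lam * qA + (1.0 - lam) * qB)))


def q_e(A: np.ndarray, B: np.ndarray, F: np.ndarray, alpha: float = 1.0) -> float:
    """Edge-dependent fusion quality Q_E = Q_W(A,B,F) · Q_W(A',B',F')^alpha.

    Primes are Sobel gradient-magnitude images; ``alpha`` weights the edge
    contribution (``alpha = 0`` reduces to the intensity term alone).
    """
    A, B, F = check_image(A, "A"), check_image(B, "B"), check_image(F, "F")
    if not (A.shape == B.shape == F.shape):
        raise ValueError("A, B, F must share a shape")
    qw = _q_w(A, B, F)
    if alpha == 0:
        return qw
    qw_edge = _q_w(_sobel_magnitude(A), _sobel_magnitude(B), _sobel_magnitude(F))
    return float(qw * np.sign(qw_edge) * np.abs(qw_edge) ** alpha)


def _edge_strength_orientation(x: np.ndarray):
    gx = ndimage.sobel(x, axis=1, mode="reflect")
    gy = ndimage.sobel(x, axis=0, mode="reflect")
    g = np.sqrt(gx**2 + gy**2)
    # orientation in (-pi/2, pi/2], the atan(gy/gx) convention
    a = np.arctan2(gy, gx)
    a = np.where(a > np.pi / 2, a - np.pi, a)
    a = np.where(a <= -np.pi / 2, a + np.pi, a)
    return g, a


def _preservation(gS: np.ndarray, aS: np.ndarray, gF: np.ndarray, aF: np.ndarray,
                  combine: str) -> np.ndarray:
    """Per-pixel edge preservation of source S in F."""
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(gS > gF, gF / gS, np.where(gF > 0, gS / gF, 0.0))
    G = np.where((gS == 0) & (gF == 0), 1.0, G)
    d = np.abs(aS - aF)
    d = np.minimum(d, np.pi - d)  # orientation is defined modulo pi
    Aval = 1.0 - d / (np.pi / 2.0)
    Qg = _GAMMA_G / (1.0 + np.exp(_KAPPA_G * (G - _SIGMA_G)))
    Qa = _GAMMA_A / (1.0 + np.exp(_KAPPA_A * (Aval - _SIGMA_A)))
    if combine == "product":
        return Qg * Qa
    elif combine == "sum":
        return Qg + Qa
    raise ValueError(f"combine must be 'product' or 'sum', got {combine!r}")


def q_abf(A: np.ndarray, B: np.ndarray, F: np.ndarray, combine: str = "product") -> float:
    """Edge-information preservation Q^AB/F in [0, 1] (``combine='product'``).

    Per pixel, the relative edge strength G and folded orientation difference
    are mapped through sigmoids to preservation scores Q_g, Q_α; the per-source
    scores (their product by default, the printed-sum variant via
    ``combine='sum'``) are averaged with the source edge strengths as weights.
    """
    A, B, F = check_image(A, "A"), check_image(B, "B"), check_image(F, "F")
    if not (A.shape == B.shape == F.shape):
        raise ValueError("A, B, F must share a shape")
    gA, aA = _edge_strength_orientation(A)
    gB, aB = _edge_strength_orientation(B)
    gF, aF = _edge_strength_orientation(F)
    QAF = _preservation(gA, aA, gF, aF, combine)
    QBF = _preservation(gB, aB, gF, aF, combine)
    wsum = np.sum(gA + gB)
    if wsum == 0:
        return 0.0
    return float(np.sum(QAF * gA + QBF * gB) / wsum)


def evaluate_all(A: np.ndarray, B: np.ndarray, F: np.ndarray, L: int = 256) -> MetricsReport:
    """All seven metrics for one (A, B, F) triple; deterministic."""
    return MetricsReport(
        AG=average_gradient(F),
        EN=shannon_entropy(F, L),
        JE=joint_entropy_triple(A, B, F, L),
        CE=cross_entropy(A, B, F, L),
        IQI=iqi_triple(A, B, F),
        Q_E=q_e(A, B, F),
        Q_ABF=q_abf(A, B, F),
    )


def psnr(reference: np.ndarray, test: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB (peak defaults to the reference range)."""
    reference = check_image(reference, "reference")
    test = check_image(test, "test")
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    if peak is None:
        peak = float(np.max(reference) - np.min(reference)) or 1.0
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)
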