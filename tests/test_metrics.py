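"""Every quality metric against a literal loop-based evaluation of its
formula, plus the exact identities the metrics must satisfy."""

import numpy as np
import pytest

from nsctfuse import evaluate_all
from nsctfuse import metrics as M


# ---------------------------------------------------------------------------
# brute-force oracles


def ag_oracle(C):
    m, n = C.shape
    acc = 0.0
    for i in range(m - 1):
        for j in range(n - 1):
            acc += np.sqrt(((C[i, j] - C[i + 1, j]) ** 2 + (C[i, j] - C[i, j + 1]) ** 2) / 2)
    return acc / ((m - 1) * (n - 1))


def entropy_oracle(C, L=256):
    q = M.quantize(C, L)
    counts = {}
    for v in q.ravel():
        counts[v] = counts.get(v, 0) + 1
    tot = q.size
    return -sum((c / tot) * np.log2(c / tot) for c in counts.values())


def joint_entropy_oracle(F, A, L=256):
    qF, qA = M.quantize(F, L), M.quantize(A, L)
    counts = {}
    for f, a in zip(qF.ravel(), qA.ravel()):
        counts[(f, a)] = counts.get((f, a), 0) + 1
    tot = qF.size
    return -sum((c / tot) * np.log2(c / tot) for c in counts.values())


def uqi_window_oracle(x, y):
    """Plain-formula Wang–Bovik index for a single full window."""
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cxy = ((x - mx) * (y - my)).mean()
    return (cxy / np.sqrt(vx * vy)) * (2 * mx * my / (mx**2 + my**2)) * (
        2 * np.sqrt(vx) * np.sqrt(vy) / (vx + vy)
    )


def iqi_oracle(x, y, w=8):
    vals = []
    for i in range(x.shape[0] - w + 1):
        for j in range(x.shape[1] - w + 1):
            vals.append(uqi_window_oracle(x[i : i + w, j : j + w], y[i : i + w, j : j + w]))
    return float(np.mean(vals))


def q_w_oracle(A, B, F, w=8):
    lam_q = []
    sal = []
    for i in range(A.shape[0] - w + 1):
        for j in range(A.shape[1] - w + 1):
            wa = A[i : i + w, j : j + w]
            wb = B[i : i + w, j : j + w]
            wf = F[i : i + w, j : j + w]
            sA, sB = wa.var(), wb.var()
            lam = sA / (sA + sB) if sA + sB > 0 else 0.5
            lam_q.append(lam * uqi_window_oracle(wa, wf) + (1 - lam) * uqi_window_oracle(wb, wf))
            sal.append(max(sA, sB))
    sal = np.asarray(sal)
    c = sal / sal.sum()
    return float(np.sum(c * np.asarray(lam_q)))


# ---------------------------------------------------------------------------
# average gradient


def test_ag_constant_and_small():
    assert M.average_gradient(np.full((5, 5), 2.0)) == 0.0
    # single valid forward-difference term
    assert np.isclose(M.average_gradient(np.array([[0.0, 1.0], [0.0, 1.0]])), np.sqrt(0.5))
    with pytest.raises(ValueError):
        M.average_gradient(np.ones((1, 5)))


def test_ag_homogeneity_and_oracle(rng):
    C = rng.standard_normal((32, 32))
    assert np.isclose(M.average_gradient(3.0 * C), 3.0 * M.average_gradient(C))
    assert np.isclose(M.average_gradient(C), ag_oracle(C), atol=1e-9)


# ---------------------------------------------------------------------------
# histogram metrics


def test_entropy_identities():
    assert M.shannon_entropy(np.full((8, 8), 0.3)) == 0.0
    uniform = np.arange(256, dtype=float).repeat(4).reshape(32, 32)
    assert np.isclose(M.shannon_entropy(uniform), 8.0)
    two = np.zeros((16, 16))
    two[:, 8:] = 255.0
    assert np.isclose(M.shannon_entropy(two), 1.0)


def test_entropy_matches_oracle(rng):
    C = rng.random((32, 32))
    assert np.isclose(M.shannon_entropy(C), entropy_oracle(C), atol=1e-12)


def test_joint_entropy_identities(rng):
    A = rng.random((32, 32))
    assert np.isclose(M.joint_entropy(A, A), M.shannon_entropy(A), atol=1e-12)
    assert np.isclose(M.joint_entropy(A, 1 - A), M.joint_entropy(1 - A, A), atol=1e-12)
    # independent 2-level halves -> 4 equiprobable cells -> 2 bits
    F = np.zeros((16, 16))
    F[:8, :] = 1.0
    G = np.zeros((16, 16))
    G[:, :8] = 1.0
    assert np.isclose(M.joint_entropy(F, G, L=2), 2.0)


def test_joint_entropy_matches_oracle(rng):
    F, A = rng.random((24, 24)), rng.random((24, 24))
    assert np.isclose(M.joint_entropy(F, A), joint_entropy_oracle(F, A), atol=1e-12)


def test_cross_entropy_identity_and_hand_value():
    A = np.random.default_rng(0).random((16, 16))
    assert abs(M.cross_entropy(A, A, A)) < 1e-12
    # 2-bin histograms: h_A = h_B = (.5,.5), h_F = (.25,.75)
    A2 = np.zeros((4, 4))
    A2[:2, :] = 1.0
    F2 = np.zeros((4, 4))
    F2[0, :] = 1.0
    ce = M.cross_entropy(A2, A2, F2, L=2)
    expect = 0.5 * np.log2(0.5 / 0.25) + 0.5 * np.log2(0.5 / 0.75)
    assert np.isclose(ce, expect)
    assert np.isclose(ce, 0.20752, atol=5e-6)


def test_cross_entropy_nonnegative(rng):
    for _ in range(5):
        A, B, F = rng.random((16, 16)), rng.random((16, 16)), rng.random((16, 16))
        assert M.cross_entropy(A, B, F) >= 0.0


# ---------------------------------------------------------------------------
# IQI family


def test_iqi_identities(rng):
    x = rng.random((16, 16))
    assert np.isclose(M.iqi(x, x), 1.0, atol=1e-9)
    assert np.isclose(M.iqi(x, x.copy()), 1.0, atol=1e-9)
    const = np.full((16, 16), 0.5)
    assert np.isclose(M.iqi(const, const.copy()), 1.0)


def test_iqi_matches_window_oracle_and_bounded(rng):
    x, y = rng.random((20, 20)), rng.random((20, 20))
    assert np.isclose(M.iqi(x, y), iqi_oracle(x, y), atol=1e-6)
    for _ in range(5):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert abs(M.iqi(a, b)) <= 1.0 + 1e-9


def test_q_e_identities(rng):
    A = rng.random((24, 24))
    assert np.isclose(M.q_e(A, A, A), 1.0, atol=1e-6)
    B, F = rng.random((24, 24)), rng.random((24, 24))
    # alpha = 0 collapses the edge term
    assert np.isclose(M.q_e(A, B, F, alpha=0.0), q_w_oracle(A, B, F), atol=1e-6)
    assert M.q_e(A, B, F) <= 1.0 + 1e-9


def test_q_e_matches_oracle(rng):
    A, B, F = (rng.random((20, 20)) for _ in range(3))
    from scipy import ndimage

    def edges(x):
        gx = ndimage.sobel(x, axis=1, mode="reflect")
        gy = ndimage.sobel(x, axis=0, mode="reflect")
        return np.sqrt(gx**2 + gy**2)

    expect = q_w_oracle(A, B, F) * q_w_oracle(edges(A), edges(B), edges(F))
    assert np.isclose(M.q_e(A, B, F), expect, atol=1e-6)


# ---------------------------------------------------------------------------
# edge-information preservation


def test_q_abf_perfect_preservation_ceiling(rng):
    """For F = A = B every pixel has G = 1 and zero orientation difference,
    so the score equals the sigmoid ceiling Qg(1)*Qa(1) ~= 0.9748."""
    A = rng.random((24, 24))
    ceiling = (0.9994 / (1 + np.exp(-15 * 0.5))) * (0.9879 / (1 + np.exp(-22 * 0.2)))
    assert np.isclose(M.q_abf(A, A, A), ceiling, atol=1e-9)
    assert M.q_abf(A, A, A) > 0.97


def test_q_abf_constant_fused_near_zero(rng):
    A = rng.random((16, 16))
    assert M.q_abf(A, A, np.full_like(A, 0.5)) < 0.05


def test_q_abf_bounded_and_sum_variant(rng):
    A, B, F = (rng.random((16, 16)) for _ in range(3))
    v = M.q_abf(A, B, F)
    assert 0.0 <= v <= 1.0
    # printed-sum variant is larger by construction and can exceed 1
    assert M.q_abf(A, B, F, combine="sum") > v


# ---------------------------------------------------------------------------
# aggregate report


def test_evaluate_all_self_triple(rng):
    A = rng.random((32, 32))
    rep = evaluate_all(A, A, A)
    assert np.isclose(rep.AG, M.average_gradient(A))
    assert np.isclose(rep.EN, M.shannon_entropy(A))
    assert np.isclose(rep.JE, M.shannon_entropy(A), atol=1e-12)
    assert abs(rep.CE) < 1e-12
    assert np.isclose(rep.IQI, 1.0, atol=1e-9)
    assert np.isclose(rep.Q_E, 1.0, atol=1e-6)
    assert rep.Q_ABF > 0.97


def test_report_ranges_and_determinism(rng):
    for _ in range(10):
        A, B, F = (rng.random((16, 16)) for _ in range(3))
        rep = evaluate_all(A, B, F)
        vals = rep.as_dict()
        assert all(np.isfinite(v) for v in vals.values())
        assert 0.0 <= rep.EN <= 8.0
        assert -1.0 - 1e-9 <= rep.IQI <= 1.0 + 1e-9
        assert 0.0 <= rep.Q_ABF <= 1.0
        assert rep.CE >= 0.0 and rep.AG >= 0.0
    A, B, F = (rng.random((16, 16)) for _ in range(3))
    assert evaluate_all(A, B, F) == evaluate_all(A, B, F)
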