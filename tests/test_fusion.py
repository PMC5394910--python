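"""Fusion rules and the end-to-end pipeline, including both baselines."""

import numpy as np
import pytest

from nsctfuse import (
    FusionConfig,
    baseline_dwt_max,
    baseline_nsct_max,
    fuse_pet_ct,
    psnr,
    region_energy,
    select_max_energy,
)
from nsctfuse.fusion import W1_LOW_TEMPLATE, W2_HIGH_TEMPLATE
from nsctfuse.nsct import DecompositionSpec
from nsctfuse.pcnn import PCNNParams


def small_config(**kw):
    """Shallow decomposition + short PCNN keeps unit tests fast."""
    kw.setdefault("spec", DecompositionSpec(2, (1, 2)))
    kw.setdefault("pcnn", PCNNParams(n_iter=60))
    return FusionConfig(**kw)


# ---------------------------------------------------------------------------
# region energy (Eq-level rules)


def test_region_energy_constant_image():
    """Uniform template w1 on a constant image c gives c^2 everywhere."""
    E = region_energy(np.full((10, 10), 3.0), W1_LOW_TEMPLATE)
    assert np.allclose(E, 9.0)


def test_region_energy_unit_impulse():
    C = np.zeros((9, 9))
    C[4, 4] = 1.0
    E = region_energy(C, W1_LOW_TEMPLATE)
    assert np.allclose(E[3:6, 3:6], 1.0 / 9.0)
    mask = np.ones_like(E, dtype=bool)
    mask[3:6, 3:6] = False
    assert np.all(E[mask] == 0.0)


def test_region_energy_matches_loop_oracle(rng):
    """Literal Eq evaluation with symmetric padding."""
    C = rng.standard_normal((12, 12))
    t = W2_HIGH_TEMPLATE

    def sym(i, n):
        if i < 0:
            return -i - 1
        if i >= n:
            return 2 * n - i - 1
        return i

    expect = np.zeros_like(C)
    for i in range(12):
        for j in range(12):
            acc = 0.0
            for a in (-1, 0, 1):
                for b in (-1, 0, 1):
                    acc += t[a + 1, b + 1] * C[sym(i + a, 12), sym(j + b, 12)] ** 2
            expect[i, j] = acc
    assert np.allclose(region_energy(C, t), expect, atol=1e-12)


def test_region_energy_nonnegative_and_template_check(rng):
    assert np.all(region_energy(rng.standard_normal((8, 8)), W1_LOW_TEMPLATE) >= 0)
    with pytest.raises(ValueError, match="3x3"):
        region_energy(np.zeros((8, 8)), np.ones((5, 5)))


def test_select_max_energy_branches(rng):
    D_A = rng.random((6, 6))
    D_B = rng.random((6, 6))
    fused, mask = select_max_energy(D_A, D_B, np.ones((6, 6)), np.zeros((6, 6)))
    assert np.array_equal(fused, D_A) and np.all(mask == 1)
    # exact tie goes to B (the printed <= branch)
    fused, mask = select_max_energy(D_A, D_B, np.ones((6, 6)), np.ones((6, 6)))
    assert np.array_equal(fused, D_B) and np.all(mask == 0)
    # identical coefficients: branch irrelevant
    fused, _ = select_max_energy(D_A, D_A, rng.random((6, 6)), rng.random((6, 6)))
    assert np.array_equal(fused, D_A)
    with pytest.raises(ValueError, match="shape"):
        select_max_energy(D_A, D_B, np.ones((3, 3)), np.zeros((6, 6)))


# ---------------------------------------------------------------------------
# pipelines


def test_self_fusion_identity(phantom_pair_64):
    """Fusing an image with itself must return it (PSNR > 40 dB) for the
    proposed method and both baselines."""
    A = phantom_pair_64.ct
    cfg = small_config()
    assert psnr(A, fuse_pet_ct(A, A, cfg).fused) > 40
    assert psnr(A, baseline_dwt_max(A, A)) > 40
    assert psnr(A, baseline_nsct_max(A, A, cfg)) > 40


def test_fusion_deterministic_and_source_sized(phantom_pair_64):
    cfg = small_config()
    a, b = phantom_pair_64.pet, phantom_pair_64.ct
    r1 = fuse_pet_ct(a, b, cfg)
    r2 = fuse_pet_ct(a, b, cfg)
    assert r1.fused.shape == a.shape
    assert np.array_equal(r1.fused, r2.fused)
    for m1, m2 in zip(r1.selection_masks, r2.selection_masks):
        assert np.array_equal(m1, m2)
        assert set(np.unique(m1)) <= {0.0, 1.0}


def test_selection_masks_reproducible_from_firing_maps(phantom_pair_64):
    """Re-evaluating region energies on the stored firing maps reproduces the
    recorded winner of every coefficient."""
    cfg = small_config()
    r = fuse_pet_ct(phantom_pair_64.pet, phantom_pair_64.ct, cfg, keep_intermediate=True)
    for i, (fA, fB, mask) in enumerate(
        zip(r.firing_maps_A, r.firing_maps_B, r.selection_masks)
    ):
        t = cfg.low_template if i == 0 else cfg.high_template
        E_A = region_energy(fA, t, cfg.boundary)
        E_B = region_energy(fB, t, cfg.boundary)
        assert np.array_equal((E_A > E_B).astype(float), mask)
        # and the fused band is exactly the recorded selection
        bA = r.decomposition_A.bands()[i]
        bB = r.decomposition_B.bands()[i]
        fused_band = r.fused_decomposition.bands()[i]
        assert np.array_equal(np.where(mask == 1, bA, bB), fused_band)


def test_intensity_shift_passes_through(phantom_pair_64):
    """Adding a constant to both inputs shifts the fused image by about that
    constant (the features are shift-invariant, so the masks do not move)."""
    cfg = small_config()
    a, b = phantom_pair_64.pet, phantom_pair_64.ct
    f0 = fuse_pet_ct(a, b, cfg).fused
    f1 = fuse_pet_ct(a + 0.25, b + 0.25, cfg).fused
    assert np.max(np.abs(f1 - (f0 + 0.25))) < 1e-2


def test_shape_mismatch_rejected(phantom_pair_64):
    a = phantom_pair_64.ct
    with pytest.raises(ValueError, match="differ"):
        fuse_pet_ct(a, a[:-2, :], small_config())
    with pytest.raises(ValueError, match="differ"):
        baseline_dwt_max(a, a[:, :-2])
    with pytest.raises(ValueError, match="differ"):
        baseline_nsct_max(a, a[:-2, :-2], small_config())


def test_dwt_baseline_constant_images():
    """For constant images the larger approximation coefficients win."""
    c1, c2 = np.full((32, 32), 0.8), np.full((32, 32), 0.3)
    out = baseline_dwt_max(c1, c2)
    assert np.allclose(out, 0.8, atol=1e-8)


def test_nsct_max_baseline_zero_second_input(phantom_pair_64):
    """Against an all-zero image, A's coefficients always win or tie equals,
    so the fusion returns A."""
    A = phantom_pair_64.ct
    out = baseline_nsct_max(A, np.zeros_like(A), small_config())
    assert psnr(A, out) > 40


def test_config_dict_round_trip():
    cfg = small_config(boundary="periodic", beta_source="subband")
    back = FusionConfig.from_dict(cfg.to_dict())
    assert back.spec == cfg.spec
    assert back.boundary == "periodic"
    assert back.beta_source == "subband"
    assert np.allclose(back.pcnn.link_kernel, cfg.pcnn.link_kernel)
    assert back.pcnn.n_iter == cfg.pcnn.n_iter


def test_config_validation():
    with pytest.raises(ValueError):
        FusionConfig(low_template=-np.ones((3, 3)))
    with pytest.raises(ValueError):
        FusionConfig(beta_source="nonsense")


def test_full_pipeline_shift_covariance_periodic(phantom_pair_64):
    """In periodic boundary mode the whole pipeline commutes with circular
    shifts: fusing shifted inputs equals shifting the fusion."""
    from nsctfuse import perturb

    cfg = small_config(boundary="periodic")
    a, b = phantom_pair_64.pet, phantom_pair_64.ct
    f0 = fuse_pet_ct(a, b, cfg).fused
    shift = (9, -6)
    f1 = fuse_pet_ct(perturb(a, shift), perturb(b, shift), cfg).fused
    assert np.max(np.abs(f1 - perturb(f0, shift))) < 1e-6
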