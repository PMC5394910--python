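"""Adaptive-PCNN fusion pipeline in the NSCT domain, plus two baselines.

The proposed pipeline for a co-registered pair (A, B):

1. NSCT-decompose both images.
2. Compute a clarity feature per band — NSML on the low-pass band, EOE on each
   directional high-pass band — and min–max normalize each feature map to
   [0, 1].
3. Run one PCNN per band, stimulated by the normalized feature map, with the
   per-pixel linking strength β equal to the region average gradient of that
   same feature map; collect firing-count maps.
4. Fuse each band coefficient-wise by the max-region-energy rule applied to
   the firing maps: the region energy is a template-weighted local sum of
   squared firing counts, with an all-ones template ``w1`` on the low band and
   a centre-dominant template ``w2`` on high bands; ties go to B.
5. Inverse NSCT of the fused bands.

Everything is deterministic; in periodic boundary mode every stage commutes
with circular shifts, so the whole pipeline is shift covariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nsct
from ._filters import check_image, conv2d
from .features import eoe_map, nsml_map
from .pcnn import PCNNParams, linking_strength_map, run_pcnn

__all__ = [
    "FusionConfig",
    "FusionResult",
    "W1_LOW_TEMPLATE",
    "W2_HIGH_TEMPLATE",
    "region_energy",
    "select_max_energy",
    "fuse_pet_ct",
    "baseline_dwt_max",
    "baseline_nsct_max",
]

#: energy template for the low-pass band: uniform 3x3 average of squares
W1_LOW_TEMPLATE = np.ones((3, 3)) / 9.0
#: energy template for high-pass bands: centre-dominant, normalized
W2_HIGH_TEMPLATE = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0


@dataclass
class FusionConfig:
    """Everything the pipeline needs: decomposition, features, PCNN, templates.

    ``beta_source`` selects the image whose region average gradient becomes the
    linking strength: ``'feature'`` (the PCNN stimulus map, the default) or
    ``'subband'`` (the raw coefficients).
    """

    spec: nsct.DecompositionSpec = field(default_factory=lambda: nsct.DEFAULT_SPEC)
    bank_name: str = "maxflat"
    pcnn: PCNNParams = field(default_factory=PCNNParams)
    low_template: np.ndarray = field(default_factory=lambda: W1_LOW_TEMPLATE.copy())
    high_template: np.ndarray = field(default_factory=lambda: W2_HIGH_TEMPLATE.copy())
    low_feature: str = "nsml"
    high_feature: str = "eoe"
    nsml_window: int = 3
    boundary: str = "symmetric"
    beta_source: str = "feature"

    def __post_init__(self):
        self.low_template = np.asarray(self.low_template, dtype=np.float64)
        self.high_template = np.asarray(self.high_template, dtype=np.float64)
        for name, t in (("low_template", self.low_template), ("high_template", self.high_template)):
            if np.any(t < 0) or t.sum() <= 0:
                raise ValueError(f"{name} must be non-negative with positive sum")
        if self.low_feature != "nsml" or self.high_feature != "eoe":
            raise ValueError("supported features: low='nsml', high='eoe'")
        if self.beta_source not in ("feature", "subband"):
            raise ValueError("beta_source must be 'feature' or 'subband'")

    # --- plain-dict round trip (used by the YAML config file of the CLI) ---

    def to_dict(self) -> dict:
        p = self.pcnn
        return {
            "levels": self.spec.levels,
            "directions_per_level": list(self.spec.directions_per_level),
            "bank_name": self.bank_name,
            "boundary": self.boundary,
            "low_feature": self.low_feature,
            "high_feature": self.high_feature,
            "nsml_window": self.nsml_window,
            "beta_source": self.beta_source,
            "low_template": self.low_template.tolist(),
            "high_template": self.high_template.tolist(),
            "pcnn": {
                "alpha_L": p.alpha_L,
                "alpha_theta": p.alpha_theta,
                "V_L": p.V_L,
                "V_theta": p.V_theta,
                "link_kernel": p.link_kernel.tolist(),
                "n_iter": p.n_iter,
                "theta_init": p.theta_init,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        d = dict(d)
        spec = nsct.DecompositionSpec(
            d.pop("levels", 3), tuple(d.pop("directions_per_level", (2, 2, 3)))
        )
        pcnn = PCNNParams(**d.pop("pcnn", {}))
        return cls(spec=spec, pcnn=pcnn, **d)


@dataclass
class FusionResult:
    """Fused image plus (optionally) everything needed to audit the decisions."""

    fused: np.ndarray
    selection_masks: list[np.ndarray]
    decomposition_A: nsct.SubbandDecomposition | None = None
    decomposition_B: nsct.SubbandDecomposition | None = None
    fused_decomposition: nsct.SubbandDecomposition | None = None
    firing_maps_A: list[np.ndarray] | None = None
    firing_maps_B: list[np.ndarray] | None = None


def region_energy(C: np.ndarray, template: np.ndarray, boundary: str = "symmetric") -> np.ndarray:
    """Template-weighted local sum of squared coefficients.

    ``E(i,j) = Σ_{a,b} template(a,b) · C(i+a, j+b)²``; applied to firing maps
    in the fusion rule but defined for any coefficient image.
    """
    C = check_image(C, "C")
    template = np.asarray(template, dtype=np.float64)
    if template.shape != (3, 3):
        raise ValueError(f"template must be 3x3, got shape {template.shape}")
    return conv2d(C**2, template, boundary)


def select_max_energy(
    D_A: np.ndarray, D_B: np.ndarray, E_A: np.ndarray, E_B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Max-region-energy coefficient selection.

    Takes ``D_A`` where ``E_A > E_B`` and ``D_B`` otherwise (ties go to B).
    Returns the fused band and a binary mask that is 1 where A won.
    """
    D_A, D_B = np.asarray(D_A, float), np.asarray(D_B, float)
    E_A, E_B = np.asarray(E_A, float), np.asarray(E_B, float)
    if not (D_A.shape == D_B.shape == E_A.shape == E_B.shape):
        raise ValueError(
            f"shape mismatch: D_A {D_A.shape}, D_B {D_B.shape}, "
            f"E_A {E_A.shape}, E_B {E_B.shape}"
        )
    mask = (E_A > E_B).astype(np.float64)
    return np.where(mask == 1.0, D_A, D_B), mask


def _minmax01_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jointly min–max normalize a pair of feature maps to [0, 1].

    The two maps of a band pair share one affine scale so that the PCNN
    stimuli stay comparable between sources (a weak feature map must not be
    stretched to the full range); a jointly constant pair normalizes to zeros.
    """
    lo = min(float(np.min(x)), float(np.min(y)))
    hi = max(float(np.max(x)), float(np.max(y)))
    if hi - lo == 0.0:
        return np.zeros_like(x), np.zeros_like(y)
    return (x - lo) / (hi - lo), (y - lo) / (hi - lo)


def _band_firing_maps(
    band_A: np.ndarray, band_B: np.ndarray, is_low: bool, config: FusionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Feature -> normalize -> adaptive PCNN, for one band of each source."""
    if is_low:
        feats = [nsml_map(b, config.nsml_window, config.boundary).values
                 for b in (band_A, band_B)]
    else:
        feats = [eoe_map(b, boundary=config.boundary).values
                 for b in (band_A, band_B)]
    stimuli = _minmax01_pair(*feats)
    beta_mode = "periodic" if config.boundary == "periodic" else "replicate"
    link_mode = "periodic" if config.boundary == "periodic" else "zero"
    out = []
    for S, band in zip(stimuli, (band_A, band_B)):
        beta_src = S if config.beta_source == "feature" else band
        beta = linking_strength_map(beta_src, boundary=beta_mode)
        out.append(run_pcnn(S, beta, config.pcnn, boundary=link_mode).astype(np.float64))
    return out[0], out[1]


def fuse_pet_ct(
    A: np.ndarray,
    B: np.ndarray,
    config: FusionConfig | None = None,
    keep_intermediate: bool = False,
) -> FusionResult:
    """Fuse a co-registered image pair with the adaptive-PCNN NSCT pipeline.

    ``A`` and ``B`` are same-shaped single-channel images (conventionally the
    CT-like and PET-like slices, rescaled to [0, 1] on load).  Returns the
    fused image and per-band selection masks; with ``keep_intermediate`` the
    decompositions and firing maps are retained for inspection.
    """
    config = FusionConfig() if config is None else config
    A = check_image(A, "A")
    B = check_image(B, "B")
    if A.shape != B.shape:
        raise ValueError(f"input shapes differ: A {A.shape} vs B {B.shape}")

    bank = nsct.build_filter_bank(config.bank_name)
    dec_A = nsct.nsct_forward(A, config.spec, bank, config.boundary)
    dec_B = nsct.nsct_forward(B, config.spec, bank, config.boundary)

    bands_A = dec_A.bands()
    bands_B = dec_B.bands()
    fused_bands: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    fires_A: list[np.ndarray] = []
    fires_B: list[np.ndarray] = []
    for i, (bA, bB) in enumerate(zip(bands_A, bands_B)):
        is_low = i == 0
        template = config.low_template if is_low else config.high_template
        fA, fB = _band_firing_maps(bA, bB, is_low, config)
        E_A = region_energy(fA, template, config.boundary)
        E_B = region_energy(fB, template, config.boundary)
        fused_band, mask = select_max_energy(bA, bB, E_A, E_B)
        fused_bands.append(fused_band)
        masks.append(mask)
        fires_A.append(fA)
        fires_B.append(fB)

    fused_dec = _rebuild(dec_A, fused_bands)
    fused = nsct.nsct_inverse(fused_dec, bank)
    return FusionResult(
        fused=fused,
        selection_masks=masks,
        decomposition_A=dec_A if keep_intermediate else None,
        decomposition_B=dec_B if keep_intermediate else None,
        fused_decomposition=fused_dec if keep_intermediate else None,
        firing_maps_A=fires_A if keep_intermediate else None,
        firing_maps_B=fires_B if keep_intermediate else None,
    )


def _rebuild(
    template_dec: nsct.SubbandDecomposition, flat_bands: list[np.ndarray]
) -> nsct.SubbandDecomposition:
    """Reshape a flat band list back into the low/high structure."""
    it = iter(flat_bands)
    low = next(it)
    high = [[next(it) for _ in level] for level in template_dec.high]
    return replace(template_dec, low=low, high=high)


# ---------------------------------------------------------------------------
# comparison baselines


def baseline_dwt_max(A: np.ndarray, B: np.ndarray, levels: int = 3) -> np.ndarray:
    """Discrete-wavelet fusion with per-coefficient max-absolute selection.

    Uses a biorthogonal 2.2 wavelet with symmetric extension; ties go to A.
    """
    import pywt

    A = check_image(A, "A")
    B = check_image(B, "B")
    if A.shape != B.shape:
        raise ValueError(f"input shapes differ: A {A.shape} vs B {B.shape}")
    wav = "bior2.2"
    cA = pywt.wavedec2(A, wav, mode="symmetric", level=levels)
    cB = pywt.wavedec2(B, wav, mode="symmetric", level=levels)
    fused = [np.where(np.abs(cA[0]) >= np.abs(cB[0]), cA[0], cB[0])]
    for tA, tB in zip(cA[1:], cB[1:]):
        fused.append(
            tuple(np.where(np.abs(a) >= np.abs(b), a, b) for a, b in zip(tA, tB))
        )
    out = pywt.waverec2(fused, wav, mode="symmetric")
    return out[: A.shape[0], : A.shape[1]]


def baseline_nsct_max(
    A: np.ndarray, B: np.ndarray, config: FusionConfig | None = None
) -> np.ndarray:
    """NSCT fusion with per-coefficient max-absolute selection in every band."""
    config = FusionConfig() if config is None else config
    A = check_image(A, "A")
    B = check_image(B, "B")
    if A.shape != B.shape:
        raise ValueError(f"input shapes differ: A {A.shape} vs B {B.shape}")
    bank = nsct.build_filter_bank(config.bank_name)
    dec_A = nsct.nsct_forward(A, config.spec, bank, config.boundary)
    dec_B = nsct.nsct_forward(B, config.spec, bank, config.boundary)
    fused_bands = [
        np.where(np.abs(a) >= np.abs(b), a, b)
        for a, b in zip(dec_A.bands(), dec_B.bands())
    ]
    return nsct.nsct_inverse(_rebuild(dec_A, fused_bands), bank)
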