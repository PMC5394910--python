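# Methods

This note documents the models implemented in `nsctfuse`, the conventions
chosen where the underlying method leaves room, and what the synthetic
phantom suite does and does not establish.

## Nonsubsampled contourlet transform

The transform is built additively:

* **Pyramid (scale axis).** At level *k* the approximation is convolved with
  the lowpass kernel dilated à-trous by 2^k (zeros inserted on the 2^k·I
  lattice); the high band is the residual `low_k − low_{k+1}`. The lowpass is
  the separable maximally-flat (binomial) filter from `[1,4,6,4,1]/16`
  (preset `maxflat`; `simple` uses `[1,2,1]/4`).
* **Directional filter bank.** A fan filter pair splits each high band along
  a binary tree. The fan lowpass is obtained by mapping a 1-D maximally-flat
  halfband filter (`[-1,0,9,16,9,0,-1]/32`) onto the diamond support with the
  McClellan substitution cos ω → (cos ω₁ + cos ω₂)/2 (Chebyshev recursion in
  the kernel algebra) and modulating rows by (−1)^i; the complement is
  δ − fan. Tree stage 2 upsamples the pair on the quincunx lattice
  Q = [[1,−1],[1,1]]; stages ≥ 3 use a parallelogram matrix — one of
  [[2,0],[±1,1]], [[1,±1],[0,2]], selected by the quadrant bits of the
  channel — dilated by 2^(s−3).

Because every two-channel analysis pair sums to a delta (and upsampling
preserves deltas), synthesis is the plain sum of subbands. Consequences that
the tests verify:

* perfect reconstruction is **exact** (machine epsilon) for every
  decomposition spec and either boundary mode;
* the transform is linear and, in periodic mode, exactly shift-covariant;
* every band is source-sized; a constant image has identically zero high
  bands.

Boundary handling is half-sample symmetric by default (appropriate for image
data); a periodic mode exists so that shift-covariance statements are exact
rather than approximate. The default spec is 3 levels with (2, 2, 3)
directional splits — enough directional resolution for 128–512 px slices
while keeping 17 bands.

## Simplified PCNN

Per iteration n = 1..n_iter, with stimulus S ∈ [0,1] and per-pixel linking
strength β:

    F[n] = S
    L[n] = e^{−α_L} L[n−1] + V_L (W ⊛ Y[n−1])
    U[n] = F[n] (1 + β L[n])
    θ'   = e^{−α_θ} θ[n−1]
    Y[n] = [U[n] ≥ θ']
    θ[n] = θ' + V_θ Y[n]

The feeding channel has no decay or memory (F = S) — the simplified model is
implemented exactly as stated, although classic PCNN formulations add a
feeding leak. Initial conditions, which the model statement leaves open, are
L[0] = 0, Y[0] = 0, θ[0] = θ_init. The threshold is compared *after* its
decay and recharged after the comparison; this ordering gives the closed-form
single-neuron behaviour the tests pin down (first firing at the smallest n
with e^{−α_θ n} θ₀ ≤ S, e.g. S = 0.5 → n = 4 and S = 0.9 → n = 1 at
α_θ = 0.2, θ₀ = 1).

Defaults (all exposed in `PCNNParams` / `FusionConfig`):

| parameter | default | why |
|---|---|---|
| α_L | 0.06931 | linking decays with a ~10-iteration half-life |
| α_θ | 0.2 | threshold reaches weak stimuli (~0.02) within n_iter |
| V_L | 1.0 | linking on the same scale as the stimulus |
| V_θ | 20 | one firing silences a neuron for ≈ ln(V_θ/U)/α_θ ≈ 15–30 steps |
| W | inverse Euclidean distance, zero centre | isotropic 8-neighbour linking |
| n_iter | 200 | every neuron with S > 0 fires several times; counts span ~0–16 |
| θ_init | 1 | stimuli are normalized to [0,1], so no neuron fires spuriously at n=1 |

These are conventional simplified-PCNN settings; the firing map is defined
as the cumulative firing count over all iterations, a stable ordinal signal
(earlier/more firing ⇔ stronger stimulus).

The adaptive linking strength is the region average gradient
β(i,j) = (1/9) Σ_{3×3} sqrt[(g₁+g₂)/2] of the PCNN stimulus map (forward
squared differences; replicated edges). Computing β from the feature map
rather than the raw subband follows from the rationale that β should grow
with the external input; `beta_source="subband"` switches to the raw
coefficients. The linking convolution zero-pads (border neurons have fewer
neighbours) except in periodic mode.

## Fusion pipeline conventions

* **Joint normalization.** The NSML/EOE maps of a band *pair* are normalized
  with a single min–max affine scale. Normalizing each map separately would
  stretch the weaker source's features to [0,1] and make the subsequent
  firing-count comparison meaningless; with a shared scale the comparison
  "whose clarity is locally larger" is preserved. A jointly constant pair
  normalizes to zeros (no neuron fires).
* **Source order and ties.** The first argument is conventionally the
  PET-like image, the second the CT-like one; the max-region-energy rule
  awards exact energy ties to the second source, so ambiguous (typically
  flat) regions default to the anatomical image.
* **Templates.** The low band uses w1 = (1/9)·ones(3,3). The high-band
  template is not fixed by the method statement beyond "strengthen the
  centre"; the default w2 = (1/16)[[1,2,1],[2,4,2],[1,2,1]] is the smallest
  normalized centre-dominant template.
* Each band runs its own PCNN; no state is shared across bands.
* The pipeline is deterministic, and in periodic mode every stage (transform,
  features, β, linking, region energy, selection) commutes with circular
  shifts, so the fused image of shifted inputs equals the shifted fused image
  exactly.

## Quality metrics

Conventions, chosen to match the metric literature and documented because
they change the numbers:

* Histogram metrics (EN, JE, CE) quantize each image independently by
  min–max rescaling to 0..255 and rounding (constant image → level 0).
  JE of a triple is (H(F,A) + H(F,B))/2; CE floors the fused histogram at
  1e−12 so zero bins cannot produce infinities (p-bins with zero mass
  contribute 0).
* IQI uses 8×8 sliding windows with stride 1, population variances, and the
  reference degenerate-window handling (luminance factor survives when only
  the variances vanish; identical constant windows score 1).
* Q_E weights windowed IQI by saliency (window variance): λ = s_A/(s_A+s_B)
  (0.5 where both vanish), c(w) ∝ max(s_A, s_B) (uniform if all windows are
  flat), and multiplies by the same functional on Sobel gradient-magnitude
  images raised to α (default 1).
* Q^AB/F uses Sobel edge strength and atan-convention orientation folded
  modulo π, sigmoid constants (Γ_g, κ_g, σ_g) = (0.9994, −15, 0.5) and
  (Γ_α, κ_α, σ_α) = (0.9879, −22, 0.8), per-pixel preservation
  Q_g·Q_α (the product keeps the metric in [0,1]; the additive variant is
  available via `combine="sum"`), weighted by source edge strength. The
  perfect-preservation ceiling Q_g(1)·Q_α(1) ≈ 0.9748 is what F = A = B
  scores — the metric cannot reach 1.
* Both-gradients-zero pixels count as perfectly preserved (G = 1); an
  entirely edge-free triple scores 0 by convention.

## Synthetic phantoms

`make_phantom_pair(seed, size=128, n_hotspots=3)` draws everything from a
PCG64 generator seeded by the user seed, so pairs are bit-identical across
platforms and sessions.

The CT-like image is piecewise-constant anatomy — elliptical soft-tissue
body (0.35), bright bone rim and spine (~0.9–0.95), 3–5 organs at densities
0.1–0.8 — with three measurement effects of real CT layered on: sub-pixel
partial-volume blur (Gaussian σ = 0.7 px), a smooth beam-hardening-like
intensity shading (±0.05 across the body), and quantum-mottle speckle
(σ = 0.02). The PET-like image is rendered at quarter resolution and
bilinearly upsampled (the native-resolution gap of PET), with three uptake
layers composed by maximum so values never clip: a heterogeneous smooth
background field (0.28 ± 0.10 — muscle/blood-pool/marrow uptake is mottled
and overlaps the CT soft-tissue gray), one or two organ-scale bright regions
co-located with CT organs (liver/brain-like physiological uptake), and
compact Gaussian hotspots (amplitude 0.62–0.9, σ = 3.2–7.2 px full-res)
whose true centres, widths and amplitudes are recorded in `truth`.

What the phantoms do *not* model: modality noise beyond CT speckle
(in particular PET reconstruction noise), residual misregistration,
anatomical realism, attenuation or partial-volume quantitative effects, and
whole-body fields of view (the body fills most of the frame). Passing tests
on phantoms therefore establish correctness and determinism of the pipeline
and the *direction* of effects that depend on intensity structure, but not
clinical performance.

One measured consequence, reported by `scripts/acceptance.py` and asserted
in the acceptance suite: on this noiseless, perfectly co-registered suite the
adaptive-PCNN framework beats per-coefficient max-absolute NSCT selection on
mean entropy (EN, 20/20 seeds) and cross entropy, but not on joint entropy or
Q_E — pointwise max-absolute selection unions the locally strongest
coefficients of both sources, which is near-optimal for exactly what JE and
Q_E measure when there is no noise for it to amplify and no misregistration
for it to double-expose. The regime where the adaptive framework's regional
coherence pays off (noisy, imperfectly aligned clinical data) is outside
what the phantom suite models.

## Numerical choices

* All filtering is zero-phase convolution with odd-sized kernels via
  `scipy.ndimage`; `reflect` (half-sample symmetric) padding by default,
  `wrap` in periodic mode.
* Exact-tie behaviour: coefficient selection ties → second source; the
  firing condition uses ≥; argmax-style decisions inherit numpy's
  first-index convention.
* β is clamped at 0 against the uniform filter's rounding residue
  (~−1e−17).
* Degenerate inputs: constant images produce zero features, zero β, zero
  high bands, entropy 0, and IQI 1 against themselves; fully documented in
  the per-function docstrings.
* Fused images are clipped to [0,1] when written or scored, mirroring
  bit-depth-limited storage of fusion results.

## Known limitations

* Directional selectivity of the additive filter bank is softer than that of
  critically-sampled contourlet designs; selectivity beyond 8 directions per
  level (d = 4) degrades although reconstruction stays exact.
* The simplified PCNN's firing counts quantize clarity coarsely (~17 levels
  at the defaults), so region-energy comparisons can tie over flat areas.
* Registration is assumed: mismatched shapes are rejected rather than
  resampled, and nothing corrects residual spatial displacement.
* 2-D slices only; volumes must be fused slice-wise.
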