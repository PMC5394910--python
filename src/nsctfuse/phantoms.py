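"""Seeded synthetic CT-like / PET-like phantom pairs.

The generator emulates the salient statistics of co-registered whole-body
slices without any claim of anatomical realism:

* CT-like image — piecewise-constant anatomy: an elliptical body of soft
  tissue, a bright bone rim and spine, a handful of internal organs
  (ellipses/rectangles) at distinct densities.  Three measurement effects of
  real CT are layered on top: sub-pixel partial-volume blur of the boundaries
  (Gaussian, sigma 0.7 px), a smooth low-order intensity shading across the
  body (beam-hardening-like, ±0.05), and quantum-mottle speckle (sigma 0.02),
  so the histogram is dense rather than a handful of spikes.
* PET-like image — smooth tracer uptake rendered at quarter resolution and
  bilinearly upsampled, mimicking the native low resolution of PET and its
  interpolation to the CT grid.  Uptake has three layers, composed by maximum
  so values never clip: a heterogeneous physiological background inside the
  body (a smooth random field around 0.28 — muscle/blood-pool/marrow uptake
  is mottled in real scans, and its overlap with the CT soft-tissue gray is
  what makes naive bright-wins fusion wash out contrast), one or two
  organ-scale bright regions co-located with CT organs (liver/brain-like
  uptake), and a few compact Gaussian hotspots ("high metabolic areas").

CT edges and PET hotspots are placed independently, so the modalities carry
complementary content for fusion.  All randomness comes from numpy's PCG64
generator seeded with the user seed, so a given seed reproduces the pair
bit-for-bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PhantomPair", "make_phantom_pair", "perturb"]


@dataclass
class PhantomPair:
    ct: np.ndarray
    pet: np.ndarray
    truth: dict
    seed: int


def _ellipse_mask(shape, center, semi, angle=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(np.float64)
    y = yy - center[0]
    x = xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / semi[1]) ** 2 + (v / semi[0]) ** 2 <= 1.0


def make_phantom_pair(seed: int, size: int = 128, n_hotspots: int = 3) -> PhantomPair:
    """Generate one co-registered CT-like / PET-like pair, both in [0, 1].

    Deterministic given ``seed``; hotspots always fall inside the body mask
    and their true centres (full-resolution coordinates) are recorded in
    ``truth['hotspots']``.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    if n_hotspots < 1:
        raise ValueError("n_hotspots must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (size, size)
    center = (size / 2.0, size / 2.0)

    # ---- CT: piecewise-constant anatomy with sharp boundaries -------------
    body_semi = (size * rng.uniform(0.40, 0.44), size * rng.uniform(0.34, 0.38))
    body = _ellipse_mask(shape, center, body_semi)
    inner = _ellipse_mask(shape, center, (body_semi[0] - size * 0.03, body_semi[1] - size * 0.03))
    ct = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int64)
    ct[body] = 0.35
    labels[body] = 1
    rim = body & ~inner
    ct[rim] = 0.95          # cortical-bone-like bright rim
    labels[rim] = 2
    spine = _ellipse_mask(
        shape, (center[0] + body_semi[0] * 0.55, center[1]), (size * 0.05, size * 0.045)
    )
    ct[spine & body] = 0.9
    labels[spine & body] = 3

    n_organs = int(rng.integers(3, 6))
    organs = []
    for k in range(n_organs):
        oc = (
            center[0] + rng.uniform(-0.45, 0.45) * body_semi[0],
            center[1] + rng.uniform(-0.45, 0.45) * body_semi[1],
        )
        value = rng.uniform(0.1, 0.8)
        semi = (size * rng.uniform(0.05, 0.12), size * rng.uniform(0.05, 0.12))
        angle = rng.uniform(0, np.pi)
        if rng.random() < 0.5:
            m = _ellipse_mask(shape, oc, semi, angle)
        else:
            yy, xx = np.mgrid[: size, : size]
            m = (np.abs(yy - oc[0]) <= semi[0]) & (np.abs(xx - oc[1]) <= semi[1])
        m &= inner
        ct[m] = value
        labels[m] = 4 + k
        organs.append({"center": oc, "semi": semi, "angle": angle, "ct_value": value})
    # measurement effects: partial-volume edge blur, beam-hardening-like
    # shading, quantum-mottle speckle (body interior only)
    ct = ndimage.gaussian_filter(ct, 0.7)
    yy, xx = np.mgrid[: size, : size].astype(np.float64)
    shade = (
        rng.uniform(-0.05, 0.05) * (yy - center[0]) / size
        + rng.uniform(-0.05, 0.05) * (xx - center[1]) / size
        + rng.uniform(-0.04, 0.04) * ((yy - center[0]) * (xx - center[1])) / size**2
    )
    ct[inner] += shade[inner]
    ct[inner] += rng.normal(0.0, 0.02, size=int(inner.sum()))
    ct = np.clip(ct, 0.0, 1.0)

    # ---- PET: smooth uptake rendered at quarter resolution ----------------
    q = size // 4
    body_q = _ellipse_mask((q, q), (center[0] / 4, center[1] / 4),
                           (body_semi[0] / 4, body_semi[1] / 4))
    # heterogeneous physiological background: smooth random field ~N(0.28, 0.1)
    field = ndimage.gaussian_filter(rng.standard_normal((q, q)), 3.0)
    sd = field.std()
    field = field / sd if sd > 0 else field
    pet_q = np.where(body_q, np.clip(0.28 + 0.10 * field, 0.05, 0.55), 0.0)
    # organ-scale physiological uptake: the first one or two anatomy shapes
    # also show as large smooth bright regions (liver/brain-like); uptake
    # layers are composed by maximum so the image never needs clipping
    n_metabolic = min(2, len(organs))
    for org in organs[:n_metabolic]:
        mq = _ellipse_mask(
            (q, q),
            (org["center"][0] / 4, org["center"][1] / 4),
            (org["semi"][0] / 4, org["semi"][1] / 4),
            org["angle"],
        )
        level = rng.uniform(0.45, 0.6)
        uptake = ndimage.gaussian_filter(mq.astype(np.float64), 1.2) * level
        pet_q = np.maximum(pet_q, np.where(body_q, uptake, 0.0))
        org["pet_uptake"] = level
    # candidate centres on the quarter grid, inside the eroded body, far apart
    core = ndimage.binary_erosion(body_q, iterations=max(1, q // 10))
    cand = np.argwhere(core)
    order = rng.permutation(len(cand))
    chosen: list[np.ndarray] = []
    min_dist = max(2.0, 0.18 * q)
    # relax the spacing deterministically rather than fail on a crowded body
    while min_dist >= 1.0:
        chosen = []
        for idx in order:
            p = cand[idx]
            if all(np.hypot(*(p - c)) >= min_dist for c in chosen):
                chosen.append(p)
            if len(chosen) == n_hotspots:
                break
        if len(chosen) == n_hotspots:
            break
        min_dist *= 0.8
    if len(chosen) < n_hotspots:
        raise ValueError(f"could not place {n_hotspots} hotspots in a {size}px body")

    yy, xx = np.mgrid[: q, : q].astype(np.float64)
    hotspots = []
    for p in chosen:
        sigma_q = rng.uniform(0.8, 1.8)
        amp = rng.uniform(0.62, 0.9)
        blob = amp * np.exp(-(((yy - p[0]) ** 2 + (xx - p[1]) ** 2) / (2 * sigma_q**2)))
        pet_q = np.maximum(pet_q, blob)
        # output pixel j maps to input coordinate (j + 0.5)/4 - 0.5, so the
        # full-resolution centre of an integer quarter-grid peak is 4q + 1.5
        hotspots.append(
            {
                "center": (4.0 * p[0] + 1.5, 4.0 * p[1] + 1.5),
                "sigma": 4.0 * sigma_q,
                "amplitude": float(amp),
            }
        )
    pet = ndimage.zoom(pet_q, 4, order=1, mode="nearest", grid_mode=True)
    pet = np.clip(pet, 0.0, 1.0)
    assert pet.shape == shape

    truth = {"hotspots": hotspots, "organs": organs, "labels": labels, "body_mask": body}
    return PhantomPair(ct=ct, pet=pet, truth=truth, seed=int(seed))


def perturb(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Circularly shift an image by (dy, dx); exact inverse is the negated shift."""
    return np.roll(np.asarray(image), shift, axis=(0, 1))
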