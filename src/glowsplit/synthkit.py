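"""Synthetic spectra, scenes, and dilution test strips with ground truth.

Everything the pipeline consumes can be generated here so that every stage
is testable without measured data: a narrowband near-UV illuminant, a
blue-peaked fluorophore emission with a small sub-400 nm reflection peak,
smooth skin reflectance curves that differ mostly in overall scale, and
rendered images (forward model of the mixture equation) whose ground-truth
coefficient maps are retained for round-trip checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import TristimulusImage
from .spectra import DEFAULT_BASIS, ProjectionBasis, Spectrum

__all__ = [
    "SceneTruth",
    "StripSpec",
    "synth_illuminant",
    "synth_fluor_emission",
    "synth_skin_reflectances",
    "synth_scene",
    "render_scene",
    "render_test_strip",
    "strip_response_model",
]

_SYNTH_GRID = np.arange(360.0, 831.0, 1.0)


@dataclass
class SceneTruth:
    """Ground-truth coefficient maps behind a rendered scene."""

    beta_w_map: np.ndarray
    beta_s_map: np.ndarray
    beta_f_map: np.ndarray
    clip_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = np.asarray(self.beta_w_map).shape
        for name in ("beta_w_map", "beta_s_map", "beta_f_map"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError("coefficient maps must share a shape")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be >= 0")
            setattr(self, name, arr)
        if self.clip_mask is None:
            self.clip_mask = np.zeros(shape, dtype=bool)

    def betas(self) -> np.ndarray:
        return np.stack([self.beta_w_map, self.beta_s_map, self.beta_f_map], axis=-1)


@dataclass(frozen=True)
class StripSpec:
    """Layout of a geometric-dilution test strip.

    Swatch k carries concentration ``top_concentration * dilution_factor**k``;
    the default factor 15/65 (~23.07% per step) mirrors serial dilution with
    a fixed pipetting ratio.  ``exposure_scale`` multiplies all rendered
    radiances, emulating exposure duration.
    """

    n_swatches: int = 12
    dilution_factor: float = 15.0 / 65.0
    top_concentration: float = 1.0
    swatch_size: tuple[int, int] = (16, 16)
    gap: int = 4
    exposure_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution_factor < 1.0):
            raise ValueError("dilution_factor must lie in (0, 1)")
        if self.n_swatches < 1:
            raise ValueError("need at least one swatch")

    @property
    def concentrations(self) -> np.ndarray:
        k = np.arange(self.n_swatches)
        return self.top_concentration * self.dilution_factor**k


# ---------------------------------------------------------------------------
# Spectra


def _gaussian(wl: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sd) ** 2)


def synth_illuminant() -> Spectrum:
    """Narrowband near-UV LED illuminant: Gaussian peak at 400 nm, sd 3 nm.

    Essentially all power falls in the 395-405 nm band of the physical lamp.
    """
    return Spectrum(_SYNTH_GRID, _gaussian(_SYNTH_GRID, 400.0, 3.0), "illuminant")


def synth_fluor_emission() -> Spectrum:
    """Blue fluorophore emission with a small sub-400 nm reflection peak.

    Dominant Gaussian at 450 nm (sd 25 nm) plus a 15%-amplitude peak at
    398 nm (sd 4 nm): the latter is reflected excitation light, not
    fluorescence, but it is part of the visible signature and is kept.
    """
    vals = _gaussian(_SYNTH_GRID, 450.0, 25.0) + 0.15 * _gaussian(_SYNTH_GRID, 398.0, 4.0)
    return Spectrum(_SYNTH_GRID, vals, "emission")


def synth_skin_reflectances(n: int, seed: int = 0) -> list[Spectrum]:
    """Smooth synthetic skin reflectance curves for n subjects.

    Each curve rises toward the red end (melanin/hemoglobin absorption is
    strongest at short wavelengths), with a per-subject overall scale drawn
    from [0.3, 0.9] and mild smooth shape perturbations.  Deterministic
    under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    wl = _SYNTH_GRID
    x = (wl - wl[0]) / (wl[-1] - wl[0])
    curves = []
    base = 0.25 + 0.75 / (1.0 + np.exp(-(wl - 570.0) / 60.0))
    for _ in range(n):
        scale = rng.uniform(0.3, 0.9)
        # low-order smooth perturbation, a few percent of the base shape
        amp = rng.normal(0.0, 0.02, size=3)
        perturb = sum(a * np.sin((k + 1) * np.pi * x) for k, a in enumerate(amp))
        vals = np.clip(scale * base * (1.0 + perturb), 0.0, 1.0)
        curves.append(Spectrum(wl, vals, "reflectance"))
    return curves


# ---------------------------------------------------------------------------
# Scenes


def synth_scene(
    shape: tuple[int, int] = (96, 96),
    seed: int = 0,
    n_blobs: int = 4,
    white_level: float = 0.5,
    skin_level: float = 1.0,
) -> SceneTruth:
    """Hand-scene fixture: white card strip, skin region, fluorescence blobs.

    The left quarter of the frame is a white-lit card (beta_w only), the rest
    is skin (beta_s only) carrying Gaussian fluorescence blobs whose
    centers, widths and amplitudes are drawn reproducibly from ``seed``.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    beta_w = np.zeros(shape)
    beta_s = np.zeros(shape)
    beta_f = np.zeros(shape)
    card = w // 4
    beta_w[:, :card] = white_level
    beta_s[:, card:] = skin_level
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        r0 = rng.uniform(0.1 * h, 0.9 * h)
        c0 = rng.uniform(card + 0.1 * (w - card), w - 0.1 * (w - card))
        sd = rng.uniform(1.5, max(2.5, 0.06 * min(h, w)))
        amp = rng.uniform(0.5, 3.0)
        beta_f += amp * np.exp(-0.5 * (((rr - r0) / sd) ** 2 + ((cc - c0) / sd) ** 2))
    beta_f[:, :card] = 0.0
    return SceneTruth(beta_w, beta_s, beta_f)


def render_scene(
    truth: SceneTruth,
    basis: ProjectionBasis = DEFAULT_BASIS,
    noise_sd: float = 0.0,
    clip_level: float = np.inf,
    seed: int = 0,
) -> TristimulusImage:
    """Forward model: c = basis @ beta + noise, then per-channel clipping.

    Channels exceeding ``clip_level`` are clipped and the affected pixels
    recorded both in ``truth.clip_mask`` and the image's ``saturated`` flags.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    xyz = np.einsum("ij,hwj->hwi", basis.matrix, truth.betas())
    if noise_sd > 0:
        xyz = xyz + noise_sd * rng.standard_normal(xyz.shape)
    clipped = np.any(xyz > clip_level, axis=-1)
    xyz = np.minimum(xyz, clip_level)
    truth.clip_mask = clipped
    return TristimulusImage(xyz, saturated=clipped)


# ---------------------------------------------------------------------------
# Test strips


def strip_response_model(concentration, floor: float = 0.01, gain: float = 1.0):
    """Fluorescent power as a function of tracer concentration.

    Proportional above a detection floor (default 1% concentration) and zero
    below it: thinly spread tracer contributes no measurable emission, and
    the response only rises above roughly 1% concentration.
    """
    c = np.asarray(concentration, dtype=float)
    return gain * np.maximum(c - floor, 0.0)


def render_test_strip(
    spec: StripSpec,
    basis: ProjectionBasis = DEFAULT_BASIS,
    response_model=strip_response_model,
    noise_sd: float = 0.0,
    clip_level: float = np.inf,
    seed: int = 0,
):
    """Render a dilution strip of fluorescent swatches on a dark background.

    Returns ``(image, boxes, concentrations, truth)``: swatch k (left to
    right, decreasing concentration) gets ground-truth fluorescent power
    ``exposure_scale * response_model(concentration_k)``.
    """
    sh, sw = spec.swatch_size
    g = spec.gap
    h = sh + 2 * g
    w = spec.n_swatches * (sw + g) + g
    beta_f = np.zeros((h, w))
    boxes = []
    conc = spec.concentrations
    for k in range(spec.n_swatches):
        c0 = g + k * (sw + g)
        box = (g, g + sh, c0, c0 + sw)
        boxes.append(box)
        beta_f[box[0] : box[1], box[2] : box[3]] = response_model(conc[k])
    truth = SceneTruth(np.zeros_like(beta_f), np.zeros_like(beta_f), spec.exposure_scale * beta_f)
    img = render_scene(truth, basis, noise_sd=noise_sd, clip_level=clip_level, seed=seed)
    return img, boxes, conc, truth
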