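"""Synthetic layered phantoms and multiplicative speckle corruption.

OCT B-scans of the retina show smoothly bowed, roughly horizontal bands of
distinct backscatter intensity.  The phantom generator emulates exactly
that geometry — piecewise-constant layers with optional sinusoidal bowing
— so the despeckling filter, its kernel ablation, and the quality metrics
are all testable without external image data.

Speckle is modelled as fully developed multiplicative noise: the clean
intensity is multiplied pixelwise by an i.i.d. unit-mean gamma field with
shape ``L`` ("number of looks"), variance ``1/L`` — the standard model for
coherent-imaging speckle.  An additive-Gaussian corruption is included for
sanity checks only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "SpeckleParams",
    "make_phantom",
    "default_phantom_spec",
    "add_speckle",
    "add_gaussian",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Description of a layered clean phantom.

    ``layer_boundaries`` are fractional row positions in (0, 1), strictly
    increasing; ``layer_intensities`` (0-255 scale) has one more entry than
    there are boundaries.  ``curvature`` is the amplitude in pixels of a
    sinusoidal vertical bowing applied to every boundary; ``seed`` fixes
    the bowing phase so the phantom is deterministic given its spec.
    """

    height: int = 256
    width: int = 256
    layer_boundaries: tuple[float, ...] = (0.18, 0.30, 0.45, 0.62, 0.78, 0.88)
    layer_intensities: tuple[float, ...] = (30.0, 180.0, 90.0, 150.0, 70.0, 120.0, 40.0)
    curvature: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        b = np.asarray(self.layer_boundaries, dtype=float)
        if b.size and (np.any(b <= 0) or np.any(b >= 1) or np.any(np.diff(b) <= 0)):
            raise ValueError("layer boundaries must be strictly increasing in (0, 1)")
        if len(self.layer_intensities) != b.size + 1:
            raise ValueError(
                f"need {b.size + 1} layer intensities for {b.size} boundaries, "
                f"got {len(self.layer_intensities)}"
            )


@dataclass(frozen=True)
class SpeckleParams:
    """Multiplicative gamma speckle: shape ``looks``, unit mean, variance 1/looks."""

    looks: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.looks > 0:
            raise ValueError(f"number of looks must be positive, got {self.looks}")


def default_phantom_spec(height: int = 256, width: int = 256, seed: int = 0) -> PhantomSpec:
    """The standard retinal-like test phantom at the requested size."""
    return PhantomSpec(height=height, width=width, seed=seed)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the layered clean image described by ``spec``.

    Boundaries are bowed by ``curvature * sin(2*pi*col/width + phase)``;
    the phase is drawn once from the spec's seed, so identical specs give
    identical images.
    """
    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    cols = np.arange(spec.width)
    bow = spec.curvature * np.sin(2.0 * np.pi * cols / max(spec.width, 1) + phase)
    rows = np.arange(spec.height)[:, None]
    img = np.full((spec.height, spec.width), spec.layer_intensities[0], dtype=float)
    for frac, intensity in zip(spec.layer_boundaries, spec.layer_intensities[1:]):
        boundary = frac * spec.height + bow  # per-column boundary row
        img = np.where(rows >= boundary[None, :], intensity, img)
    return img


def add_speckle(clean: np.ndarray, params: SpeckleParams) -> np.ndarray:
    """Corrupt ``clean`` with multiplicative gamma speckle.

    noisy = clean * G, with G i.i.d. Gamma(shape=looks, scale=1/looks):
    E[G] = 1, Var[G] = 1/looks, so E[noisy] = clean and the per-pixel
    SNR (mean/std) is sqrt(looks) independent of intensity.
    """
    clean = np.asarray(clean, dtype=float)
    if np.any(clean < 0):
        raise ValueError("clean intensities must be non-negative")
    rng = np.random.default_rng(params.seed)
    gain = rng.gamma(shape=params.looks, scale=1.0 / params.looks, size=clean.shape)
    return clean * gain


def add_gaussian(clean: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Additive white Gaussian corruption (sanity-test noise model only)."""
    clean = np.asarray(clean, dtype=float)
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, sigma, size=clean.shape)
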