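"""Fractional compact finite difference scheme (FCFDS) building blocks.

The scheme combines three shifted Gruenwald-Letnikov difference operators
(shifts 0, -1, -2) with weights fixed by moment (consistency) conditions,
which lifts the plain shifted Gruenwald difference from first- to
third-order accuracy for the Riemann-Liouville derivative of order
``alpha`` in (0, 1) while keeping a short one-sided stencil.

The same construction, collapsed to a single convolution stencil
``c1..cN``, yields the directional fractional masks applied along the
horizontal and vertical image axes to produce per-pixel fractional
gradient fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "RhoWeights",
    "DirectionalMasks",
    "FcfdsSeries",
    "GradientFields",
    "grunwald_coeffs",
    "rho_weights",
    "mask_coeffs",
    "directional_masks",
    "fcfds_1d",
    "shifted_grunwald_1d",
    "fractional_gradients",
]

#: Shifts of the three Gruenwald operators entering the compact scheme.
SHIFTS = (0, -1, -2)


def _check_alpha(alpha: float) -> float:
    """Validate a fractional order.

    Orders in (0, 1) are the scheme's domain; alpha = 1 is admitted as the
    classical first-derivative limit (useful for exactness checks).
    """
    alpha = float(alpha)
    if not np.isfinite(alpha) or not 0.0 < alpha <= 1.0:
        raise ValueError(f"fractional order must lie in (0, 1], got {alpha!r}")
    return alpha


def grunwald_coeffs(alpha: float, K: int) -> np.ndarray:
    """Gruenwald-Letnikov coefficients g_0..g_K for order ``alpha``.

    g_k = (-1)^k C(alpha, k) = Gamma(k - alpha) / (Gamma(-alpha) Gamma(k + 1)),
    computed by the stable recurrence ``g_k = (1 - (alpha + 1)/k) g_{k-1}``
    with ``g_0 = 1``.

    Parameters
    ----------
    alpha : float
        Fractional order in (0, 1].
    K : int
        Largest index; the returned array has ``K + 1`` entries.
    """
    alpha = _check_alpha(alpha)
    K = int(K)
    if K < 0:
        raise ValueError(f"K must be non-negative, got {K}")
    g = np.empty(K + 1)
    g[0] = 1.0
    for k in range(1, K + 1):
        g[k] = (1.0 - (alpha + 1.0) / k) * g[k - 1]
    return g


class RhoWeights(NamedTuple):
    """Weights of the three shifted Gruenwald operators (shifts 0, -1, -2)."""

    rho1: float
    rho2: float
    rho3: float


def rho_weights(alpha: float) -> RhoWeights:
    """Compact-scheme weights for shifts (0, -1, -2) at order ``alpha``.

    The triple is the unique solution of the three moment conditions

        sum rho_r           = 1
        sum rho_r * r       = alpha / 2
        sum rho_r * r**2    = alpha**2 / 4 - alpha / 12

    over shifts r in {0, -1, -2}, which cancel the first- and second-order
    truncation terms of the shifted Gruenwald expansion and leave an
    O(spacing^3) error.
    """
    alpha = _check_alpha(alpha)
    rho1 = (24.0 + 17.0 * alpha + 3.0 * alpha**2) / 24.0
    rho3 = (5.0 * alpha + 3.0 * alpha**2) / 24.0
    rho2 = -(11.0 * alpha + 3.0 * alpha**2) / 12.0
    return RhoWeights(rho1, rho2, rho3)


def mask_coeffs(alpha: float, N: int) -> np.ndarray:
    """Stencil coefficients c_1..c_N of the directional fractional mask.

    c_k = g_{k-1} rho1 + g_{k-2} rho2 + g_{k-3} rho3  (g_j = 0 for j < 0),

    i.e. the single convolution stencil equivalent to the weighted sum of
    the three shifted Gruenwald operators, truncated to N taps.  N must be
    even so that the (N+1) x (N+1) two-dimensional mask built from the
    stencil has a well-defined centre row/column.

    At ``alpha = 1, N = 4`` the stencil reduces to the classical
    third-order backward difference (11/6, -3, 3/2, -1/3) for f'.
    """
    alpha = _check_alpha(alpha)
    N = int(N)
    if N < 2 or N % 2 != 0:
        raise ValueError(f"mask length N must be a positive even integer >= 2, got {N}")
    g = grunwald_coeffs(alpha, N - 1)
    rho = rho_weights(alpha)
    c = rho.rho1 * g[:N]
    c[1:] += rho.rho2 * g[: N - 1]
    c[2:] += rho.rho3 * g[: N - 2]
    return c


@dataclass(frozen=True)
class DirectionalMasks:
    """The fractional mask stencil and the axes it acts along.

    The identical coefficient sequence ``c`` is applied along both image
    axes: the target pixel carries ``c[0]`` and ``c[1:]`` weight the
    preceding pixels in the positive axis direction (one-sided mask).
    """

    alpha: float
    c: np.ndarray

    @property
    def N(self) -> int:
        return self.c.size


def directional_masks(alpha: float, N: int = 4) -> DirectionalMasks:
    """Build the horizontal/vertical fractional differential masks."""
    return DirectionalMasks(alpha=_check_alpha(alpha), c=mask_coeffs(alpha, N))


class FcfdsSeries(NamedTuple):
    """1-D fractional derivative estimate plus boundary metadata.

    ``n_boundary`` flags how many leading entries were computed with the
    unavailable shifted sums dropped (the compact combination needs two
    samples of history before it is complete).
    """

    values: np.ndarray
    n_boundary: int


def fcfds_1d(samples: np.ndarray, alpha: float, spacing: float) -> FcfdsSeries:
    """Apply the compact fractional difference operator to a 1-D signal.

    Entry n (n >= 2) is

        spacing**(-alpha) * [ rho1 * sum_{k=0..n}   g_k f_{n-k}
                            + rho2 * sum_{k=0..n-1} g_k f_{n-k-1}
                            + rho3 * sum_{k=0..n-2} g_k f_{n-k-2} ]

    which approximates the Riemann-Liouville derivative of order alpha
    (lower terminal at the first sample) to O(spacing^3).  Entries n < 2
    drop the shifted sums that would reach before the first sample and are
    flagged via ``n_boundary``.
    """
    f = np.asarray(samples, dtype=float)
    if f.ndim != 1 or f.size < 3:
        raise ValueError("need a 1-D signal with at least 3 samples")
    spacing = float(spacing)
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    alpha = _check_alpha(alpha)
    n = f.size
    g = grunwald_coeffs(alpha, n - 1)
    rho = rho_weights(alpha)
    # Each shifted sum is a full (truncated) convolution of g with f.
    conv = np.convolve(g, f)[:n]  # conv[m] = sum_{k=0..m} g_k f_{m-k}
    out = rho.rho1 * conv
    out[1:] += rho.rho2 * conv[:-1]
    out[2:] += rho.rho3 * conv[:-2]
    out *= spacing ** (-alpha)
    return FcfdsSeries(values=out, n_boundary=2)


def shifted_grunwald_1d(samples: np.ndarray, alpha: float, spacing: float) -> np.ndarray:
    """Plain (unshifted, gamma = 0) Gruenwald difference of a 1-D signal.

    First-order accurate; kept as the comparison baseline for the compact
    scheme's convergence-order experiments.
    """
    f = np.asarray(samples, dtype=float)
    if f.ndim != 1 or f.size < 1:
        raise ValueError("need a non-empty 1-D signal")
    spacing = float(spacing)
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    alpha = _check_alpha(alpha)
    g = grunwald_coeffs(alpha, f.size - 1)
    return np.convolve(g, f)[: f.size] * spacing ** (-alpha)


class GradientFields(NamedTuple):
    """Per-pixel fractional gradients along the two image axes."""

    dx: np.ndarray  # horizontal (along columns)
    dy: np.ndarray  # vertical (along rows)


def fractional_gradients(image: np.ndarray, masks: DirectionalMasks) -> GradientFields:
    """Fractional gradient fields of an image (unit pixel spacing).

    dx[r, c] = sum_k c_k * image[r, c - (k - 1)]   (horizontal)
    dy[r, c] = sum_k c_k * image[r - (k - 1), c]   (vertical)

    Out-of-range samples are supplied by replicate padding, so the output
    fields match the input shape.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    N = masks.N
    if min(img.shape) < N:
        raise ValueError(
            f"image of shape {img.shape} is smaller than the {N}-tap mask"
        )
    # correlate1d offsets run j - origin; padding the reversed stencil with
    # trailing zeros centres c1 on the target pixel with c2..cN behind it.
    w = np.concatenate([masks.c[::-1], np.zeros(N - 1)])
    dx = ndimage.correlate1d(img, w, axis=1, mode="nearest")
    dy = ndimage.correlate1d(img, w, axis=0, mode="nearest")
    return GradientFields(dx=dx, dy=dy)
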