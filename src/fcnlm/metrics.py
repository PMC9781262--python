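"""Full-reference image quality metrics: PSNR and SSIM.

PSNR = 10 log10(peak^2 / MSE) in dB; SSIM is the mean local structural
similarity with the standard 11x11 Gaussian window (sigma = 1.5) and
stabilizers (0.01 peak)^2 and (0.03 peak)^2.  Both default to the 8-bit
peak of 255 but accept any positive intensity scale.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricsReport", "psnr", "ssim", "report"]


class MetricsReport(NamedTuple):
    psnr: float
    ssim: float
    peak: float


def _check_pair(reference: np.ndarray, estimate: np.ndarray, peak: float):
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {est.shape}")
    if not peak > 0:
        raise ValueError(f"peak must be positive, got {peak}")
    return ref, est


def psnr(reference: np.ndarray, estimate: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    ref, est = _check_pair(reference, estimate, peak)
    mse = np.mean((ref - est) ** 2)
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(reference: np.ndarray, estimate: np.ndarray, peak: float = 255.0) -> float:
    """Mean structural similarity index in [-1, 1]."""
    ref, est = _check_pair(reference, estimate, peak)
    if min(ref.shape) < 11:
        raise ValueError("SSIM needs images of at least 11x11 pixels")
    return float(
        structural_similarity(
            ref,
            est,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=peak,
            K1=0.01,
            K2=0.03,
        )
    )


def report(reference: np.ndarray, estimate: np.ndarray, peak: float = 255.0) -> MetricsReport:
    """Both metrics at once."""
    return MetricsReport(
        psnr=psnr(reference, estimate, peak),
        ssim=ssim(reference, estimate, peak),
        peak=float(peak),
    )
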