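"""Estimation of the Poisson-Gaussian noise parameters (a, b) from a single
noisy image.

The image is smoothed and segmented into intensity level-sets; within each
segment the local signal level is the mean of the smoothed image and the
local noise standard deviation is a robust (median-absolute-deviation) scale
estimate of unit-gain high-pass detail coefficients.  The affine variance
law ``sigma^2 = a*yhat + b`` is then fitted to the per-segment pairs by
variance-weighted least squares with weights iteratively refreshed from the
current fit (Fisher scoring for the Gaussian sampling model of a sample
standard deviation, whose variance is approximately ``(a*yhat+b)/(2n)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .grid import ImageGrid, NoiseParams
from .noise import approximate_signal

__all__ = [
    "LocalStatPair",
    "EstimationResult",
    "segment_by_level",
    "local_stats",
    "fit_affine_variance",
    "estimate_noise_params",
]

# 2x2 unit-gain high-pass: for i.i.d. unit-variance input the response has
# unit variance (4 taps of magnitude 1/2)
_DETAIL_KERNEL = 0.5 * np.array([[1.0, -1.0], [-1.0, 1.0]])
_MAD_TO_SD = 1.4826022185056018


@dataclass(frozen=True)
class LocalStatPair:
    """Local signal level and noise scale of one intensity segment."""

    mean_hat: float
    std_hat: float
    count: int


@dataclass
class EstimationResult:
    params: NoiseParams
    pairs: list
    converged: bool
    n_iterations: int
    residual_rms: float

    def to_dict(self) -> dict:
        return {
            "a": self.params.a,
            "b": self.params.b,
            "scale": self.params.scale,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "residual_rms": self.residual_rms,
            "n_segments": len(self.pairs),
        }


def segment_by_level(noisy: ImageGrid, n_bins: int = 24, min_segment: int = 256):
    """Partition pixels into intensity level-sets of the smoothed image.

    Quantile binning of the low-pass estimate into ``n_bins`` levels;
    segments smaller than ``min_segment`` pixels are discarded (their local
    statistics would be dominated by sampling error).  Returns a list of
    boolean masks.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sm = approximate_signal(noisy).values
    qs = np.quantile(sm, np.linspace(0.0, 1.0, n_bins + 1))
    qs = np.unique(qs)
    if len(qs) < 2:
        raise ValueError("image has no intensity structure to segment")
    lab = np.clip(np.searchsorted(qs, sm, side="right") - 1, 0, len(qs) - 2)
    masks = [lab == i for i in range(len(qs) - 1)]
    masks = [m for m in masks if m.sum() >= min_segment]
    if len(masks) < 2:
        raise ValueError(
            "fewer than two usable intensity segments; the image is too "
            "small or too uniform for noise estimation"
        )
    return masks


def local_stats(noisy: ImageGrid, segments) -> list:
    """Per-segment (mean, noise-sd, count) statistics.

    The mean is taken from the smoothed image; the noise standard deviation
    is MAD x 1.4826 of the high-pass detail coefficients over the segment
    (robust to residual edges inside a segment), corrected so that white
    noise of unit variance gives a unit estimate.
    """
    sm = approximate_signal(noisy).values
    detail = convolve(noisy.values, _DETAIL_KERNEL, mode="wrap")
    out = []
    for mask in segments:
        d = detail[mask]
        sd = _MAD_TO_SD * float(np.median(np.abs(d - np.median(d))))
        out.append(LocalStatPair(float(sm[mask].mean()), sd, int(mask.sum())))
    return out


def fit_affine_variance(
    pairs, scale: str = "unit", fix_b: float | None = None, max_iter: int = 50
) -> EstimationResult:
    """Fit ``sigma^2 = a*yhat + b`` to local statistics pairs.

    Iteratively reweighted least squares on the squared scale: the sample
    variance of segment i has approximate sampling variance
    ``2*(a*yhat_i+b)^2 / n_i``, so weights ``n_i / (a*yhat_i+b)^2`` are
    refreshed from the current estimate until the fit is stationary.  Exact
    data (pairs lying on one affine law) are reproduced exactly.  Estimates
    are constrained to a, b >= 0; ``fix_b`` pins the Gaussian variance (e.g.
    at 0 for a Poisson-only fit).
    """
    y = np.array([p.mean_hat for p in pairs], dtype=float)
    s2 = np.array([p.std_hat**2 for p in pairs], dtype=float)
    n = np.array([p.count for p in pairs], dtype=float)
    if len(pairs) < 2 or np.ptp(y) == 0:
        raise ValueError("need at least two segments with distinct levels")

    def wls(wts, fix_b):
        if fix_b is None:
            X = np.stack([y, np.ones_like(y)], axis=1)
            coef, *_ = np.linalg.lstsq(X * np.sqrt(wts)[:, None],
                                       s2 * np.sqrt(wts), rcond=None)
            a, b = coef
            if a < 0:
                a = 0.0
                b = float(np.sum(wts * s2) / np.sum(wts))
            if b < 0:
                b = 0.0
                a = float(np.sum(wts * y * s2) / np.maximum(np.sum(wts * y * y), 1e-300))
                a = max(a, 0.0)
            return float(a), float(b)
        b = float(fix_b)
        a = float(np.sum(wts * y * (s2 - b)) / np.maximum(np.sum(wts * y * y), 1e-300))
        return max(a, 0.0), b

    a, b = wls(n, fix_b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pred = np.maximum(a * y + b, 1e-12 * max(s2.max(), 1e-30))
        wts = n / (2.0 * pred**2)
        a_new, b_new = wls(wts, fix_b)
        if abs(a_new - a) <= 1e-10 * max(abs(a), 1e-30) and abs(
            b_new - b
        ) <= 1e-10 * max(abs(b), 1e-30):
            a, b = a_new, b_new
            converged = True
            break
        a, b = a_new, b_new
    rms = float(np.sqrt(np.mean((s2 - (a * y + b)) ** 2)))
    if a == 0 and b == 0:
        b = float(np.sum(n * s2) / np.sum(n))
    return EstimationResult(NoiseParams(a, b, scale), list(pairs), converged, it, rms)


def estimate_noise_params(
    noisy: ImageGrid,
    n_bins: int = 24,
    min_segment: int = 256,
    fix_b: float | None = None,
) -> EstimationResult:
    """One-call (a, b) estimation: segment, measure, fit."""
    segments = segment_by_level(noisy, n_bins=n_bins, min_segment=min_segment)
    pairs = local_stats(noisy, segments)
    return fit_affine_variance(pairs, scale=noisy.range_convention, fix_b=fix_b)
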