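"""Mixed Poisson-Gaussian noise model.

The observation model is ``z = y + eta_p(y) + eta_g`` where the scaled signal
``chi*(y + eta_p)`` is Poisson with mean ``chi*y`` (photon shot noise,
``chi = 1/a``) and ``eta_g ~ N(0, b)`` is signal-independent read noise.  The
total noise variance is affine in the signal, ``sigma^2(y) = a*y + b``.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

from .grid import ImageGrid, NoiseParams

__all__ = [
    "add_pg_noise",
    "variance_map",
    "approximate_signal",
    "psnr",
    "binomial_kernel",
    "clipped_moments",
]


def add_pg_noise(
    image: ImageGrid,
    params: NoiseParams,
    seed: int | np.random.Generator = 0,
    clip: bool = False,
) -> ImageGrid:
    """Draw one Poisson-Gaussian noise realization of a clean image.

    For ``a > 0`` each pixel is sampled as ``a * Poisson(y/a)`` (so its mean
    is ``y`` and its variance ``a*y``); for ``a = 0`` the Poisson part is the
    identity.  Independent ``N(0, b)`` read noise is added on top.  With
    ``clip=True`` the result is clamped to the image's declared range, which
    matters for strongly noisy low-count data where a sensor or file format
    cannot represent negative or over-range values.
    """
    image.assert_same_scale(params)
    y = image.values
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.a > 0:
        if np.any(y < 0):
            raise ValueError("Poisson noise (a > 0) requires non-negative intensities")
        lam = y / params.a
        big = lam > 1e12   # sampler limit; normal approximation is exact here
        lam_safe = np.where(big, 0.0, lam)
        counts = rng.poisson(lam_safe).astype(np.float64)
        if np.any(big):
            counts = np.where(big, lam + np.sqrt(lam) * rng.standard_normal(y.shape), counts)
        z = params.a * counts
    else:
        z = y.astype(np.float64, copy=True)
    if params.b > 0:
        z = z + rng.normal(0.0, np.sqrt(params.b), size=y.shape)
    out = image.with_values(z)
    return out.clipped() if clip else out


def variance_map(reference: ImageGrid, params: NoiseParams) -> np.ndarray:
    """Per-pixel noise variance ``a*y + b`` evaluated on a reference image.

    The reference stands in for the clean signal; in practice it is the
    low-pass estimate from :func:`approximate_signal`.
    """
    reference.assert_same_scale(params)
    return params.a * reference.values + params.b


def binomial_kernel(size: int = 5) -> np.ndarray:
    """Separable binomial (approximate Gaussian) smoothing kernel."""
    from math import comb

    w = np.array([comb(size - 1, k) for k in range(size)], dtype=np.float64)
    w /= w.sum()
    return np.outer(w, w)


def approximate_signal(noisy: ImageGrid, size: int = 5) -> ImageGrid:
    """Low-pass estimate of the clean signal used to evaluate the variance law.

    A binomial smoothing (periodic boundary, matching the transform's
    extension mode) clamped to non-negative values.  Constants are preserved
    exactly.
    """
    sm = convolve(noisy.values, binomial_kernel(size), mode="wrap")
    return noisy.with_values(np.maximum(sm, 0.0))


def clipped_moments(params: NoiseParams, n_grid: int = 513):
    """Mean and variance of the range-clipped observation as functions of y.

    At low photon counts the recorded value ``clip(z, 0, max)`` is a biased
    estimate of the signal: its conditional mean ``m(y) = E[clip(z) | y]``
    bends away from the identity near the range limits and its variance
    ``v(y)`` falls below the affine law ``a*y + b``.  Both are computed
    exactly on a grid of signal levels by summing the Poisson mixture
    components (each a clipped Gaussian with closed-form moments).

    Returns ``(y_grid, m, v)``; for noiseless parameters this degenerates to
    the identity with zero variance.
    """
    from scipy.stats import norm, poisson

    top = 1.0 if params.scale == "unit" else 255.0
    y = np.linspace(0.0, top, n_grid)
    sd = np.sqrt(params.b) if params.b > 0 else 0.0

    def clip_gauss_moments(mu):
        """E and E[X^2] of clip(N(mu, b), 0, top) (vectorized over mu)."""
        if sd == 0.0:
            c = np.clip(mu, 0.0, top)
            return c, c * c
        al = (0.0 - mu) / sd
        be = (top - mu) / sd
        Fa, Fb = norm.cdf(al), norm.cdf(be)
        fa, fb = norm.pdf(al), norm.pdf(be)
        pmid = np.maximum(Fb - Fa, 0.0)
        # truncated-normal mean/second moment on (0, top)
        with np.errstate(invalid="ignore", divide="ignore"):
            tm = mu + sd * (fa - fb) / np.where(pmid > 0, pmid, 1.0)
            tv = sd * sd * (
                1.0
                + (al * fa - be * fb) / np.where(pmid > 0, pmid, 1.0)
                - ((fa - fb) / np.where(pmid > 0, pmid, 1.0)) ** 2
            )
        tm = np.where(pmid > 0, tm, 0.0)
        tv = np.where(pmid > 0, np.maximum(tv, 0.0), 0.0)
        e1 = (1.0 - Fb) * top + pmid * tm
        e2 = (1.0 - Fb) * top * top + pmid * (tv + tm * tm)
        return e1, e2

    if params.a == 0:
        m, e2 = clip_gauss_moments(y)
        v = np.maximum(e2 - m * m, 0.0)
        return y, m, v

    m = np.zeros_like(y)
    e2 = np.zeros_like(y)
    lam = y / params.a
    kmax = int(np.ceil(lam.max() + 12.0 * np.sqrt(lam.max() + 1.0))) + 1
    for k in range(kmax + 1):
        pk = poisson.pmf(k, lam)
        if not np.any(pk > 1e-16):
            if k > lam.max():
                break
            continue
        e1k, e2k = clip_gauss_moments(np.full_like(y, params.a * k))
        m += pk * e1k
        e2 += pk * e2k
    v = np.maximum(e2 - m * m, 0.0)
    return y, m, v


def psnr(reference: ImageGrid, test: ImageGrid, peak: str = "range") -> float:
    """Peak signal-to-noise ratio ``10*log10(Imax^2 / MSE)`` in decibels.

    ``peak="range"`` (default) takes ``Imax`` from the declared range maximum
    of the reference (255 on the byte scale, 1 on the unit scale);
    ``peak="empirical"`` uses the reference's actual maximum.  Identical
    images give ``inf``.
    """
    reference.assert_same_scale(test)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    mse = float(np.mean((reference.values - test.values) ** 2))
    if mse == 0.0:
        return np.inf
    imax = reference.range_max if peak == "range" else float(reference.values.max())
    return 10.0 * np.log10(imax * imax / mse)
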