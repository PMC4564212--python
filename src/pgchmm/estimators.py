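"""scikit-learn-style estimators wrapping the denoising pipeline.

These follow the fit/transform convention on single-channel 2-D images:
``PoissonGaussianNoiseEstimator`` fits the affine noise-variance law of an
image, ``ContourletHMTDenoiser`` fits the noise law (or accepts known
parameters) and transforms images by the full cycle-spun contourlet-HMT
pipeline.  Both expose ``get_params``/``set_params`` and fitted attributes
with trailing underscores, so they compose with scikit-learn model
selection on parameter grids.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .estimation import estimate_noise_params
from .grid import ImageGrid, NoiseParams
from .hmt import EMConfig
from .pipeline import DenoiseConfig, denoise

__all__ = ["PoissonGaussianNoiseEstimator", "ContourletHMTDenoiser"]


def _as_grid(X, range_convention):
    if isinstance(X, ImageGrid):
        return X
    return ImageGrid(np.asarray(X, dtype=np.float64), range_convention)


class PoissonGaussianNoiseEstimator(BaseEstimator):
    """Estimate the noise law ``sigma^2(y) = a*y + b`` from one noisy image.

    Parameters
    ----------
    range_convention : {"unit", "byte"}
        Intensity scale the image (and hence ``a_`` and ``b_``) refer to.
    n_bins, min_segment : int
        Level-set segmentation granularity and minimum usable segment size.
    fix_b : float or None
        Pin the Gaussian variance (0 for a Poisson-only fit).

    Attributes
    ----------
    a_, b_ : float
        Fitted Poisson slope and Gaussian variance.
    result_ : EstimationResult
        Full diagnostics (segment statistics, convergence).
    """

    def __init__(self, range_convention="unit", n_bins=24, min_segment=256, fix_b=None):
        self.range_convention = range_convention
        self.n_bins = n_bins
        self.min_segment = min_segment
        self.fix_b = fix_b

    def fit(self, X, y=None):
        img = _as_grid(X, self.range_convention)
        self.result_ = estimate_noise_params(
            img, n_bins=self.n_bins, min_segment=self.min_segment, fix_b=self.fix_b
        )
        self.a_ = self.result_.params.a
        self.b_ = self.result_.params.b
        return self

    @property
    def params_(self) -> NoiseParams:
        return self.result_.params


class ContourletHMTDenoiser(TransformerMixin, BaseEstimator):
    """Mixed Poisson-Gaussian denoiser (contourlet hidden Markov tree).

    ``fit`` establishes the noise parameters — estimating them from the
    image unless both ``a`` and ``b`` are given — and ``transform`` runs
    the cycle-spun contourlet-HMT pipeline with Wiener post-filtering.

    Parameters mirror :class:`~pgchmm.pipeline.DenoiseConfig`; see there
    for semantics.  Attributes ``a_``/``b_`` hold the noise law used and
    ``report_`` the run report of the last transform.
    """

    def __init__(
        self,
        a=None,
        b=None,
        range_convention="unit",
        levels=5,
        dirs_per_scale=4,
        lp_filter="9/7",
        k1=4,
        k2=4,
        stride=1,
        em_max_iter=50,
        em_tol=1e-5,
        em_per_shift=True,
        mapping_mode="same_direction",
        wiener=True,
        wiener_window=3,
        wiener_alpha=0.25,
        clip=True,
        seed=0,
    ):
        self.a = a
        self.b = b
        self.range_convention = range_convention
        self.levels = levels
        self.dirs_per_scale = dirs_per_scale
        self.lp_filter = lp_filter
        self.k1 = k1
        self.k2 = k2
        self.stride = stride
        self.em_max_iter = em_max_iter
        self.em_tol = em_tol
        self.em_per_shift = em_per_shift
        self.mapping_mode = mapping_mode
        self.wiener = wiener
        self.wiener_window = wiener_window
        self.wiener_alpha = wiener_alpha
        self.clip = clip
        self.seed = seed

    def _config(self) -> DenoiseConfig:
        return DenoiseConfig(
            levels=self.levels,
            dirs_per_scale=self.dirs_per_scale,
            lp_filter=self.lp_filter,
            k1=self.k1,
            k2=self.k2,
            stride=self.stride,
            em=EMConfig(max_iter=self.em_max_iter, tol=self.em_tol),
            em_per_shift=self.em_per_shift,
            mapping_mode=self.mapping_mode,
            wiener=self.wiener,
            wiener_window=self.wiener_window,
            wiener_alpha=self.wiener_alpha,
            clip=self.clip,
            seed=self.seed,
        )

    def fit(self, X, y=None):
        img = _as_grid(X, self.range_convention)
        if self.a is not None and self.b is not None:
            self.a_, self.b_ = float(self.a), float(self.b)
        else:
            est = estimate_noise_params(img)
            self.a_, self.b_ = est.params.a, est.params.b
            self.estimation_ = est
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "a_"):
            raise RuntimeError("call fit before transform")
        img = _as_grid(X, self.range_convention)
        params = NoiseParams(self.a_, self.b_, img.range_convention)
        out, self.report_ = denoise(img, self._config(), params)
        return out.values

    def fit_transform(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X).transform(X)
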