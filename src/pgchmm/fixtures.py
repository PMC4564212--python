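"""Synthetic data generation: piecewise-smooth phantoms with curved
contours, replicate "microscopy stacks", and coefficient fields drawn from a
known hidden Markov tree.  Everything is deterministic per seed, so each
pipeline stage can be tested without external image downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .contourlet import ContourletConfig, ContourletPyramid, contourlet_forward
from .grid import ImageGrid, NoiseParams
from .hmt import HMTParams, build_trees, sample_hmt
from .noise import add_pg_noise

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_microscopy_stack",
    "generate_hmt_field",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the piecewise-smooth phantom generator."""

    size: tuple = (256, 256)
    n_regions: int = 6
    smoothness: float = 24.0      # correlation length of region boundaries, px
    levels: tuple = (0.1, 0.95)   # intensity range spanned by region levels
    texture_amplitude: float = 0.03
    range_convention: str = "unit"
    seed: int = 0


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> ImageGrid:
    """Piecewise-smooth phantom with curved region boundaries.

    Regions are the argmax partition of ``n_regions`` smooth random fields
    (which yields curved, cell-like contours); each region gets a distinct
    intensity level plus a gentle smooth ramp and low-amplitude texture.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    fields = np.stack(
        [
            gaussian_filter(rng.standard_normal((H, W)), spec.smoothness, mode="wrap")
            for _ in range(spec.n_regions)
        ]
    )
    label = np.argmax(fields, axis=0)
    lo, hi = spec.levels
    levels = np.linspace(lo, hi, spec.n_regions)
    rng.shuffle(levels)
    img = levels[label].astype(np.float64)
    # smooth intensity ramp inside regions (piecewise smooth, not constant)
    ramp = gaussian_filter(rng.standard_normal((H, W)), spec.smoothness * 2, mode="wrap")
    ramp = 0.1 * (hi - lo) * ramp / max(np.abs(ramp).max(), 1e-12)
    img = img + ramp
    if spec.texture_amplitude > 0:
        tex = gaussian_filter(rng.standard_normal((H, W)), 1.5, mode="wrap")
        img = img + spec.texture_amplitude * tex / max(np.abs(tex).max(), 1e-12)
    rmax = 1.0 if spec.range_convention == "unit" else 255.0
    if spec.range_convention == "byte":
        img = img * 255.0
    return ImageGrid(np.clip(img, 0.0, rmax), spec.range_convention)


def generate_microscopy_stack(
    truth: ImageGrid, params: NoiseParams, n_frames: int, seed: int = 0
):
    """Replicate acquisition: independent noisy frames of one clean image.

    Mirrors a repeated-exposure fluorescence acquisition whose frame average
    serves as the PSNR baseline.  Returns an array of shape
    ``(n_frames, H, W)``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    return np.stack(
        [add_pg_noise(truth, params, seed=rng, clip=True).values for _ in range(n_frames)]
    )


def generate_hmt_field(
    params: HMTParams,
    image_shape: tuple,
    config: ContourletConfig = ContourletConfig(),
    seed: int = 0,
):
    """A full pyramid whose directional coefficients are drawn from a known
    HMT (lowpass zero).  Returns ``(pyramid, states)``."""
    template = contourlet_forward(np.zeros(image_shape), config)
    trees = build_trees(template, params.mapping_mode)
    states, coeffs = sample_hmt(params, trees, seed)

    def fill(sb):
        return coeffs[(sb.scale_index, sb.direction_index)]

    pyr = template.map_coeffs(fill)
    pyr.lowpass = np.zeros_like(pyr.lowpass)
    return pyr, states
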