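# Methods

## Noise model

The recorded intensity is `z = y + η_p(y) + η_g` where `χ(y + η_p)` is
Poisson with mean `χy` and `η_g ~ N(0, b)`. Writing `a = 1/χ`, the noise
variance is affine in the signal, `σ²(y) = a·y + b`; `a` has intensity
units (variance added per unit of brightness), `b` intensity² units. Both
refer to a declared intensity convention — `unit` ([0, 1]) or `byte`
([0, 255]) — that is carried explicitly by every image and parameter set:
rescaling an image by `c` maps `a → c·a` and `b → c²·b`, so silent
rescaling would silently change the model. Simulation draws
`a·Poisson(y/a) + N(0, b)` (mean `y`, variance `a·y + b`), with an optional
clamp to the declared range that mimics a sensor/file format that cannot
record negative or over-range values.

### Clipped observations

At very low counts the clamp is not a technicality: for `a = 1/3,
b = 0.3²` on the unit scale the conditional mean `m(y) = E[clip(z) | y]`
saturates near 0.75 at `y = 1` and the conditional variance `v(y)` is
roughly half the affine value mid-range. `clipped_moments` computes both
exactly by summing the Poisson mixture (each component a clipped Gaussian
with closed-form moments). The pipeline's `declip` stage (on by default)
maps the smoothed image through `m⁻¹` to estimate the signal, subtracts
the pointwise clipping bias from the input, and uses `v(ŷ)` as the
variance map. Without it the bias — which concentrates in the lowpass band
that Bayesian shrinkage passes through untouched — dominates the residual
error at low counts (3–4 dB on 512² benchmarks at `a = 1/3, b = 0.09`).
For mild noise, or with `a = b = 0`, the correction is numerically a
no-op, so unclipped byte-scale experiments are unaffected.

## Noise-parameter estimation

`(a, b)` are estimated from one noisy image: the image is smoothed (5×5
binomial), partitioned into intensity level-sets (24 quantile bins,
segments under 256 pixels discarded), and each segment contributes a pair
`(ŷ_i, σ̂_i)` — the mean of the smoothed image, and a robust scale
(MAD × 1.4826) of unit-gain 2×2 high-pass detail coefficients. The affine
law is fitted by iteratively reweighted least squares on the squared
scale: the sample variance of segment i has approximate sampling variance
`2(a·ŷ_i + b)²/n_i`, so weights `n_i/(a·ŷ_i + b)²` are refreshed from the
current fit (Fisher scoring for the Gaussian approximation of the
likelihood). Estimates are constrained to `a, b ≥ 0` by projection onto
the active boundary; exact data are reproduced exactly, which a full ML
objective with its log-variance term would not do. `fix_b = 0` gives
Poisson-only fits. No censored-likelihood correction is attempted for
clipped data; on heavily clipped inputs the estimator returns the
effective (clipped) law.

## Contourlet transform

A Laplacian pyramid (default 5 levels; CDF 9/7 filter pair from
PyWavelets, orthogonal `db8` selectable) separates scales; each bandpass
band is split into directional subbands (default 4) by a directional
filter bank. Everything uses periodic boundary handling, which makes
perfect reconstruction exact and variance propagation
translation-consistent.

The directional filter bank is implemented with **exact DFT wedge masks**
rather than a spatial ladder structure: every frequency bin of the band is
assigned to exactly one slope wedge (|f_r/f_c| sectors and their
transposes), each wedge is decimated on its alias-free lattice (quincunx
at depth 1, diag(2,2) at depth 2, row/column refinements at depths 3–4),
and synthesis inverts the masked folding bin by bin. A small combinatorial
compiler resolves the discrete boundary bins: Hermitian bin-pairs are
assigned to wedges by an augmenting (Kuhn-style) search so that no wedge
holds two bins of one alias orbit, and the measure-zero set of bins that
alias themselves in every wedge is split across two wedges with a
conjugate ±i/2 mask pair whose 2×2 synthesis system is solved exactly.
The result is critically sampled (total coefficients = 4/3 of the pixels,
the Laplacian pyramid's redundancy), reconstructs to machine precision for
arbitrary input, and keeps all subband coefficients real. The trade-off is
spatial: brick-wall wedges have sinc-like impulse responses, so edges ring
across a subband and the representation is measurably less sparse than
with compactly supported fan filters — worth roughly 0.5–1 dB of
end-to-end PSNR. Since reconstruction, critical sampling and exact
variance propagation are the properties the rest of the pipeline depends
on, this design favors exactness over compact support; the filter family
is config, not contract.

## Variance propagation

Each subband coefficient is one inner product `⟨h, image⟩` with an
equivalent analysis filter `h` (obtained by probing the adjoint of the
analysis cascade with a unit coefficient; one probe per subband, two for
the quincunx phases). Under independent per-pixel noise the coefficient's
noise variance is therefore `Σ_x σ²_e(x) h(x − p)²`: the pixel-variance
map cross-correlated with `h²`, sampled on the subband lattice. For
stationary noise this is exact; for signal-dependent maps it inherits
only the (paper-level) assumption that neighboring pixel noises are
independent — the Monte-Carlo check at 1,000 realizations agrees to the
sampling floor (median relative deviation ≈ 3%, the expected
`0.674·√(2/n)` of a sample variance). The squared-filter spectra are
cached per image shape, so re-propagating for a circularly shifted image
(every cycle-spinning pass) costs one FFT per subband.

## Hidden Markov tree

Each directional coefficient carries a hidden state (1 small, 2 large
variance); states follow parent→child transitions across scale on
quad-trees rooted at the coarsest directional scale, and coefficients are
conditionally `N(0, σ²_{j,d,m})`. Two parent→child mappings are
available: `same_direction` (default; the 2×2 spatial block below the
parent in the same direction index — the natural choice when every scale
has the same number of directions) and `split_direction` (two spatial
children in each of the two finer subbands sharing the parent's
orientation, for 4-direction configurations; children alternate by column
parity so the mapping is a bijection).

Parameters are tied per subband (state variances), per scale-pair
(transition matrix into each subband) and per coarsest subband (root
priors); means are fixed at zero. The E-step is the exact upward–downward
algorithm, vectorized over the scale-contiguous node layout, with
per-node normalization for numerical stability. The observation
likelihood adds the propagated noise variance per coefficient,
`w | S=m ~ N(0, σ²_m + σ²_n)`, and the M-step updates the variances in
closed form through the latent clean coefficient
(`E[v² | w, m] = g²w² + g·σ²_n`, `g = σ²_m/(σ²_m+σ²_n)`), so the
log-likelihood is non-decreasing by construction (asserted in tests).
Initialization is a deterministic moment split
(σ²-small/large = 0.25/4 × the noise-adjusted second moment, floor
10⁻⁸·E[w²]; priors ½/½; transitions 0.8 diagonal); states are relabeled
after fitting so state 2 is the larger, with the relabeling cascaded
consistently through the transition matrices. The pipeline stops EM at a
relative log-likelihood change of 10⁻⁵ (max 50 iterations), which is
ample for shrinkage; parameter-recovery studies run to 10⁻⁷ because the
small-state variance converges slowly under added noise — at 10⁻⁵ it can
still sit ~40% high even though the shrinkage output is unchanged at the
displayed precision.

Denoising applies the posterior-weighted Wiener gain per coefficient
(a contraction: every gain is in [0, 1]); the lowpass band passes through
unshrunk.

## Pipeline

`denoise` = estimate `(a, b)` if not supplied → de-clip (above) → for each
of k1×k2 circular shifts (default 4×4, stride 1): transform, propagate
variances, fit the HMT (warm-started from the previous shift's fit, which
cuts later fits to a few iterations without changing the fixed point),
shrink, invert, un-shift → average → local adaptive Wiener filter
(3×3 window; residual-noise power `α·mean(a·ŷ+b)`, α = 0.25, gain
`(local_var − ν)₊/local_var`) → clamp to the declared range. The noise
parameters are shift-invariant under circular shifts, so they are
estimated once. All stages are deterministic, so repeated runs are
bit-identical.

## Synthetic data

`generate_phantom` builds piecewise-smooth images with curved, cell-like
boundaries (argmax partition of smooth random fields; distinct region
levels plus a gentle ramp and low-amplitude texture; 256², 6 regions, unit
scale by default — sized for fast test runs). `generate_microscopy_stack`
mimics replicate acquisitions: independent clipped noise realizations of
one clean frame, whose average serves as the PSNR baseline, as in
multi-frame confocal protocols. `generate_hmt_field` draws full pyramids
from a known HMT for parameter-recovery studies. What these fixtures do
not emulate: optics (PSF blur), photobleaching and temporal drift across
frames, pixel-correlated read noise, and the texture statistics of real
cell interiors — so passing tests demonstrate correctness of the noise
model, transform and inference machinery, not biological realism.

## Problem sizes and tolerances in the shipped checks

Reconstruction is checked to 10⁻⁶ (measured ~10⁻¹⁵). The Monte-Carlo
variance check uses 1,000 realizations at 256² and asserts the median
relative deviation ≤ 5% (per-coefficient deviations at this sample size
are ~4.5% sd, so a per-coefficient bound would fail for an exact
implementation). HMT recovery uses 4 scales with a 64² root field
(~3.5·10⁵ nodes); noise-law recovery a 512² ramp. The end-to-end grid
runs 128² phantoms with a reduced 2×2 cycle spin and capped EM — the
denoised-beats-noisy property is insensitive to these sizes, and the
shipped acceptance script re-runs a full-size 256² low-count example with
the complete 4×4 spin.

## Known limitations

- The brick-wall directional filters trade ~0.5–1 dB of denoising
  performance for exact reconstruction and exact variance propagation
  (see above).
- The `(a, b)` estimator assumes unclipped statistics; heavily clipped
  inputs yield the effective clipped law, which then interacts with the
  de-clipping stage's assumption that `(a, b)` describe the pre-clip
  model. When possible, supply calibrated parameters for strongly
  clipped data.
- Images are processed per channel; no cross-channel statistics.
- Frames of a stack are denoised independently; no temporal model.
- Grid dimensions must be divisible by `2^levels` (pad beforehand;
  periodic padding matches the transform's boundary model).
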