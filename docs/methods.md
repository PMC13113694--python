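# Methods

## Problem and model

Lung CT scans acquired on different scanners and with different
reconstruction protocols differ systematically in apparent brightness and
local contrast, which destabilizes downstream nodule classification.  The
package corrects this at the input level with contrast-limited adaptive
histogram equalization (CLAHE) whose two parameters are chosen
automatically by an evolution strategy.

### CLAHE

An image `I(x, y)` on the working range [0, 1] is divided into square
tiles of edge length `T`.  Per tile, a histogram `h(i)` over `L`
equal-width bins is computed (bin index `floor(v * L)` clamped to
`L - 1`), clipped at the limit `C_abs`,

    h~(i) = min(h(i), C_abs),

and turned into a cumulative mapping

    CDF(i) = (1 / N) * sum_{j <= i} h~(j),      N = T * T.

Each pixel's output is the bilinear blend of the four nearest tile-center
mappings at the pixel's bin; pixels beyond the outermost tile centers use
two mappings on edges and one in corners, which removes tile-boundary
artifacts.

Choices the defining equations leave open, resolved as follows:

* **Clip-limit unit.**  `C` is a fraction of the tile pixel count:
  `C_abs = max(1, round(C * N))`.  This makes the search range
  [0.01, 0.5] scale-free across tile sizes; a per-bin absolute count or a
  multiple of the uniform bin height would change meaning with `T`.
* **Excess mass.**  Default mode redistributes the clipped excess
  uniformly over all bins in a single pass (mass conserved; bins may
  marginally exceed the cap).  A `literal` mode performs truncation only.
* **Renormalization.**  The mapping is the CDF divided by its final
  value, so the output spans [0, 1] even after clipping; the literal,
  unrenormalized CDF is available behind `renormalize=False`.
* **Tile size** is a pixel edge length (values 8-64), not a grid count.
* **Non-divisible edges** are reflect-padded to a multiple of `T` and
  cropped after mapping.

### Quality metrics and the composite objective

Fidelity of an enhanced patch is measured against its un-enhanced
original: MSE; PSNR = `10 log10(MAX_I^2 / MSE)` with `MAX_I = 1` on the
working range (PSNR is invariant to joint rescaling, so dB values are
directly comparable to 8-bit-scale reports); NRMSE = `sqrt(MSE) / (max -
min)` of the *reference* image; and windowed SSIM (11x11 Gaussian window,
sigma 1.5, `C1 = (0.01 L)^2`, `C2 = (0.03 L)^2`, population moments,
averaged over interior window positions; images smaller than the window
fall back to one global window).  The tuning objective is

    f(C, T) = alpha * min(PSNR, cap) + beta * SSIM - gamma * NRMSE

averaged over a calibration set.  Defaults `alpha = beta = gamma = 1`;
the PSNR term in dB then dominates, which matches the observation that
the winning configuration is also the PSNR-maximizing one.  The 100 dB
cap keeps the identity enhancement finite and comparable.  All three
weights are configurable.

### CMA-ES over (C, T)

The clip limit is searched continuously on [0.01, 0.5]; the tile size
through a continuous exponent `z2` in [2.5, 6.5] with `T = 2^round(z2)`
snapped at evaluation (round half to even, exponent finally clipped to
[3, 6]), so both parameters are drawn jointly from one multivariate
normal.  The strategy is the canonical `(mu/mu_w, lambda)` CMA-ES for
dimension 2: population 6 (`4 + floor(3 ln n)`), logarithmic
recombination weights over the better half, cumulative step-size
adaptation, rank-1 plus rank-mu covariance update.  Numerical choices:

* **Initialization.**  Mean at the search-space center; unit global step
  size with diagonal covariance `diag((0.3 * range)^2)` per coordinate.
  The two coordinates have ranges 0.49 and 4.0, so the anisotropy must be
  carried by the covariance; a single scalar step over an identity
  covariance cannot serve both.
* **Boundary handling.**  Candidates are clamped only at decode time; for
  ranking, a quadratic penalty on the range-normalized distance to the
  feasible box (weight 10) is subtracted.  Without the penalty the
  genotype mean drifts arbitrarily far onto the clamped plateau and the
  search stalls.
* **Discrete tile coordinate.**  The snapped exponent makes the objective
  piecewise-flat: within a (T, C_abs) cell the objective is exactly
  constant, and the T=64 / large-C region is one large plateau where the
  cap never binds.  Two standard countermeasures keep the search global:
  the exponent's sampling standard deviation is floored at half a
  discretization cell (0.5), and on flat parent sets the step size is
  inflated by `exp(0.2 + c_sigma / d_sigma)`, the reference CMA-ES
  flat-fitness response.
* **Stopping.**  The evaluation budget (default 240) is the primary
  stop.  A stagnation rule (best-ever unchanged within 1e-6 for 25
  consecutive non-flat generations) saves budget once converged; flat
  generations do not count because they are plateau escape in progress.
  A 10-generation window was tried first and regularly cut off the escape
  dynamics on the discrete landscape.
* **Caching.**  The objective depends on the parameters only through
  `(T, C_abs)`, so scores are cached per cell within a run; cache hits do
  not consume budget.

Validated against an exhaustive 200-point grid (C in 0.01..0.50 step
0.01, T in {8, 16, 32, 64}) on a 6-patch phantom calibration set: 40/40
seeds reach the grid optimum within 1e-3.

### CutMix

For a pair of labeled patches, a rectangle with side ratio
`sqrt(1 - lambda)` (lambda drawn from Beta(alpha, alpha), default alpha
1.0) is pasted from the partner image; the keep-mask `M` marks pixels
retained from the first image.  The rectangle's center is drawn uniformly
and shifted just enough to keep the rectangle inside the image, so a
full-size cut covers the image exactly and no area is lost to border
clipping; the realized lambda is recomputed from the actual mask, making
`lambda = area(M) / (H W)` an exact integer identity for every draw.  The
soft label is `lambda * yA + (1 - lambda) * yB`.

### Intensity stratification

Mean lung intensity is `I_avg = (1/N) sum P_i` over a lung mask.  The
mask recipe is the package's own deliberately simple heuristic, validated
on phantoms only: HU band (-950, -300), morphological closing with a
radius-2 structuring element, hole filling, then the at most two largest
connected components not touching the array border.  Group cutoffs
default to the empirical 1/3 and 2/3 quantiles (linear interpolation) of
the supplied means — published low/medium/high boundaries are not
available, so auto-terciles stand in; explicit HU cutoffs can be passed.

### Classification metrics and split

Accuracy, precision, recall, specificity and F1 derive from the
confusion cells on unrounded fractions; a zero-denominator ratio is
reported as absent (`None`), never as zero.  AUC is the tie-aware rank
statistic.  Percentages round half away from zero, which reproduces the
published 98.88 / 99.10 figures from their confusion matrices.  The
scan split rounds the train and test fractions half away from zero and
gives validation the remainder — the unique rule that reproduces
622/178/88 from 888 scans at 70/20/10 (rounding all three independently
would give 89 and break the total).

## Synthetic phantom

Each phantom is a soft-tissue body ellipsoid (0 HU) in air (-1000 HU)
containing two lung ellipsoids (-850 HU), with spherical nodules
(default 4, radii 2-5 mm, -50..50 HU) and z-aligned cylindrical vessels
(default 6, radii 0.8-1.6 mm, 40 HU) placed inside the lungs by seeded
rejection sampling without overlap.  Object edges are blended linearly
over about one voxel, giving the weak partial-volume boundaries
enhancement must amplify.  Additive i.i.d. Gaussian noise (default SD
20 HU) emulates acquisition noise; a configurable global offset on the
lung interior emulates the scanner low/medium/high brightness groups.
Default grid 64 x 128 x 128 voxels at (0.7, 0.7, 1.25) mm spacing —
desk-scale but anisotropic like real CT.

What the phantom does not emulate: airway trees, lobular texture,
reconstruction-kernel and beam-hardening effects, motion artifacts, and
realistic nodule morphology (spiculation, juxta-vascular attachment).
Tests passing on phantoms therefore establish algorithmic correctness
and the qualitative behavior of the pipeline, not clinical performance
on real scans; absolute metric values on phantoms (e.g. tuned-CLAHE PSNR
around 25 dB on noisy synthetic patches) are not comparable to values
reported on real, smoother CT data.

## Problem sizes

Tests and the acceptance script run at deliberately modest sizes chosen
as sufficient for their statistical purpose: one 64 x 128 x 128 phantom
and six 51 x 51 calibration patches for the optimizer checks, 32 x 64 x
64 phantoms for stratification, 50 random 64 x 64 images for the CLAHE
oracle comparison, 1000 draws for the CutMix identity, and a 240-
evaluation search budget (about 40 generations of 6).

## Known limitations

* The lung mask is threshold-based and will fail on pathologies that
  fill the parenchyma; it is intended for intensity profiling, not
  segmentation.
* Only axial 2-D patches and diagonal (+/-1) direction matrices are
  supported; no resampling to isotropic spacing.
* The composite objective with default unit weights is dominated by
  PSNR; users wanting structure-weighted tuning should raise `beta`.
* CMA-ES is run single-start; the flat-fitness and std-floor safeguards
  proved sufficient in 2-D but are not a global-optimality guarantee.
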