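# Methods

## Fractional compact difference scheme

The shifted Grünwald difference `S_{β,γ} f(x) = β^{-α} Σ_k g_k f(x−(k−γ)β)`
with `g_k = (−1)^k C(α,k)` approximates the Riemann–Liouville derivative of
order `α ∈ (0,1)` only to first order in the grid spacing `β`.  Combining
the three shifts γ = 0, −1, −2 with weights ρ1, ρ2, ρ3 chosen to satisfy
the moment conditions

    Σ ρ = 1,   Σ ρ·r = α/2,   Σ ρ·r² = α²/4 − α/12     (r ∈ {0, −1, −2})

cancels the first two truncation terms and yields third-order accuracy.
The closed forms are ρ1 = (24 + 17α + 3α²)/24, ρ3 = (5α + 3α²)/24 and
ρ2 = −(11α + 3α²)/12.  Note ρ2 is fixed by consistency: it must equal
1 − ρ1 − ρ3, and the implementation's convergence test discriminates this
value empirically — with it, the operator applied to `f(x) = x⁴` converges
to `Γ(5)/Γ(5−α)·x^{4−α}` with fitted order ≈ 3.0 over spacings
1/64…1/256, while the single-shift operator shows order ≈ 1.0.

Collapsing the weighted operators into one stencil gives the mask
coefficients `c_k = g_{k−1}ρ1 + g_{k−2}ρ2 + g_{k−3}ρ3` (terms with
negative index dropped), consistent with the explicit low-order values
c1 = ρ1 and c2 = −αρ1 + ρ2.  At α = 1, N = 4 the stencil is exactly the
classical third-order backward difference (11/6, −3, 3/2, −1/3).

Conventions: images are indexed (row, col), 0-based; the "horizontal"
mask runs along columns, the "vertical" one along rows; both are
one-sided (the target pixel carries c1, the trailing taps look in the
negative axis direction), with replicate padding at borders and unit
pixel spacing.  The 1-D operator exposes spacing as a parameter purely so
the convergence experiments can refine the grid.  One-sidedness means the
gradient operator is *not* equivariant under 180° rotation unless the
stencil is reversed; a test documents this rather than hiding it.

## The despeckling filter

Standard NLM machinery: search window radius `l` (candidates), patch
radius `k` (similarity support), filtering parameter `h`.  The patch
distance is a kernel-weighted squared difference; the kernel is
normalized to unit sum, so the distance is a weighted *mean* squared
difference and `h` is directly comparable across configurations.  The
squared difference (rather than a signed sum) is required for the weights
to be positive, bounded by 1, and monotone in dissimilarity; likewise the
vertical variance uses |Δ^α_x| + |Δ^α_y| so that φ_y ∈ (0, 1].  φ_y is
evaluated once per pixel from precomputed gradient fields of the padded
image and read at the offset pixel x+Δ inside the kernel.  The self
weight ω(x,x) = 1 is used as computed, with no max-of-neighbors
substitution.  Every output pixel is a convex combination of its search
window, so the filter can never overshoot the local intensity range, and
the pipeline is fully deterministic.

The hot double loop (pixels × search offsets × patch offsets) is
numba-compiled; a pure-Python reference built from the public per-pixel
operations (`kernel_map`, `nl_weight`) is kept in the test suite and the
two paths are required to agree to 1e−10.

## Parameter defaults and rationale

| parameter | default | units | rationale |
|---|---|---|---|
| α | 0.5 | – | mid-range fractional order; α is a user choice, 0 < α ≤ 1 (α = 1 only as classical limit) |
| N | 4 | taps | shortest even stencil using all three ρ terms |
| l | 10 | px | 21×21 search window, standard NLM scale |
| k | 3 | px | 7×7 patch |
| h | 250 | intensity | matched patches have expected distance ≈ 2σ²; under 4-look speckle σ ≈ I/2 reaches ≈ 90 at the brightest layer, and h = 250 keeps genuine matches near unit weight. h of order σ or below collapses all non-self weights and the filter degenerates to identity |
| φ_x | 9 | px² | = k², so the kernel spans the patch horizontally while the vertical reach stays within ~1 px (φ_y ≤ 1): the intended along-layer anisotropy |
| η | 100 | intensity | scale of fractional-gradient magnitudes on a 0–255 image; gradients of that size halve φ_y |

The defaults form a broad operating regime, not a knife edge: on the
standard phantom conditions, h ∈ {250…400} and φ_x ∈ {9, 16} all give the
adaptive kernel an SSIM advantage over the uniform kernel on every seed
tried, with ≈ 10 dB PSNR gain.  With the normalized patch distance, a
*concentrated* kernel averages fewer effective patch samples, so its
distance estimate is noisier; small h amplifies that weight noise, which
is why the adaptive kernel needs h comfortably above σ to realize its
edge-preservation advantage.

## Synthetic data

The phantom emulates the geometry the filter targets: piecewise-constant
horizontal layers (seven bands, intensities 30–180 on a 0–255 scale) with
a sinusoidal vertical bowing of ±8 px, echoing retinal curvature.  Speckle
is multiplicative unit-mean gamma noise with `L = 4` looks (variance 1/L),
the fully developed speckle model — per-layer std/mean is 1/√L at every
intensity, which the tests verify.  An additive-Gaussian corruption exists
for sanity checks only.

What the phantom does *not* emulate: depth-dependent attenuation and
shadowing, the spatial correlation of real OCT speckle (speckle grain
size ≈ resolution cell, not 1 px), log-compressed display scaling,
vessel/lesion structure, and the fact that real "clean" references are
multi-frame averages with residual noise.  Passing the phantom tests
therefore demonstrates the algorithm's mechanics and its relative kernel
ablation, not clinical-grade performance on real scanners.

## Numerical choices

- Grünwald coefficients via the stable recurrence
  `g_k = (1 − (α+1)/k) g_{k−1}`; validated against the log-Γ closed form
  to 1e−10 relative error out to k = 512.
- Replicate ("edge") padding everywhere, by `l + k` pixels in the filter.
- Intensities are float throughout; quantization to 8 bits only at image
  write time (with clipping to [0, 255]).
- PSNR uses peak = 255 by default (flag-selectable); identical images
  report +inf.  SSIM uses the standard 11×11 Gaussian window (σ = 1.5)
  and stabilizers (0.01·peak)², (0.03·peak)².
- Degenerate inputs are rejected, not coerced: non-finite pixels, α
  outside (0, 1], odd stencil lengths, images smaller than one
  search+patch extent.

## Problem sizes

The test suite runs the convergence experiment to spacing 1/256, the
filter-invariant checks at 128×128, and the efficacy/ablation experiment
on five seeded 256×256 phantoms; the acceptance script uses three seeded
256×256 phantoms.  These sizes give stable statistics (SSIM spread across
seeds ≈ 0.001) while keeping a full run in the low tens of seconds.

## Known limitations

- The fractional masks are one-sided (positive axis directions only);
  no mixed-direction or centered 2-D fractional operators.
- Orders α > 1 and general shift triples beyond (0, −1, −2) are out of
  scope.
- The filter is O(HW·(2l+1)²·(2k+1)²); 3-D volumes and multi-frame
  fusion are not supported.
- On real OCT data the optimal (h, η) depend on the scanner's intensity
  scaling and must be set by the user; the defaults assume a 0–255 scale
  with strong speckle.
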