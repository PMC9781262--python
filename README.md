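# fcnlm

Speckle reduction for optical coherence tomography (OCT) images with a
non-local means (NLM) filter whose patch-similarity kernel is driven by a
third-order **fractional compact finite difference scheme (FCFDS)**.

OCT is a coherent imaging modality, so its B-scans are corrupted by
multiplicative speckle that obscures the retinal layer structure
clinicians rely on.  Classic NLM replaces each pixel by a weighted average
over a search window, with weights from patch similarity under a *uniform*
patch kernel.  `fcnlm` replaces that kernel with an adaptive anisotropic
one: broad along the (horizontally layered) image structure and shrunk
vertically wherever a fractional-gradient edge detector fires, so layer
boundaries are compared sharply while homogeneous speckle is averaged
away.

## The method

The Grünwald–Letnikov coefficients `g_k = (-1)^k C(α,k)` define the
shifted fractional difference of order `α ∈ (0,1)`.  A weighted
combination of three shifted operators (shifts 0, −1, −2) with weights

    ρ1 = (24 + 17α + 3α²)/24,  ρ2 = −(11α + 3α²)/12,  ρ3 = (5α + 3α²)/24

satisfies the moment conditions Σρ = 1, Σρ·r = α/2, Σρ·r² = α²/4 − α/12
and approximates the Riemann–Liouville derivative to **O(β³)** with a short
one-sided stencil (a compact scheme).  Collapsed to a single stencil
`c_k = g_{k−1}ρ1 + g_{k−2}ρ2 + g_{k−3}ρ3`, it is applied along both image
axes to give fractional gradient fields `Δ^α_x`, `Δ^α_y`.  These set a
per-pixel vertical variance

    φ_y = 1 / (1 + (|Δ^α_x| + |Δ^α_y|)/η),

and the similarity kernel over patch offsets Δ = (Δx, Δy)

    ℜ(Δ, x) = exp(−(Δx²/(2φ_x) + Δy²/(2φ_y(x+Δ)))),  normalized to unit sum.

NLM weights and the estimate are then the standard

    ω(x,t) = exp(−Σ_Δ ℜ(Δ,x)·(v(x+Δ) − v(t+Δ))²/h²),
    v̂(x) = Σ_t ω(x,t) v(t) / Σ_t ω(x,t).

The package also ships a layered-phantom simulator with unit-mean gamma
speckle (`L` looks, variance `1/L`), PSNR/SSIM metrics, and a
uniform-kernel NLM baseline for ablation.  See `docs/methods.md` for
parameter rationale and limitations.

## Worked example

```
$ fcnlm simulate --seed 3 --out-clean clean.png --out-noisy noisy.png
$ fcnlm denoise --in noisy.png --out est.png --verbose
fcnlm: config: NLMConfig(alpha=0.5, N=4, h=250.0, search_radius=10, patch_radius=3, phi_x=9.0, eta=100.0, pad_mode='edge') kernel=fcfds
fcnlm: read noisy.png (256x256) in 0.02s
fcnlm: filtered in 3.19s
fcnlm: wrote est.png
$ fcnlm evaluate --ref clean.png --est noisy.png
psnr=14.8959 ssim=0.131194 peak=255
$ fcnlm evaluate --ref clean.png --est est.png
psnr=22.8317 ssim=0.779034 peak=255
```

The 4-look speckle costs the phantom ~14.9 dB PSNR and almost all
structural similarity; the filter recovers ~8 dB and brings SSIM from 0.13
to 0.78.  The stencil itself can be inspected:

```
$ fcnlm masks --alpha 0.5 --n 4
c1 = +1.385416666667
c2 = -1.213541666667
c3 = +0.222656250000
c4 = -0.089192708333
sum = +0.305338541667
```

(At `--alpha 1` this reduces to the classical third-order backward
difference `11/6, −3, 3/2, −1/3`, whose taps sum to zero.)

The same pipeline is available as a library:

```python
from fcnlm import NLMConfig, denoise, make_phantom, default_phantom_spec

clean = make_phantom(default_phantom_spec(256, 256, seed=3))
est = denoise(noisy_array, NLMConfig(alpha=0.5, h=250.0))
```

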