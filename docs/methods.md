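# Methods

## Problem and model

Projection (sinogram) measurements in low-dose CT are photon counts, and the
detected count for ray *i* follows

    N_d ~ Poisson( N0 · exp(−∫_i μ ds) ),

so the noise standard deviation grows as the square root of the signal.
Classical variational denoising minimizes the ROF energy

    E_λ(u) = ½ ‖u − v‖² + λ TV(u),      TV(u) = Σ_ij |∇u|_ij ,

whose Gaussian fidelity term mismatches counting statistics.  Replacing it
with the negative Poisson log-likelihood changes the optimality condition
from `(u − v) + λp = 0` to `(u − v) + (λu)p = 0` (p a subgradient of TV):
the effective regularization should be *proportional to the signal*.

`sinotv` exploits this without solving the non-quadratic problem globally.
Each pixel's denoised value is obtained from a small weighted ROF problem on
a (2m+1)×(2m+1) window ω around it,

    E_{λ,W}(u′) = ½ ‖u′ − v_ω‖²_W + λ′ TV(u′),
    W(i,j)  = exp(−(i²+j²)/h²),
    λ′      = λ · Σ W′(i′,j′) v(i−i′, j−j′) / Σ W′(i′,j′),
    W′(i,j) = exp(−(i²+j²)/h′²)   over the (2a+1)² block,

i.e. the global strength λ scaled by a Gaussian-weighted local mean of the
counts — the maximum-likelihood estimate of the local Poisson mean.  Within
a window small enough that signal and noise level are roughly constant, the
quadratic-fidelity solution approximates the Poisson-likelihood solution,
and local minimization also suppresses the staircase artifacts that global
TV produces on the piecewise-smooth profiles typical of projections.

## Solver

The (weighted) ROF problems are solved by dual projection.  With the
forward-difference gradient (zero trailing boundary) and the divergence
defined as its exact negative adjoint, the dual iteration is

    p⁰ = 0;   g = ∇(D⁻¹ div pⁿ − v/λ′);
    semi-implicit:  pⁿ⁺¹ = (pⁿ + τ g) / (1 + τ |g|)
    projection:     pⁿ⁺¹ = Π_{|p|≤1}(pⁿ + τ g)

with D = diag(W) (identity in the unweighted case) and the recovery
u = v − λ′ D⁻¹ div p.  Both updates keep every iterate dually feasible.
Numerical behavior that shaped the defaults:

- τ = 0.125, the largest step with a convergence guarantee for the
  semi-implicit form; in the weighted problem the step is rescaled by
  min(W) to survive the D⁻¹ amplification (a conservative contraction
  bound).
- Stopping: max-norm of the dual update < 1e-4 or 200 sweeps, whichever
  first; tests that need optimality to many digits tighten both.
- The semi-implicit update is the default.  When the dual optimum sits on
  the |p| ≤ 1 boundary with a vanishing residual (e.g. a two-pixel image at
  the λ that exactly closes the gap), it converges only O(1/n) in the dual
  variable — though O(1/n²) in energy; the projection update converges
  linearly or finitely there and is energy-monotone to round-off, while the
  semi-implicit form can overshoot the energy by ~1e-8 relative near
  convergence.  `update="project"` selects it.
- |p| is the pointwise Euclidean norm of the 2-vector (isotropic TV).
- The window weight W is used with peak value 1 (not unit sum); any global
  rescaling of W is exactly equivalent to rescaling λ′.

## Tiling

The image is partitioned into (2a+1)×(2a+1) write-back blocks; each block's
window is the (2m+1)² neighbourhood of the block centre, clipped at image
borders with W and W′ renormalized over the clipped support (no padding —
no invented boundary data); final partial blocks absorb the remainder, so
the blocks tile the image with every pixel written exactly once.  Windows
with an all-zero local mean (λ′ = 0) are returned unchanged — zero counts
carry zero Poisson noise, and the weighted update divides by λ′.  Tiles
whose window geometry coincides are solved as one batched dual-projection
run; a per-pixel mode (stride 1, centre pixel only) verifies that the block
scheme is a faithful acceleration.  Denoising operates in the count domain
(pre-logarithm), where the Poisson model is written and λ′ is a mean
estimate; conversion to line integrals, −ln(max(counts, ε)/N0) with the
half-photon clamp ε = 0.5 (configurable), is a separate explicit step.

Because λ′ is proportional to the local signal, the whole scheme is
scale-equivariant: denoise(c·v; λ) = c·denoise(v; λ).

## Parameters

| symbol | meaning | default | rationale |
|---|---|---|---|
| λ | global regularization strength | user | swept over 10 log-spaced points in [0.01, 1] on simulated data |
| m | window half-size (px) | 10 | TV influence region ≈ 10 px at typical λ |
| h | bandwidth of W (px) | 2m | wide fidelity taper across the window |
| a | write-back / local-mean half-size (px) | 4 | block scheme nearly identical to per-pixel |
| h′ | bandwidth of W′ (px) | 2a | smooth local mean |
| τ | dual step | 1/8 | convergence guarantee bound |
| w, d, σ | bilateral window, spatial and range scales | 5, 5/6, swept | comparator's published setting; σ swept linearly over [0.5, 3.2] |

The bilateral comparator is the standard normalized weighted average whose
spatial/range kernels are the Gaussians of the published cost form (the
cost form itself specifies no minimization procedure).  Published σ values
of order 1 are far below the count-scale noise, so by default σ is
interpreted in local Poisson standard-deviation units (σ_eff = σ·√(local
mean count)); an absolute mode is available, and conclusions that depend on
the normalization should be read per mode.

## Simulator

The synthetic scenes emulate low-dose micro-CT projection acquisition of
the modified Shepp-Logan head phantom: 2-D parallel-beam by default (an
analytically checkable transform), with an optional fan-beam mode using the
scanner distances 449.29/397.04 mm.  Geometry choices, made once:

- Field of view 180 mm (adult-head scale) and attenuation scale 0.1 mm⁻¹
  per relative phantom unit (soft-tissue composite ≈ 0.02 mm⁻¹, skull rim
  0.1 mm⁻¹ at ~60 keV).  Peak line integrals are then ≈ 4.5, so expected
  counts at N0 = 500 span ≈ 5–500 — a genuinely low-dose regime.  Both are
  config values.
- Ray integration by sampled accumulation, step = half the pixel pitch,
  bilinear interpolation: central chords of test discs are reproduced
  within 1 %, non-grazing chords within ~4 %, and the per-view mass is
  conserved to ~0.01 %.
- Constant N0 across rays (no bowtie filtration); independent Poisson
  pixels; one integer seed determines all draws, with a per-view substream
  keyed by view index so results are independent of simulation order.

Not emulated: scatter, beam hardening, detector blur, electronic noise,
polychromatic spectra, 3-D cone geometry.  Tests passing on these scenes
therefore demonstrate the statistical and variational behavior of the
method under ideal Poisson counting noise, not robustness to correlated or
non-Poisson scanner effects.

Default desk-scale study size: a 128² phantom projected over 180 views
(sinogram 180×128) at N0 = 500 (high-noise) or 2000 (low-noise); sweeps use
five noise realizations.

## Metrics

- RMSE against the noise-free expected counts.
- Mutual information from 256-bin (configurable) equal-width histograms
  over the pooled range of both images, normalized by the reference's
  self-information; the plug-in estimator carries an upward bias of order
  (bins−1)²/(2N) nats, which matters for small images.
- SSIM evaluated globally from whole-image means, variances and covariance
  with C1 = (0.01·L)², C2 = (0.03·L)², L the reference's dynamic range.
  The product form of the two factors is used.
- Noise level: mean per-ROI population standard deviation.  Resolution
  proxy: maximum absolute first difference of a bilinearly interpolated
  line profile at unit spacing.
- `fbp2d`: ramp-filtered backprojection (scikit-image `iradon`) for
  parallel-beam image-domain checks; a centred-disc project/reconstruct
  round trip recovers the disc attenuation within 5 %.

## Known limitations

- No seam treatment between adjacent write-back blocks; measured block-mode
  vs per-pixel-mode discrepancy is small relative to the noise, but seams
  are not provably absent.
- The fan-beam mode has no matching reconstruction here.
- Population-std convention and global (not sliding-window) SSIM are
  deliberate, documented choices; comparisons with other toolchains must
  match them.
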