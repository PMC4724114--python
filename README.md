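# sinotv

Locally adaptive total-variation denoising of Poisson-noisy CT projection
(sinogram) data, with a projection simulator, a bilateral-filter baseline,
and image-quality metrics.

**Who it is for.** Low-dose CT and micro-CT work where the raw projections
are photon counts corrupted by quantum noise.  Denoising in the projection
domain — before reconstruction — can exploit the known Poisson statistics of
the counts, which are lost after backprojection.

**The method.** Counts obey `N_d ~ Poisson(N0·exp(−∫μ ds))`, so the noise
std grows as √signal.  Maximizing the Poisson likelihood under a
gradient-sparsity (total-variation) prior yields the optimality condition
`(u − v) + (λu)p = 0`: smoothing should be proportional to the signal.
`sinotv` realizes this by denoising each pixel from a small window around
it with the weighted ROF model

    ½‖u′ − v_ω‖²_W + λ′ TV(u′),    λ′ = λ × (Gaussian-weighted local mean count),

solved by Chambolle-type dual projection (`p ← (p+τg)/(1+τ|g|)`, τ ≤ 1/8).
Central (2a+1)² blocks are written back and the window advanced by (2a+1)
for speed.  Local minimization also avoids the staircase artifacts global
TV creates on the piecewise-smooth profiles typical of projections.
Defaults: m = 10, h = 2m, a = 4, h′ = 2a.  See `docs/methods.md` for the
full model, parameter table and numerical choices.

## Worked example

Simulate a low-dose (N0 = 500) Shepp-Logan parallel-beam count sinogram at
desk scale (128² phantom, 180 views), then sweep the regularization grid of
the adaptive TV denoiser and the σ grid of the bilateral baseline against
the noise-free expected counts:

```python
import numpy as np
from sinotv.workflows import simulate_counts, sweep_table

line, counts = simulate_counts(size=128, views=180, n0=500.0, seed=1)
truth = 500.0 * np.exp(-line.values)          # expected counts
noisy = counts.values.astype(float)           # RMSE vs truth: 11.16

print(sweep_table(noisy, truth, "tv-local")[["parameter", "rmse"]])
print(sweep_table(noisy, truth, "bilateral")[["parameter", "rmse"]])
```

Output (abridged):

```
tv-local    parameter      rmse          bilateral   parameter   rmse
            0.046416   4.926102                      2.6     5.764511
            0.077426   4.772320   <- optimum         2.9     5.629979
            0.129155   5.262763                      3.2     5.544833  <- optimum
```

The adaptive TV denoiser more than halves the RMSE of the raw counts
(11.16 → 4.77), its optimum sits at λ ≈ 0.08–0.13 on the 10-point log grid
over [0.01, 1], and it beats the bilateral baseline's best RMSE (5.54).

The same workflow is available from the shell:

```sh
sinotv simulate --size 128 --views 180 --n0 500 --seed 1 --out sim/
sinotv sweep --method tv-local --in sim/counts.tif \
       --truth sim/line_integrals.tif --sidecar sim/sidecar.json --out sweep.csv
sinotv denoise --method tv-local --lambda 0.08 --in sim/counts.tif --out den.tif
```

Projection stacks travel as multi-page TIFF (uint32 counts, float32
otherwise) with JSON sidecars; metric tables as CSV.

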