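# iterfbp

Iterative filtered-back-projection (iFBP) reconstruction for 2-D parallel-beam
computed tomography, with a complete simulation harness: deterministic
phantoms, an exact ray-driven projector, a low-dose photon-noise model,
image-quality metrics, and a small worked-example cohort statistic.

The package is aimed at people studying low-dose CT reconstruction who need a
self-contained, oracle-checkable testbed: every operator is small enough to be
verified against dense linear algebra, and every experiment is seeded.

## The method

The discrete acquisition model is

```
u = E r
```

where `r` is the image (h·w pixels, row-major), `u` the sinogram (X angles ×
Y detector bins, angle-major) and `E` the sparse matrix of exact ray/pixel
intersection lengths (Siddon traversal). Reconstruction is `r = E⁺ u` with
`E⁺` the Moore–Penrose generalized inverse, which is approximated by the
first-order iteration

```
P₀    = θ Eᵀ,          θ ∈ (0, 2 / λ₁(E Eᵀ))
P_{K+1} = P_K + P₀ − P₀ E P_K
```

whose residual `C_K = Π_range(E) − E P_K` contracts geometrically whenever
`‖C₀‖ < 1`. Multiplying the recursion by the measured data `u` and replacing
the `θ Eᵀ`-type applications with filtered back projection gives the
production image-domain loop:

```
R₀      = θ · FBP(u)
R_{K+1} = R_K + R₀ − θ · FBP(E R_K)
```

stopped when `Δ = ‖R_{K+1} − R_K‖₂ ≤ φ` or at the iteration cap. Both forms
coincide exactly when FBP is replaced by the explicit adjoint operator (this
equivalence is a test).

## Worked example

```python
from iterfbp import (ReconConfig, fbp_reconstruct, ifbp_reconstruct,
                     make_disk_phantom, mse, parallel_geometry, project)

disk = make_disk_phantom(128, 128, radius_fraction=0.3, value=1.0)
geom = parallel_geometry(60, 128, 128)          # sparse-view: 60 angles
sino = project(disk, geom)

config = ReconConfig(theta=1.0, phi=1e-4, max_iters=50)
fbp_img = fbp_reconstruct(sino, 128, 128, 1.0, config.filter)
ifbp_img, trace = ifbp_reconstruct(sino, 128, 128, 1.0, config, truth=disk)

print(f"FBP  MSE: {mse(disk, fbp_img):.6f}")
print(f"iFBP MSE: {mse(disk, ifbp_img):.6f}  after {len(trace)} iterations")
```

prints

```
FBP  MSE: 0.002956
iFBP MSE: 0.001913  after 50 iterations
```

i.e. on noiseless sparse-view data the iterative correction loop recovers
detail that the windowed FBP initialization smoothed away, driving the mean
squared error toward zero monotonically. The same pipeline is available from
the shell:

```
iterfbp phantom --kind lesion --size 128 --seed 0 --out phantom.tif
iterfbp project --image phantom.tif --angles 60 --out sino.csv
iterfbp recon --sino sino.csv --size 128 --theta 1.0 --max-iters 50 \
              --trace trace.csv --out recon.tif
iterfbp stats --out stats.json     # worked-example cohort table
```

`iterfbp stats` recomputes the two-arm survival rates (90.0% and 98.0%) and
the Pearson chi-square (2.8369, p = 0.092) from the bundled outcome counts.

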