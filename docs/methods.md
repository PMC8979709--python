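# Methods

## Acquisition model and discretization

The scanner is modelled as 2-D parallel-beam: X projection angles uniformly
spaced in [0, π), one ray per detector bin, bins centred on the rotation axis
with spacing equal to the pixel size by default, and Y = ⌈√2·max(h, w)⌉ bins
so the detector always spans the image diagonal. The forward operator `E` is
assembled (or applied matrix-free) by Siddon-style traversal: entry
(ray, pixel) is the exact intersection length in mm. Because `project`,
`backproject` and `build_system_matrix` share one ray tracer, the matrix-free
operators agree with explicit sparse products to rounding error and
`backproject` is the exact adjoint `Eᵀ` — both properties are asserted in
tests rather than assumed.

Pixel centres sit at half-integer offsets from the grid centre; phantom
ellipse membership is decided at pixel centres with no anti-aliasing, so
rasterization is exactly checkable against the analytic inequality. The
default study grid is 128×128 pixels at 1 mm: a "128 × 128" template is read
as a pixel count with unit pixel pitch, since a physical size alone does not
determine a discretization.

## Filtered back projection

Rows are ramp-filtered in the frequency domain with zero padding to the next
power of two ≥ 2Y (no circular wrap-around). The frequency response is the
FFT of the band-limited spatial kernel h[0] = 1/(4Δt²),
h[n odd] = −1/(πnΔt)², h[n even] = 0, which keeps a small positive DC gain
(~0.1% of peak at length 512) that corrects the negative bias of sampling
|f| directly; this is why noiseless FBP recovers the image mean to well
within 2%. An exactly-zero DC response is neither achievable for finite
kernels nor desirable. Apodization windows: ram-lak (none), hann (default),
cosine, each with a cutoff fraction of Nyquist (default 1.0).

Backprojection uses the exact adjoint; since the adjoint deposits
approximately (pixel area)/(bin spacing) per crossing ray, the inversion
weighting is π/(2X) times Δt/s². The default hann window was chosen for
stability under noise; the method's original description leaves the filter unspecified.

## The iterative reconstruction

Relaxation θ: admissible values lie strictly inside (0, 2/λ₁(E Eᵀ)), with
λ₁ found by power iteration (relative tolerance 1e-8). The dimension-based
selection rule is θ = 1 when h·w < Y·X and θ = 2^(−h·w/(Y·X)) otherwise,
both clamped at 0.99× the spectral bound; the production default is θ = 1,
the nominal choice for the under-determined sparse-view setting. The second
branch of the rule as published is garbled ("if PP < YX") and is
read as the complement of the first; without the spectral clamp the printed
rule alone can violate the convergence bound.

Stopping: Δ is the Frobenius norm over pixels of the update; φ defaults to
1e-4·‖R₀‖₂, scaling the tolerance to the data. The iteration cap defaults
to 50. The update is signed and never clamped mid-loop; a final clamp at 0
is an off-by-default flag. The residual norm of the matrix iteration uses
the orthogonal projector onto range(E) (SVD with a rank tolerance), the only
reading under which the contraction inequality and the Moore–Penrose limit
both hold; for full-row-rank E it reduces to I − E·P_K. The dense matrix
path is restricted to h·w ≤ 1024 by contract — it exists to be tested
against dense oracles, while the image-domain loop is the production path.

Divergence: θ above the bound makes the residual grow geometrically; the
dense path reports it (growth past 10× the initial residual, or non-finite
iterates) and the image loop raises on any non-finite iterate, naming the
iteration.

## Low-dose simulator

Dose reduction is Poisson thinning of a Beer–Lambert photon count:
N ~ Poisson(I₀·d·e^(−p)) per bin, p̂ = −ln(N/(I₀·d)), with zero counts
floored to one photon. I₀ defaults to 10⁵ per bin; the ladder experiment
uses I₀ = 10⁴ where the delta-method variance e^p/(I₀·d) is comfortably in
the photon-limited regime. Dose-study phantoms use attenuation 0.03 /mm
(soft-tissue scale): line integrals then peak near 2.3, so counts stay well
above the floor. A phantom at the convention ceiling of 1.0 /mm across a
77 mm disk would give line integrals ≈ 77 and starve every central bin,
reducing the model to its count floor.

Default measurement regions for centred-disk phantoms: a centred
(h/4)-square "uniform" ROI inside the object (noise and SNR signal) and a
corner (h/8)-square "background" ROI in air but inside the field of view.

## Problem sizes

Unit and property tests run on grids ≤ 64×64 with ≤ 30 angles; the
reconstruction studies use the 128×128 grid at 60 views (noiseless MSE
study) and 180 views (dose ladder, fractions 1.0/0.75/0.5); the matrix
iteration runs on 4×6, 6×4 and 8×8 toy operators (the last rank-deficient,
built by duplicating rows of an identity-plus-noise matrix — random
all-positive matrices are too close to rank one for meaningful convergence
studies) with the near-optimal relaxation 2/(λ_max + λ_min) over the
nonzero spectrum.

## What the synthetic data does and does not show

The phantoms are piecewise-constant ellipse composites; the "lesion" kind
mimics the morphology of a necrotic focus (hypodense interior) and a
rim-enhanced pseudocyst, not anatomy. The simulator omits fan/helical
geometry, scatter, beam hardening, electronic noise and tube-current
modulation. Passing tests therefore demonstrate the algebraic and
statistical properties of the operators under an idealized parallel-beam,
photon-limited model — not clinical image quality.

## Known limitations

- **The iteration sharpens; it does not denoise.** The update is noise-blind
  (no statistical weighting or prior). In the frequency domain FBP∘E acts
  approximately as multiplication by the filter window W(ω), so after K
  iterations the noise transfer is 1 − (1 − θW)^{K+1}, which exceeds the
  single-pass factor W at every frequency for any K ≥ 1: the loop
  progressively undoes the hann apodization and converges toward the
  unapodized data-consistent solution. Measured on the dose ladder, the
  iterative reconstruction's uniform-ROI noise is ≈3× FBP's at matched dose,
  while its sparse-view artifact MSE is lower. The corresponding acceptance
  test of the opposite ordering is deliberately left failing rather than
  weakened; claims that this family of iterations lowers noise require a
  noise model or regularization that the implemented update does not
  contain.
- Δ-monotonicity under noise is observed but not guaranteed and is not
  asserted.
- The dense pseudo-inverse path recomputes a small SVD per step for its
  residual; it is a verification tool, not an efficient solver.
- The worked-example cohort table as published is internally inconsistent;
  the loader reconciles counts to the printed rates (45/5, 49/1) and warns.
  The chi-square printed alongside that table (5.89) is not reproducible
  from any standard 2×2 statistic on those cells; the recomputed Pearson
  value is 2.8369 (Yates 1.5957), reported but never asserted against the
  printed one.
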