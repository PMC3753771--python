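# Methods

## Problem and forward model

A real image `u` on an `N×N` grid (intensities nominally in [0, 1]) is
observed through a partial Fourier operator `K = P F`: a unitary 2D DFT
(`norm="ortho"`) followed by restriction to a boolean sampling mask.  The
unitary convention makes `K*` the inverse transform restricted to the mask,
gives Parseval exactly, and makes the diagonal of `K*K` equal to the
sampling ratio — facts the solver and its tests rely on.  Off-mask k-space
entries are stored as exact zeros and carry no information.

**Variable-density sampling.**  Real CS-MRI acquisitions sample low spatial
frequencies densely.  The mask generator selects the `round(c·N²)`
lowest-frequency points deterministically (a fully sampled center disk,
`c = center_fraction`, default 0.04; the DC point is always included so the
image mean is always observed), then draws the remainder without replacement
with probability `∝ (1 − r)^decay`, `r` the normalized distance from DC
(`decay = 6` by default).  Exactly `round(ratio·N²)` points are selected,
reproducibly per seed.

**Noise models.**  Gaussian noise is added in k-space: i.i.d. complex,
standard deviation `level` per real/imaginary component, on acquired entries
only.  Rician noise models magnitude MRI and is applied in the image domain
— `u_noisy = sqrt((u + n₁)² + n₂²)` with `n₁, n₂ ~ N(0, (level·max u)²)` —
and then measured through the mask.  This is the standard two-channel
construction by which Rician noise physically arises; the "level" is the
component standard deviation relative to the maximum intensity (unit scale
for an all-zero image, so the Rayleigh limit is well-defined).

## The nonlocal weight graph

Weights follow the non-local-means construction:
`w_ij = exp(−‖G_σ ∗ (patch_i − patch_j)‖²/h²)` over a Gaussian-weighted
(σ = `sigma_patch`, default 1 px, kernel normalized to unit sum) squared
difference of 5×5 patches (`patch_radius = 2`), for every candidate `j` in
an 11×11 search window (`search_radius = 5`).  Patches are mirror-padded at
the image border; candidate neighbours must be real pixels (no wrap-around).
Per pixel the `neighbors_kept = 10` largest weights are retained, then the
graph is symmetrized by `w ← max(w, wᵀ)`, which bounds memory at `O(N·k)`
while keeping `w_ij = w_ji ∈ (0, 1]`.

**Bandwidth `h`.**  `h` is the perturbation scale below which patches count
as similar; it should track the noise level *of the guide image*.  A guide
reconstructed from undersampled data is dominated by aliasing artifacts, not
thermal noise, so a wavelet-based noise estimate is far too small (measured:
weights collapse to ~1e−11 and the solver loses the regularizer).  The
default is therefore adaptive: `h = h_scale·sqrt(median patch distance)`
over all in-window candidates.  For a noise-dominated guide the median
distance is ≈ 2σ², so this reduces to the noise-standard-deviation scale.
`h_scale = 0.5` (selective) is the default and suits artifact-dominated
guides; reconstruction-quality guides tolerate the full scale
(`h_scale = 1`), which the pipeline uses for its second pass (below).

**Guide image and the two-pass default.**  Weights are computed from the
zero-filled reconstruction of the observed data (the image-domain
counterpart of the noisy measurement).  At 20% sampling this guide limits
the method: with oracle weights (built from the ground truth) NLTV beats the
TV baseline by ≈ 1.9 dB on the textured phantom, with zero-fill weights by
only ≈ 0.1 dB.  The pipeline therefore rebuilds the weights once from the
first-pass NLTV image and reconstructs again (`graph.recompute_once`,
default on); this restores a robust ≈ 0.5 dB margin at twice the cost.  Set
the flag off for the single-pass behaviour.

## Discrete nonlocal calculus

Edge fields live on the directed edges of the graph (CSR order).  The
operators are

    (∇u)_ij  = (u_j − u_i)·√w_ij
    |∇u|_i   = sqrt(Σ_j (u_j − u_i)² w_ij)
    (div q)_i = Σ_j (√w_ij q_ij − √w_ji q_ji)
    (Δu)_i   = Σ_j (u_j − u_i) w_ij  =  div(∇u)/2   for symmetric w

The square root is attached to the edge operators so that the per-pixel norm
carries plain weights *and* the adjoint identity `⟨∇u, q⟩ = −⟨u, div q⟩`
holds exactly — the formulation is otherwise over-determined, and adjointness
is the property the solver's optimality conditions are derived from.  The
divergence is written with both `√w_ij` and `√w_ji` so that it remains the
exact negative adjoint even for asymmetric weights; for symmetric weights it
reduces to the familiar `Σ_j (q_ij − q_ji)√w_ij`.  Adjointness to 1e−10 on
random instances is the module's primary correctness oracle.

## Split Bregman solver

The unconstrained problem `min_u ‖∇_NL u‖_1 + (μ/2)‖Ku − v‖²` is solved with
an outer Bregman data refresh `v^{k+1} = v^k + v − Ku^{k+1}` (on acquired
entries) and inner splitting sweeps:

* **u-step.**  The quadratic subproblem's normal equations are
  `(μK*K + γ∇ᵀ∇) u = μ Re(K*v^k) − γ div(d − b)`, with
  `(∇ᵀ∇u)_i = Σ_j (w_ij + w_ji)(u_i − u_j)` — diagonal
  `μ·ratio + γ·Σ_j(w_ij + w_ji)`.  They are solved by a few exact
  lexicographic Gauss-Seidel sweeps: `K*K` restricted to real images is
  circular convolution with `C = Re(ifft2(mask))`, so each pixel update can
  propagate its exact column contribution (an `O(N)` inner loop, numba-
  compiled; the residual is refreshed by one FFT round trip per sweep).
  Exact coordinate descent on a symmetric positive definite system never
  increases the subproblem objective — the property the descent tests
  assert.  A damped-Jacobi mode (`sweep_mode="jacobi"`, damping 0.5) uses
  only FFTs per sweep and scales better to large images, at the price of a
  convergence guarantee.
* **d-step.**  With `s_ij = (∇u)_ij + b_ij` and group norm
  `n_i = sqrt(Σ_j s_ij²)`, the exact minimizer is groupwise (isotropic)
  shrinkage `d_ij = (s_ij/n_i)·max(n_i − 1/γ, 0)` (zero where `n_i = 0`);
  the output's group norm equals `shrink(n_i, 1/γ)` exactly.
* **b-step.**  `b ← b + ∇u − d` per edge.

The solver initializes with the zero-filled image and `d = b = 0`, runs
`n_outer = 30` refreshes of `n_inner = 1` sweeps with `gs_sweeps = 4`, and
stops early when the relative change of `u` drops below `tol = 1e−4`
(set `tol = 0` to disable; at full sampling the relative change can fall
below tolerance while the iterates are still converging, so consistency
checks use `tol = 0`).  It is deterministic — identical inputs give
bit-identical outputs — and complex intermediates never arise because the
real-variable normal equations are solved directly.

**Defaults** `μ = 100`, `γ = 10` (unit-intensity images) were chosen by a
coarse grid search on the synthetic protocol; reconstruction quality is flat
within a factor ~2 of both.  `μ` trades data fidelity against smoothing
(larger = sharper but noisier); `1/γ` is the shrinkage threshold on
edge-group norms.

**TV baseline.**  The SB-TV baseline uses the identical loop structure with
forward finite differences (Neumann boundary) and per-pixel isotropic
shrinkage over the two directions, implemented independently of the graph
machinery (dense array stencils, the 5-point `DᵀD` Laplacian).  On the
unit-weight forward-difference grid graph the NLTV solver reproduces it to
≈ 1e−13 relative error — the bridge test tying the two implementations
together.

## Quality metrics

* **SNR** `= 10·log10(‖u_ref − mean(u_ref)‖ / ‖u_ref − u_rec‖)` dB with
  *unsquared* norms — half the usual `20 log10` convention; halving the
  error adds 3.01 dB.  Infinite at identity, undefined (error) for a
  constant reference.
* **RE** `= ‖u_rec − u_ref‖/‖u_ref‖·100` %.
* **SSIM**: Wang et al. index with local Gaussian windows (σ = 1.5,
  11×11), `K1 = 0.01`, `K2 = 0.03`, dynamic range `L = 255`; delegated to
  scikit-image with sample covariance disabled.  For constant images it
  reduces to the closed form `(2ab + C1)/(a² + b² + C1)`.
* **FSIM**: similarity maps of phase congruency
  (`S_PC = (2·PC1·PC2 + T1)/(PC1² + PC2² + T1)`, `T1 = 0.85`) and gradient
  magnitude (`T2 = 160`, Scharr/16 stencil on the 8-bit scale), combined as
  `S_PC^α·S_G^β` (`α = β = 1`) and pooled with weights
  `PC_m = max(PC1, PC2)`.  Phase congruency uses the standard log-Gabor
  construction: 4 scales × 4 orientations, smallest wavelength 6 px, scale
  multiplier 2, σ_onf = 0.5978, Gaussian angular spread, Rayleigh-statistics
  noise compensation (k = 2) and a frequency-spread sigmoid weight.  The
  map is dimensionless — invariant to positive affine rescaling of the
  input up to the stabilization constants (~1e−3).
* SSIM/FSIM expect both images on the same dynamic range; the pipeline
  clips reconstructions to [0, 1] and multiplies by 255 before computing
  them.  SNR/RE are computed on raw intensities.  No FSIM downsampling
  stage is applied (images here are small).

## Synthetic phantoms — what they do and do not show

The piecewise phantom (elliptical body, rectangular insert, disk; ≥ 3
constant regions with small seeded intensity jitter) is TV's best case.  The
textured phantom superimposes a band-limited texture — unit-variance white
noise smoothed with a Gaussian of σ = 1 px, amplitude 0.10 — on the body and
the insert, giving nonlocal regularization something local TV cannot
represent; the default study conditions (64×64, 20% sampling, Gaussian
σ = 0.01 or Rician 5%, five mask seeds) yield the method ordering
zero-fill < SB-TV < NLTV on mean SNR in both noise cases.  A Shepp-Logan
variant (resampled from scikit-image) is included for qualitative use.

These phantoms emulate undersampling artifacts, global noise, and repeating
texture.  They do not emulate anatomy-scale structure variety, coil
sensitivity or phase variation (all data are real-valued), motion, or
intensity nonuniformity — so passing tests demonstrate correctness of the
machinery and the texture-preservation mechanism at reduced scale, not
clinical performance.  Experiments default to 64×64 (versus the 256×256
typical of the literature) so the whole comparison protocol runs in about a
minute; larger sizes are a config change, and the exact Gauss-Seidel
u-step's `O(N²)` sweep cost is the main scaling concern (use
`sweep_mode="jacobi"` beyond ~128×128).

## Numerical notes and limitations

* Weights below the exp underflow threshold are clamped at `exp(−700)` so
  every retained edge stays strictly positive; a constant guide yields all
  weights exactly 1.
* Degenerate group norms (`n_i = 0`) shrink to exactly 0; masks always
  include DC, so the linear systems are nonsingular (`μ·ratio` plus a
  positive graph diagonal).
* Early stopping compares successive iterates; it can trigger while the
  outer Bregman loop still has bias to remove (see above).
* The multi-seed comparison reports mean ± sd over mask realizations;
  per-seed values are written alongside.
* History records (objective, relative change, SNR per sweep) are
  monitoring aids; the objective is the splitting objective with the
  current `b`, which is not monotone across outer refreshes by design.
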