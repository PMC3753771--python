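# nltvmri — compressed-sensing MRI reconstruction with nonlocal total variation

Magnetic resonance imaging acquires Fourier coefficients of the image
("k-space"); acquiring fewer of them shortens the scan.  Compressed sensing
recovers the image from a random undersampled subset by exploiting sparsity
under a regularizer.  The workhorse regularizer, total variation (TV),
penalizes local gradients uniformly and therefore flattens exactly the
fine-scale texture that matters clinically.

`nltvmri` implements reconstruction with a **nonlocal total variation (NLTV)
regularizer solved by Split Bregman iteration**, together with everything
needed to evaluate it end to end on synthetic phantoms: k-space simulation
with variable-density undersampling, Gaussian and Rician noise models, an
isotropic-TV Split Bregman baseline, the zero-filled baseline, and the four
standard quality metrics (SNR, relative error, SSIM, FSIM — the last with a
full log-Gabor phase-congruency implementation).

## The method

With `K = P F` the partial unitary Fourier operator (`P` the sampling mask)
and `v` the measured k-space data, the reconstruction solves

    min_u  || ∇_NL u ||_1  +  (μ/2) || K u − v ||²

where the nonlocal gradient couples each pixel `i` to the pixels `j` in its
search window whose 5×5 patches look similar,

    (∇_NL u)_ij = (u_j − u_i) √w_ij,
    w_ij = exp( −‖G_σ ∗ (patch_i − patch_j)‖² / h² ) ∈ (0, 1].

An outer Bregman loop "adds back" the data residual
(`v^{k+1} = v^k + v − K u^{k+1}`), and each step alternates

1. **u-step** — linear solve `(μK*K + γ∇ᵀ∇) u = μK*v^k − γ div_NL(d − b)`,
   by exact Gauss-Seidel sweeps (K*K on real images is circular convolution
   with the inverse DFT of the mask);
2. **d-step** — per-pixel groupwise soft thresholding of `∇_NL u + b` with
   threshold `1/γ`;
3. **b-step** — Bregman update `b ← b + ∇_NL u − d`.

Because the weights tie together repeating structure anywhere in the search
window, texture is reinforced instead of smoothed away.

## Worked example

```sh
nltvmri init-config config.yaml          # textured 64×64 phantom, 20% sampling,
nltvmri compare -c config.yaml -o demo   # Gaussian σ=0.01, 5 mask seeds
```

prints (also written to `demo/comparison.csv`):

```
method           SNR (dB)         RE (%)             SSIM             FSIM
zero_fill     7.13 ± 0.07   13.43 ± 0.23   0.8245 ± 0.0078   0.7986 ± 0.0067
sb_tv        10.30 ± 0.09    6.47 ± 0.13   0.9575 ± 0.0007   0.9549 ± 0.0020
nltv         10.79 ± 0.12    5.77 ± 0.15   0.9665 ± 0.0015   0.9698 ± 0.0017
```

Each row averages one method over five random mask realizations.  Zero-fill
(plain inverse FFT of the undersampled data) is the floor; the TV baseline
removes most aliasing; NLTV adds ~0.5 dB SNR and the largest FSIM gain
because the textured regions of the phantom survive reconstruction instead
of being flattened.  SNR here is `10·log10(‖u_ref − mean‖/‖u_ref − u_rec‖)`
(unsquared norms), so +3.01 dB means the error norm halved.

The same pipeline is scriptable from Python:

```python
import nltvmri as nv

ref  = nv.make_phantom("textured", 64, seed=0)
mask = nv.make_vardens_mask(64, ratio=0.20, seed=1)
data = nv.add_noise(nv.forward_measure(ref, mask), "gaussian", 0.01, seed=2)
graph = nv.compute_weights(nv.zero_fill_recon(data))
recon, history = nv.reconstruct_nltv(data, graph, nv.SolverParams(), ref=ref)
print(nv.snr(ref, recon), nv.relative_error(ref, recon))
```

## Layout

| module | contents |
|---|---|
| `nltvmri.kspace` | phantoms, variable-density masks, forward model, noise, zero-fill |
| `nltvmri.graph` | patch-similarity weights; nonlocal gradient/divergence/Laplacian |
| `nltvmri.solvers` | shrinkage, Split Bregman NLTV solver, SB-TV baseline |
| `nltvmri.metrics` | SNR, relative error, SSIM, FSIM (+ phase congruency) |
| `nltvmri.pipeline` / `nltvmri.cli` | experiment runner and `nltvmri` command |

See `docs/methods.md` for the numerical details, parameter guidance, and
known limitations.
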