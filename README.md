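# relaxmore

Self-supervised, subject-specific reconstruction of quantitative MRI
parameter maps from undersampled multi-coil acquisitions, by unrolling a
learnable proximal gradient descent — an independent implementation of the
RELAX-MORE approach, exercised end-to-end on synthetic variable-flip-angle
(vFA) T1-mapping data with known ground truth.

## The problem

vFA T1 mapping acquires spoiled gradient-echo (SPGR) images at several flip
angles η_k and fits, per voxel, the signal model

    M_k(T1, I0) = I0 · (1 − E1) sin η_k / (1 − E1 cos η_k),   E1 = e^(−TR/T1)

for the spin-lattice relaxation time T1 and complex proton density I0.
Accelerating the acquisition by undersampling k-space breaks the pixel-wise
fit: zero-filled reconstructions alias, and the classical DESPOT1 regression
amplifies noise in low-SNR regions. Supervised deep-learning reconstructions
need fully sampled training data that is expensive to acquire for qMRI.

`relaxmore` instead trains on the **subject's own undersampled k-space**.
With the multi-coil encoding f = U F C x (U sampling mask, F unitary FFT,
C coil sensitivities), the parameter maps Δ = {T1, I0} solve

    min_Δ  ½‖U F C M(Δ) − f‖² + R(Δ),

unrolled into T phases of proximal gradient descent: a data-fidelity gradient
step with learnable step size α_i^(t) per parameter and phase, followed by a
learned residual proximal operator D̃( S_β( D(·) ) ) + id, with S_β soft
thresholding and D / D̃ mirror-image convolutional networks. Initialization
networks (coil combination + δ-initialization) produce δ^(0) from the
zero-filled images. All learnables are optimized with Adam against the
multi-phase self-supervised loss

    L = Σ_{t=0..T} γ_t ‖U F C x^(t) − f‖²,   x^(t) = M(δ^(t)),

with γ_T = 1 and γ_t = 1e−4 otherwise. Training **is** reconstruction: no
reference data, no population training set.

## Worked example

Simulate a brain-like digital phantom acquisition (4 coils, FA {5,10,20,40}°,
TR 40 ms, AF=3 variable-density Cartesian mask, complex k-space noise), then
train and evaluate:

```bash
relaxmore simulate out/sim --grid 32 --n-coils 4 --af 3 --n-center 6 \
    --noise-sigma 0.004 --seed 1
relaxmore train out/sim/kspace_under.h5 out/run --epochs 400 \
    --learning-rate 3e-3 --n-phases 4 --seed 1
relaxmore evaluate out/sim/truth out/run/recon out/report.csv
```

which prints

```
wrote acquisition to out/sim
final loss 6.13917 after 400 epochs -> out/run
recon: PSNR 20.96 dB, SSIM 0.9206, NMSE 0.05011
```

The final loss is the multi-phase k-space MSE in normalized units; the
evaluate line scores the trained T1 map against the ground truth inside the
object. The zero-filled DESPOT1 baseline on the same data scores NMSE 0.272 /
SSIM 0.775, so the self-supervised reconstruction cuts the T1 error roughly
five-fold while removing the aliasing artifacts. The same comparison is
available programmatically via `relaxmore.compare_methods`, and
`relaxmore.despot1_fit` / `relaxmore.nlls_fit` provide the classical
baselines.

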