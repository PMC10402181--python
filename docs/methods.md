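# Methods

## Signal model and baselines

The vFA SPGR steady-state signal is M_k(T1, I0) = I0 (1 − E1) sin η_k /
(1 − E1 cos η_k) with E1 = exp(−TR/T1). T1 and TR are in milliseconds
throughout; flip angles are degrees at the API surface. A B1+ transmit-field
map, when provided, scales the nominal flip angles voxel-wise
(η_eff = b1 · η_k), the standard vFA compensation. Echo-time decay,
imperfect spoiling, magnetization transfer and multi-compartment effects are
outside the model.

Two classical pixel-wise baselines are provided because the field's
"standard pixel-wise fitting" can mean either: the DESPOT1 linearization
(regress S/sin η on S/tan η; slope → T1, intercept → |I0|) and per-voxel
nonlinear least squares of |M| initialized from DESPOT1. Both fit magnitude
images; the phase of I0 is recovered only by the network path. Voxels whose
DESPOT1 slope falls outside (0, 1), with degenerate regressors, or excluded
by the fit mask are **flagged invalid (T1 = NaN) rather than clamped**:
pixel-wise fitting genuinely fails in low-SNR regions and silently clamped
values would contaminate the metrics. Invalid voxels are excluded from
evaluation masks.

## Encoding operator and masks

The multi-coil encoding is f = U F C x with a **unitary, centered** 2D FFT
per slice (pre/post `fftshift`), so the adjoint is the inverse transform and
the forward/adjoint pair passes the dot-product test at machine precision.
Arrays are 0-based with fixed axis order [kx, ky, z, coil, flip-angle]; a
mask's z axis may be singleton and broadcasts. Coil maps are an input
(simulated or precomputed); no calibration/ESPIRiT estimation is performed.

Two mask families implement the reference undersampling schemes, with a
fresh seeded realization per flip angle and bit-exact reproducibility from
(seed, scheme, shape, AF):

- **1D Cartesian variable density**: fully sampled readout; exactly
  round(Nky/AF) phase-encode lines per flip angle, the central n_center
  always included, the rest drawn without replacement with density
  (1 − d/dmax)^q in the distance d from the center. The decay law is not
  fixed by the scheme's definition, so the exponent is exposed (default
  q = 3, a common center-weighted choice).
- **2D Poisson disk**: Bridson-style dart throwing on integer pixel sites
  around an all-ones central calibration block. The minimum-distance radius
  is bisected to the largest value that over-samples the budget and the
  surplus points are randomly thinned to land the total sampled fraction
  within 10 % of 1/AF — thinning cannot violate the minimum distance, which
  is checked on the snapped integer coordinates actually emitted. The AF
  accounting **includes** the calibration block, so AF is a true
  acceleration statement.

## Synthetic study conditions

The generators are pure functions of (parameters, seed) and emulate three
regimes: a vial phantom (non-overlapping constant-T1 disks in a bath,
defaults spanning 300–3000 ms), a brain-like object (WM 850 ms / GM 1400 ms
/ CSF 4000 ms — literature-typical 3T values, configurable), and a low-SNR
regime reached by raising the k-space noise and dropping to few coils rather
than by anatomical realism. |I0| is 1 inside the object with a smooth
low-order polynomial phase; noise is i.i.d. complex Gaussian **in k-space**
(per coil and flip angle), matching the measurement model. Coil
sensitivities are smooth complex Gaussian lobes placed around the FOV
perimeter, RSS-normalized to 1.

What the phantoms do *not* model — anatomical texture, B0/B1 field
structure beyond a smooth multiplicative map, motion, imperfect spoiling —
bounds what passing tests show: they validate the estimation machinery under
the stated measurement model, not clinical image quality.

## Unrolled reconstructor

Each of T phases applies, per parameter i ∈ {T1, I0}:

1. **Gradient step** δ̄_i = δ_i − α_i^(t) ∇_i ½‖U F C M(Δ) − f‖², with the
   gradient computed analytically (Jacobian of M times the adjoint-encoded
   residual), not by nested automatic differentiation — the forward pass is
   a defined operator. The training-time derivative *through* this step is
   taken by the package's autodiff tape.
2. **Learned proximal step** δ_i = D̃_i(S_{β_i^(t)}(D_i(δ̄_i))) + δ̄_i, a
   residual network with elementwise soft thresholding between a
   convolutional transform D and its mirror-image (reversed channel
   progression, independent weights) D̃.

Complex quantities enter networks as two real channels; volumes are
processed as stacks of 2D slices (slices are the batch axis) with 3×3
kernels. The reference architecture is 4×[Conv(3×3, 32), ReLU] plus a linear
head for the two initialization networks and 8×[Conv(3×3, 64), ReLU] plus a
single-kernel head for each D; these are the class defaults.

Numerical choices that make the scheme stable:

- **T1 bounds.** The signal model diverges for T1 ≤ 0, so the
  δ-initialization network maps its T1 channel through a bounded sigmoid
  onto [t1_min, t1_max] (defaults 1–5000 ms) and every phase re-projects T1
  into the bounds by clipping.
- **T1 step preconditioning.** Under unit-normalized data the fidelity
  gradient w.r.t. T1 in ms is ~10⁶ smaller than w.r.t. I0. The T1 gradient
  step is multiplied by t1_scale_ms² (default 1000²), a fixed Jacobi-style
  preconditioner, so one α₀ preset serves both parameters. The prox networks
  likewise see T1 in units of t1_scale (≈ unit range) and their residual is
  scaled back.
- **Identity-at-init proximal.** All network weights use seeded Xavier
  initialization *except* the output layer of each D̃, which starts at zero:
  every learned proximal step is then exactly the identity at
  initialization. Without this, the Xavier-scale residual (×1000 ms on the
  T1 channel) swamps the physics-driven gradient steps and short training
  budgets cannot recover.
- **Positivity of learnables.** α and β are stored as logarithms, so
  α > 0, β > 0 hold by construction during optimization.
- **Degenerate input.** All-zero k-space is accepted with a warning and
  yields the initialization-driven output, enabling smoke tests.

α_i^(t), β_i^(t) are independent scalars per parameter and phase,
initialized from the per-anatomy presets (brain α₀ = 0.1, β₀ = 1e−5; knee
α₀ = 0.5, β₀ = 1e−7; phantom α₀ = 0.9, β₀ = 1e−3). The proximal derivation
uses the standard squared proximity term; the soft threshold is the
elementwise ℓ1 shrinkage (a grouped row-wise ℓ2 variant is a known
alternative but is not implemented). The regularization weight λ and the
proximity weight ρ are absorbed into the learned β.

## Self-supervised training

Adam (library-standard β₁ = 0.9, β₂ = 0.999, ε = 1e−8) optimizes all
learnables against L = Σ_t γ_t ‖U F C x^(t) − f‖², t = 0…T, with γ_T = 1
and γ_t = 1e−4 otherwise. Learning-rate presets: 1e−4 (brain, knee), 5e−4
(phantom); the reference schedule is 10,000 epochs. Before training, f is
scaled so the maximum magnitude of the RSS-combined zero-filled images is 1
(the factor is undone on the output I0); this is what makes the α₀/β₀/lr
presets transfer across data sets. Training is deterministic given the
seed (pure numpy, single-threaded reductions). Early stopping is not used —
budgets are fixed epoch counts. Transfer learning loads a checkpoint's
weights as the starting point on new data (architecture checked
field-by-field); optimizer state is reset.

## Evaluation

PSNR, SSIM and NMSE are computed on T1 maps within a declared object mask,
with the reference peak/range L taken as the masked maximum of the
reference. SSIM uses the customary 11-tap Gaussian window (σ = 1.5,
population covariance), which the metric definition leaves open; values
outside the evaluation mask are zeroed before the windowed statistics so
windows straddling the object boundary compare methods on the same support,
and the mean is taken over mask voxels. K1 = 0.01, K2 = 0.03. Identical
inputs report a +∞ PSNR sentinel rather than raising.

## Scaled study conditions

The end-to-end, transfer-learning and phase-depth studies (tests and
`scripts/acceptance.py`) run at reduced sizes chosen as this package's
standard synthetic conditions: 32×32 single-slice brain-like phantoms,
4 coils, FA {5, 10, 20, 40}°, TR 40 ms, AF = 3 Cartesian masks with 6
central lines, k-space noise σ = 0.004 (placing the zero-filled DESPOT1 T1
NMSE near 0.1–0.2, i.e. aliasing-dominated), T = 4 phases, width-16 depth-3
networks, 400 epochs at learning rate 3e−3. The shorter schedule uses a
larger learning rate than the 10,000-epoch reference presets, as usual when
compressing an Adam schedule. The phase-depth study compares T = 8 vs T = 2
at an equal 100-epoch budget; the transfer study uses a 60-epoch budget on
second subjects with new anatomy, mask and noise realizations but the same
simulated receive array — the subject-specific networks key strongly on the
coil profiles, and a transfer study models a second subject scanned on the
same scanner. Transferring across coil arrays fails outright here (the
initialization network's T1 logits saturate on out-of-distribution input),
a stronger subject-specificity than real multi-subject data exhibits.

## Known limitations

- The learned proximal operator has no convergence guarantee; T is fixed.
- DESPOT1's noise sensitivity makes the zero-filled baseline's NMSE heavy-
  tailed (slope → 1 gives unbounded T1); invalid-voxel flagging mitigates
  but does not remove this.
- 3D data is processed slice-wise; no 3D convolutions or through-slice
  regularization.
- The numpy autodiff engine favors clarity over speed; wall-clock budgets,
  not statistical ones, set the default problem sizes above.
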