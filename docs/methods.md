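# Methods

This note documents the models, numerical choices and limitations of
`axdki` in the way its maintainers reason about them.  Nothing here
states an empirical result that the test suite or the acceptance script
does not itself compute.

## Signal model

The diffusion-weighted log signal is represented by the second-order
cumulant expansion, log(S/S0) = −b·D(n) + (b²/6)·D̄²·W(n), with b in
ms/µm² and diffusivities in µm²/ms throughout (1000 s/mm² = 1 ms/µm²;
FSL-style bval files are converted on read).  Working in ms/µm² keeps
the design-matrix entries and the spatial-penalty entries of comparable
magnitude, which matters for the conditioning of the joint solve.

Under axial symmetry the kurtosis tensor reduces to (W⊥, W∥, W̄) and the
directional kurtosis becomes

W(θ) = (1/16)[cos4θ·(10W⊥ + 5W∥ − 15W̄) + 8cos2θ·(W∥ − W⊥) − 2W⊥ + 3W∥ + 15W̄].

This grouping is the unique axisymmetric quartic satisfying all three
defining identities — W(0) = W∥, W(π/2) = W⊥, and uniform sphere average
W̄ — and each identity is locked by a unit test, as is the exact
agreement between this expression and the kurtosis columns of the
linear design matrix.  W̄ and W⊥ are *tensor* quantities (contractions
and surface averages of the kurtosis tensor); they are deliberately
distinct from the conventional numerically averaged mean/radial
kurtosis, which this package does not compute.

The sign convention places an explicit minus on the b·D term so that
kurtosis-free signals decay monotonically with b; a unit test asserts
the decay.

## Two-step regularized fitting

Both steps minimize ‖Ax − y‖² + γ‖Tx‖² jointly over all masked voxels,
where A is voxel-separable and T takes spatial first differences of
selected parameter components.  Ordinary (unweighted) least squares is
used for the data term in both steps for its lower bias relative to
weighted least squares.

**Step one (axis).** A 7-parameter log-linear diffusion-tensor fit;
the symmetry axis is its principal eigenvector and is never updated
afterwards.  Pooling strategies: AFAB (all frequencies and b-values,
one shared axis field — the default, resting on the assumption that
the fiber axis does not change over the frequency range), SFAB (per
frequency, all shells), SFLB (per frequency, low shell ≤ 1.5 ms/µm²
plus b0; threshold configurable).  The penalty weights are 1 on
diagonal and 2 on cross-term tensor components — equal weighting within
each group keeps the quadratic penalty rotationally invariant; the √2
cross-term weighting found elsewhere in the literature is documented
but not adopted.  log S0 is never penalized (18 penalty entries per
voxel).

The tensor data model has two variants.  `joint` (default) is the
standard joint OLS over all selected volumes; on data with non-zero
kurtosis its tensor estimate carries an O(b²·W) bias because the
quartic signal term projects onto the quadratic design — for axis
estimation this bias is generally tolerable and it is what a plain DTI
fit of DKI data does.  `quadratic` first solves, per direction, the
exact quadratic-in-b system log S(b) = c0 − bD + (b²/6)U (requires ≥2
distinct non-zero shells per direction and a b0), then fits the tensor
to the kurtosis-free ADCs; on noiseless axisymmetric data this recovers
the tensor and the axis exactly, which is what makes the 9-direction
exact-recovery property testable to 1e-6.  Joint estimation of the
axis together with the kurtosis parameters is deliberately out of
scope.

**Step two (kurtosis).** With θ = arccos|n̂·axis| fixed per voxel and
volume, the model is linear in x = (log S0, D⊥, D∥, D̄²W⊥, D̄²W∥, D̄²W̄).
Fitting the D̄²-scaled kurtosis components keeps the problem linear; W
quantities are recovered afterwards as u/D̄², and the kurtosis ratios
never divide by D̄ at all (K∥ = u∥/D∥², K⊥ = u⊥/D⊥²).  Each frequency
is solved independently — the model has no cross-frequency coupling
beyond a shared AFAB axis; a joint multi-frequency solve would be a
possible extension, not implemented.  b0 volumes are always included
(they constrain log S0) and carry the frequency label of their
acquisition block.  The penalty covers the five diffusion/kurtosis
components (15 entries per voxel).

Negative fitted kurtosis ("blackened" voxels) is preserved in stored
maps and counted in sidecars — its prevalence is a useful noise
diagnostic; clamping, if any, belongs to visualization.  Metric values
with zero denominators (K⊥ at D⊥ = 0, etc.) are NaN sentinels, never
silent infinities, and are excluded-but-counted in ROI statistics.

**Defaults.** Base regularization γ_DT = 0.5 and γ_DK = 0.075
(preclinical-style protocols) or γ_DK = 0.2 (human-style), with a
single net multiplier scaling both — these are the knobs a user sweeps.
Automatic γ selection (L-curve, GCV) is out of scope.

## Solver

Conjugate gradients on the normal equations (AᵀA + γTᵀT)x = Aᵀy with a
matrix-free operator; per-voxel AᵀA blocks are precomputed, the penalty
is applied as weighted masked forward differences followed by their
exact adjoint.  The penalty here is the quadratic (ℓ2) form of total
variation — the squared norm of first differences, fast to evaluate by
CG — not the ℓ1 edge-preserving variant.

Numerical choices: forward first differences in index space (the
penalty is defined per voxel, with no voxel-size scaling); at mask and
array boundaries the difference is zero (Neumann-style), so the penalty
never couples masked to unmasked voxels; the adjoint is the exact
transpose of that masked operator, locked by an inner-product test —
this pairing is the single most bug-prone contract in the package.
Defaults: relative tolerance 1e-8 on the normal-equation residual, 500
iterations, zero initialization; all configurable.  The solver is
deterministic and single-threaded; maximum-iteration exhaustion
returns the best iterate flagged non-converged and the fitting layer
raises with diagnostics.

The log transform guards non-positive magnitudes from noise with
y = log(max(S, ε·S0_est)), ε = 1e-6, S0_est the per-voxel maximum;
guarded-sample counts surface in diagnostics.

Eigenvector signs are fixed (first non-zero component positive) purely
for reproducibility; every consumer is sign-invariant, and degenerate
(λ1 ≈ λ2) voxels take whatever eigenvector the decomposition returns —
such axes are arbitrary under noise by nature.

## Full-tensor baseline

The 22-parameter kurtosis-tensor OLS fit exists to benchmark the
axisymmetric route.  It shares the same forward model (kurtosis term
(b²/6)·D̄²·W(n)); the D̄²-scaled components are fitted linearly and
unscaled afterwards from the fitted tensor block.  Axisymmetric-defined
metrics from the full tensor use W∥ = W(axis), the closed-form sphere
average for W̄, and the closed-form circle average for W⊥,
(3/8)(W̃2222 + W̃3333) + (3/4)W̃2233 in the axis-aligned frame, derived
from the trigonometric moments ⟨cos⁴⟩ = 3/8 and ⟨cos²sin²⟩ = 1/8.  Both
closed forms are locked against quadrature oracles rather than trusted
from external implementations.  D∥/D⊥ come from the tensor eigenvalues
(axial eigenvalue; mean of the two radial ones).  The default metric
axis is the principal eigenvector of this same fit's tensor block.

## Encoding schemes

Directions are stored in the channel-amplitude convention as printed
(1 = one channel at maximum) and unit-normalized internally wherever
the b-matrix is formed; the per-volume b-value from the bval file is
always authoritative.  The 10-direction scheme combines six two-channel
directions (|G|² = 2, hence twice the b-value of a single-channel
direction at fixed timing) with four tetrahedral directions at
amplitude 2/3 (|G|² = 4/3).  The "factor of two" efficiency statement
is exact for the six two-channel rows; the tetrahedral rows fall short
of it at 4/3 if read as a norm-squared (b-value) ratio — the package
stores the rows as printed and exposes `b_efficiency_ratio` so the
ambiguity is inspectable rather than hidden.

Effective diffusion time for cosine OGSE is Δt_eff = 9/(64f); for PGSE
it is a sequence parameter and must be supplied, never computed.
Frequency 0 denotes PGSE throughout.

`repulsion_directions` generates antipodally symmetric
electrostatic-repulsion direction sets (deterministic per seed); the
golden-angle spiral construction is also provided but its symmetry
makes it slightly non-generic for quartic design matrices, so rank
studies use the repulsion sets.

## Synthetic phantom

The generator emulates a desk-scale multi-frequency acquisition: a
16×16×8 grid holding a curved high-anisotropy "WM" tube (axis following
the tube tangent) in a near-isotropic "GM" background, scanned with the
10-direction scheme, shells 1.0/2.5 ms/µm², frequencies 0/60/120 Hz and
2 b0 volumes per frequency.  Default region parameters (WM: D∥ = 1.5,
D⊥ = 0.4 µm²/ms, W∥ = 0.6, W⊥ = 1.6, W̄ = 1.0; GM: D = 0.8 isotropic,
W = 0.7) are library defaults in the physiologic range — inputs to the
tests, not claims.  Noise is Rician by default (magnitude of a complex
Gaussian perturbation, σ = S0/SNR, default SNR 20) with Gaussian
available for linear-theory tests; signal averages are independent
repetitions combined by mean.  An optional linear-decrease dispersion
profile scales the kurtosis triplet by (1 − s·f/f_max) to give each
frequency distinct ground truth.

What the phantom does *not* emulate: realistic microstructural
substrates (no random-walk simulation), partial-volume and CSF
contamination, EPI/partial-Fourier artifacts, eddy currents, motion, or
spatially varying coil sensitivity.  Passing tests therefore
demonstrate the correctness and noise behavior of the *fitting
machinery* under the stated noise model, not the biological accuracy of
frequency-dependent kurtosis values in tissue.

Monte-Carlo problem sizes in the test suite (grids from 6×6×3 to
16×16×8, 5–20 noise seeds, SNR 15–20) were chosen as the smallest sizes
at which the directional effects under test are comfortably resolved
above seed-to-seed variation.

## Evaluation utilities

CSR between two ROIs is (mean_A − mean_B)/√(σ²_A + σ²_B); it is
undefined when both ROIs are exactly constant.  SNR maps are mean/std
across repeated b0 acquisitions (≥3 repetitions; zero-std voxels
flagged infinite and excluded from ROI means).  Cross-frequency axis
agreement is histogrammed by FA bin; the default edges 0.2/0.4
separate low, moderate and high anisotropy and are configurable, since
any specific binning is a reporting convention.  Gaussian pre-smoothing
(the baseline noise control) filters each magnitude volume before the
log transform with a 4σ-truncated kernel and reflect boundaries — the
kernel dialect only affects edge voxels but is stated because it
changes them deterministically.

## Known limitations

- The quadratic TV penalty smooths noise but, unlike ℓ1 TV, does not
  preserve sharp edges perfectly at high γ; over-regularization
  flattens genuine contrast.  γ selection is manual.
- The axis is a point estimate; its uncertainty does not propagate into
  the kurtosis maps.
- Gradient-vs-image frame reorientation, preprocessing (denoising,
  Gibbs, eddy/distortion correction) and atlas registration are out of
  scope and assumed done upstream.
- No Rician-bias correction in the log-domain fit: at low SNR the
  floored log transform inherits the magnitude bias; the phantom's
  Rician mode exists precisely so this effect is visible in tests.
- Single-threaded CPU implementation; large human-scale volumes are
  feasible but not fast.
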