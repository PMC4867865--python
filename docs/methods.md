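# Methods

This note records the model, the estimation procedure, every tunable
that matters, the design choices made where the design was genuinely
open, and the known limitations.  Nothing here states an empirical
result that the test suite does not itself compute.

## Model

Voxel concentration curves are convolutions of a known, positive
arterial input function with an unknown impulse-response function
(IRF): C_i(t) = (I ⊗ M_i)(t).  The scanner observes the decayed signal
Y_ij = C_i(t_j) e^{−λ t_j} + ε_ij at frame times t_1 < … < t_p, with λ
the isotope decay constant (5.663×10⁻⁴ s⁻¹ for ¹¹C) and ε independent
noise.  The target is V_T(i) = ∫₀^τ M_i, with τ = t_p: a nonparametric
estimate cannot be extrapolated beyond the experiment, so the
finite-horizon integral is the estimand throughout (including in the
simulators' ground truth).

Decay-corrected curves follow a multiplicative random-effects
Karhunen–Loève expansion

    C_i(t) = A_{i0} μ(t) + Σ_k A_{ik} φ_k(t),

with E[A_{i0}] = 1 and φ_k the eigenfunctions of the covariance of
C_i − A_{i0} μ.  The multiplicative term reflects receptor-density
scaling of otherwise similar kinetics.  Because convolution is linear,
M_i(t) = A_{i0} μᵈ(t) + Σ_k A_{ik} φ_kᵈ(t) where μ = I ⊗ μᵈ and
φ_k = I ⊗ φ_kᵈ: deconvolution is needed only for 1 + K functions.
Note φ_kᵈ is a basis of the deconvolved space, not itself an
eigenbasis.

## Estimation

**Mean.**  μ̂(t_j) is the *unsmoothed* cross-sectional mean of Y·_j
times e^{λ t_j} (smoothed-then-decay-corrected means inherit a bias
from the exponential transform), linearly interpolated between frames.
It is exactly unbiased at the frame times — an algebraic identity the
suite asserts at machine precision.

**Presmoothing.**  X_i is reconstructed by a local-linear fit with a
product Epanechnikov kernel over space and time, computed as
sequential one-dimensional passes (the product-kernel shortcut; this
approximates the joint 4D fit).  One spatial bandwidth h_z (mm) is
shared by all spatial dimensions.  The temporal bandwidth is locally
adaptive: at each of n_b knot times the raw half-width is the smallest
h with ≥ `min_count` frame times in [t−h, t+h] (default 4; this floors
the width at the distance to the 2nd-nearest frame, keeping it
positive at the left boundary), a degree-4 polynomial smooths the knot
half-widths, the evaluated profile is clamped below at 10% of the
median raw half-width, and a calibration coefficient β scales the
result.  Defaults: n_b = 13 (about a third of a 32-frame schedule;
clamped to p for shorter schedules).

**Bandwidth calibration.**  (h_z, β) minimize the leave-`n_cv`-voxels-
out mean squared prediction error of the *measured* values, averaged
over `n_replicates` random draws (defaults n_cv = 1, N = 5000;
deterministic given the seed, and the draws are shared by all
candidates).  h_z is selected first with β = 1, then β with h_z fixed
— sequential to save computation.  Candidate grids default to
{1, 1.5, 2, 3, 4}× the voxel size for h_z and {0.5, 0.75, 1, 1.5, 2}
for β; both are configurable since no canonical values exist.
Cross-validation predicts with the joint (not sequential) product-
kernel fit at the held-out voxel, which is exact and cheap for single
voxels.

**A_{i0}, covariance, scores.**  Â_{i0} = ⟨Ĉ_i, μ̂⟩/⟨μ̂, μ̂⟩ with
composite-trapezoid quadrature on the frame grid (all functional inner
products in the package use this rule on whatever grid the functions
live on).  The residual covariance is the plain second moment
Γ̂ = n⁻¹ Σ R_i R_iᵀ with R_i = Ĉ_i − Â_{i0} μ̂ — no re-centering, which
preserves positive semi-definiteness.  The eigenproblem is
symmetrized with √w (w the quadrature weights) so the recovered
eigenfunctions are quadrature-orthonormal (asserted to 10⁻⁸).
Numerical policy: eigenvalues below 10⁻¹⁰ of the leading one are
dropped, at most K_max = 10 are kept, an eigensystem whose leading
eigenvalue is at the round-off floor of the data scale is treated as
empty, and each eigenfunction's largest-magnitude entry is made
positive (a reproducible sign convention; the expansion is invariant).
Scores are quadrature inner products of the residual with each
eigenfunction.

**Component count.**  R²(i, L) = 1 − var{Y_i − Ĉ_i(·, L) e^{−λ·}} /
var{Y_i}, with population variances across the p frame times, and
L_i is the smallest k ≥ 0 with R²(i, k+1) − R²(i, k) < 0.025 (else
K_max).  The search starts at the mean-only fit k = 0.  Voxels with
var{Y_i} = 0 (flat background inside the mask) are assigned L = 0 and
a mean-term-only V_T, with a log entry.

**Deconvolution.**  On the grid 0 = s_0 < … < s_m = τ (equispaced,
m = 250 by default — enough that quadrature error is negligible
against noise, small enough to be instant), the convolution becomes a
lower-triangular matrix A with entries I(s_j − s_{k−1}) times the
composite weights s_1/2, s_2/2, (s_k − s_{k−2})/2.  Positivity of I on
(0, τ] makes every diagonal entry positive, so the least-squares
problem is an exact triangular solve; an optional ridge penalty
(default 0) is exposed for noisy curve-by-curve use, and an
ill-conditioned operator falls back to a pseudo-inverse solve with a
warning.  Frame-time curves are linearly interpolated onto the grid;
values on [0, t_1), where nothing is measured but the operator needs
support, hold the value at t_1 (flagged in the basis metadata).
V_T integrals use trapezoid quadrature over the response nodes
s_0…s_{m−1}.

Accuracy of the discretization: for input functions with I(0) = 0 —
every physical arterial bolus — the rule is second-order (error ÷4
per grid doubling, verified against closed-form convolution pairs).
For hypothetical inputs with I(0) > 0 it degrades to first order,
because the rule omits each row's I(0)·M(s_j) endpoint triangle.

## Baselines

*Curve-by-curve* applies the identical triangular solve independently
per voxel — the brute-force comparator whose noise amplification the
basis expansion avoids.  *Spectral analysis* expands each
decay-corrected curve on input-convolved decaying exponentials
(I ⊗ e^{−β_g t}, default 64 rates log-spaced in [10⁻⁵, 1] s⁻¹,
configurable) with nonnegative coefficients via NNLS, and
V_T = Σ_g θ_g (1 − e^{−β_g τ})/β_g; applied to presmoothed curves it
is the "preprocessed" variant.  Both share the pipeline's operator
and finite-horizon V_T so comparisons are like for like.

## Synthetic data

**Input function.**  No measured arterial curve is distributed, so a
scaled-gamma bolus I(t) ∝ t^{shape−1} e^{−t/scale} is the default
everywhere (shape 3, scale 30 s, peak 350 activity units at 60 s):
a sharp early peak with a decaying tail, the canonical bolus shape.
I(0) = 0 and I > 0 on (0, τ].

**1D curves.**  M_i = μ_M + B_{i1}ψ_1 + B_{i2}ψ_2 with
μ_M(t) = 0.0049 e^{−0.0005t} + 0.0018 e^{−0.0112t}, ψ₁, ψ₂
L²-normalized sine/cosine of period 2000 s (normalizers √(2/2000)),
B_{i1} ~ N(0, 0.1²), B_{i2} ~ N(0, 0.05²); 200 curves at 200 equally
spaced times on (0, 2000] s; iid N(0, 2²) noise at the observation
times.  Convolution runs on a fine grid (m = 2000) so the generator's
quadrature error is an order below the analysis grid's.

**2D phantom.**  Nested elliptical regions with exact pixel counts
(pixels sorted by elliptical radius; smallest region innermost),
default five regions of 9614/5351/3701/414/5704 pixels.  Those counts
sum to 24 784, which cannot partition a 128×128 grid, so the default
grid is 160×160 at 2 mm with the leftover pixels labelled 0 and
excluded from the mask.  Kinetics per region: sums of decaying
exponentials Σ α e^{−βt} (two-compartment), or scaled survival
functions S(t) = 1 − Σ_j w_j F_j(t/60) of a two-component gamma
mixture (shape/scale in minutes, parameters drawn per voxel from the
configured normal laws).  Because the printed survival scale constants
do not reconcile with the printed V_T targets under any single reading,
each survival voxel is instead rescaled so its finite-horizon integral
equals its drawn target — the stated purpose of those constants.
Per-voxel V_T variability is a mean-one log-normal factor with 6.5%
coefficient of variation (the within-region variability reported for
measured data); compartmental voxels scale their amplitudes by the
same factor, which is exact for V_T.  Frames: 32 of increasing
duration (4×15 s … 12×300 s, 87 min).  The signal is blurred
frame-wise with a Gaussian PSF (FWHM 6 mm; σ = FWHM/(2√(2 ln 2))),
decayed, and degraded with Gaussian noise of variance κ·S̄_i, S̄_i the
voxel's time-averaged blurred signal (quasi-Poisson).  κ defaults to
S̄_med/SNR² with a target median-voxel SNR of 5 — a deliberately noisy,
PET-like regime — because the quantity is never stated and the
signal-free region precludes defining it there; any quantitative
comparison should state its κ.

What the generators do *not* emulate: tomographic reconstruction
artifacts and spatially correlated (non-Gaussian) reconstruction
noise, scanner normalization, motion, and measured-AIF shape details.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not scanner-grade validation.

## Design choices on open points

- Frame representative time is the mid-time (standard for rebinned
  PET; not otherwise specified anywhere).
- Times are seconds; voxel coordinates in mm from the affine (or voxel
  size); activity units are opaque and only need to be consistent
  between scan and input function.
- Input-function interpolation is linear; extrapolation beyond its
  domain is an error rather than a guess.
- Cross-validation scores predictions against the measured (decayed)
  values, since that is the scale on which the smoother operates.
- A_{i0} is not re-estimated after component selection; V_T stays the
  exact linear form in (A_{i0}, scores).
- The deconvolution grid is equispaced on [0, t_p]; m = 250.

## Known limitations

- **Truncation shrinkage.**  The R²-increment rule measures fit to the
  *noisy* measured curve, so when noise dominates, regional-shape
  components are discarded and per-voxel V_T shrinks toward the
  A_{i0}-scaled global mean — inflating below-mean-V_T regions and
  deflating above-mean ones.  The acceptance suite documents this on
  the noisy two-region phantom: the high-V_T region's mean is
  recovered within a few percent while the low-V_T region's mean is
  biased upward beyond 10%.  Forcing L = K removes the bias at the
  price of variance.
- **Early-time support.**  Holding curve values constant on [0, t_1)
  injects a small systematic error into the deconvolved basis near
  zero; it is visible as a boundary artifact in IRFs but contributes
  little to V_T.
- **Partial volume.**  PSF blur mixes kinetics across region
  boundaries; no partial-volume correction is attempted, and region
  means on small grids inherit the mixing.
- The spline-based deconvolution comparator and measured-data
  workflows (test–retest summaries) are out of scope.
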