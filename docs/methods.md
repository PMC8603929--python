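# Methods

## Physical model

At the Larmor frequency ω = 2πγB0 (γ = 42.577 MHz/T; 400.22 MHz at 9.4 T),
the transceive phase ϕ_tr of a spin-echo acquisition over a conductive
sample satisfies, under the standard MREPT assumptions (isotropic,
piecewise-smooth electrical properties; B1 magnitude variation negligible
against phase curvature),

    ∇·((1/σ_H) ∇ϕ_tr) = 2 μ₀ ω .

The factor 2 absorbs the transmit/receive split: transmit and receive RF
phases each contribute a μ₀ω source, and their sum is what a spin echo
measures.  ϕ_tr is never divided by two anywhere in the package.

Expanding the divergence gives the convection–reaction form solved by the
reconstruction, with an artificial diffusion term added for stability:

    −c ∇²u + ∇ϕ_tr·∇u + (∇²ϕ_tr) u = 2 μ₀ ω ,   u = 1/σ_H .

For exact data and c = 0 the two forms are algebraically identical, which
makes the phantom → forward solve → reconstruction loop self-consistent:
every accuracy number reported by the tests is a property of the
discretisation and the processing chain, not of modelling slack.

The phase-based estimate σ_H = ∇²ϕ_tr/(2μ₀ω) is the piecewise-constant
limit (∇u ≈ 0); it is exact for homogeneous media and biased at tissue
boundaries.

## Forward simulation

**Geometry.** Voxel-centred grids, index order (z, y, x), 0-based; in-plane
matrix 128×64 at 0.313 mm, slice thickness 0.3 mm.  The phantom is a list
of ellipsoidal regions rasterised in order (later regions overwrite
earlier, so nested tumor shells are listed outside-in).  Regions may extend
past the slice stack in z (a structure cut by a multi-slice acquisition)
but never in-plane.

**Tissue values.** The six-region rat-glioma phantom uses σ (S/m) /
MD (µm²/ms): contralateral cortex 0.44/0.69, tumor rim 0.96/0.81, viable
tumor 0.93/0.76, necrotic core 0.84/0.89, ventricles 0.72/1.23, edema
0.77/0.89, on a 0.5 S/m, 0.70 µm²/ms background.  Per-tissue T2 values
(40–150 ms) are simulation nuisance parameters chosen as plausible 9.4 T
magnitudes; they shape the echo-magnitude decay and therefore the echo
weights, nothing else.  The longitudinal schedule drops the necrotic core
on day 8 (not yet evident early after implantation) and grows tumor-region
conductivity linearly at 0.04 S/m/day around the day-11 values.

**Forward solve.** The divergence-form PDE is discretised per slice with a
5-point flux stencil and harmonic-mean face coefficients (standard for
discontinuous coefficients) and solved with a sparse direct factorisation.
Dirichlet boundary values default to the homogeneous-medium closed form
ϕ = a(x²+y²), 4a = 2μ₀ωσ̄, with σ̄ the slice median.  Reconstruction is
likewise per slice: slice thickness and in-plane resolution are comparable
and the acquisition is multi-slice, so the slice-normal phase derivative is
not measured reliably; a full-3D solve is not implemented.

**Coil model.** Four receive channels with Gaussian magnitude profiles
centred at the in-plane image corners.  Each channel's phase offset is
defined by a harmonic quadratic boundary trace (terms y²−x², xy, linear;
≈0.3 rad variation across the FOV, arbitrary constants) extended into the
interior by solving the source-free equation ∇·((1/σ)∇ψ)=0.  This is the
physically consistent choice: a receive field's phase propagates through
the same conductive sample, so the offset retained after referenceless
combination (the reference channel's own ψ) leaves ϕ_tr + ψ an exact
solution of the transceive model.  Larger or non-physical offsets degrade
reconstruction through the convection term — the transceive-assumption
error that real acquisitions also carry.

**Noise.** I.i.d. complex Gaussian per channel/echo/voxel, seeded; DWI
noise is added on complex channels before the magnitude is taken (Rician).
All randomness flows from one root `numpy.random.SeedSequence`, split per
day and then per stage (acquisition, DWI), so pipeline outputs are
hash-reproducible.

## Phase processing

**Channel combination** (two-step, referenceless): the channel with the
highest mean magnitude is the reference; each channel's offset is estimated
as the phase of the Gaussian-low-passed product ch·conj(ref), accumulated
over echoes (spin-echo phase is TE-independent, echoes only add SNR);
offsets are subtracted and the channels summed with magnitude² weighting.
The smoothing radius (default 3 voxels) trades offset-estimation noise
against a residue that the low-pass leaves around tissue interfaces where
the offset fields kink; noiseless data are best served by radius 1.  The
filter also distorts a band of ≈2 radii along the image edge, so the
pipeline insets its solve domain by `2·radius + 2` voxels.

**Unwrapping.** A quality-guided unwrapper provides the continuous
estimate; the result is snapped to the congruent lattice: output = input +
2π·k with k an integer grid stored on the map.  Bitwise congruence cannot
be achieved by float arithmetic alone (x + 2πk − 2πk ≠ x in IEEE754), so
the wrapped original and the wrap counts are part of the unwrapped
representation and `rewrap()` is exact by construction.  Disconnected mask
components are unwrapped independently, each with its own 2π·k ambiguity —
harmless, because only phase derivatives enter the reconstruction; no
global anchoring is performed.

**Echo averaging.** Weights wₙ = Mₙ²/Σₖ Mₖ² per voxel, the phase-noise
optimal weighting for complex Gaussian noise under T2 decay; echoes are
unwrapped slice-wise and aligned to echo 1 modulo 2π before averaging.
Voxels with zero total magnitude are masked.

## Reconstruction numerics

* Derivatives: central differences (exact for quadratics), or separable
  Savitzky–Golay (order 2, radius default 4) for noisy data — the Laplacian
  amplifies voxel-scale phase noise by ~1/h² ≈ 10⁷ m⁻², so a smoothing
  derivative kernel is required at realistic SNR.  Voxels whose kernel
  touches the mask are flagged invalid.
* Stabilisation c: `auto` uses the global c = ½·h·max|∇ϕ_tr|; `local`
  (pipeline default) uses the voxelwise c = ½·h·|∇ϕ_tr|, equivalent to a
  locally upwinded scheme — it stabilises convection-dominated voxels
  without blurring regions where the phase is flat, which the global rule
  does (the FOV-corner gradient maximum would otherwise set the smoothing
  everywhere).  `fixed` exposes c directly.
* Convection is centrally differenced, switching to first-order upwind
  where the per-axis mesh Péclet |∂ϕ|·h/c exceeds 2.
* Dirichlet boundary for u on the outermost ring of the derivative-valid
  domain, from a 3×3-median-filtered phase-based estimate (invalid voxels
  filled from their nearest valid neighbour, clipped to [0.05, 10] S/m
  before inversion); user-overridable.
* The reported residual is the discrete stencil applied to the solution
  (Dirichlet values in place), summed over solved voxels — reproducible by
  an independent implementation of the written scheme.
* σ = 1/u; values outside (0, 10) S/m are masked with a warning, never
  clipped.  `erode_and_mask` removes voxels within a chosen distance of any
  VOI boundary to counter reconstruction blurring (default 1 voxel in the
  pipeline; more erosion empties the thin tumor rim).

## Diffusion

Log-linear least-squares tensor fit, ln S = ln S₀ − b gᵀDg, all shells in
one mono-exponential fit (no kurtosis term); b in s/mm² is rescaled by
10⁻³ so D comes out in µm²/ms.  Voxels with non-positive signal are
excluded; a rank-deficient design (fewer than 6 independent directions plus
b=0) is rejected with a diagnostic.  MD = trace(D)/3.  The default
direction set is 15 unit vectors spread by seeded electrostatic repulsion
with antipodal symmetry.

## Statistics

Per-VOI mean/sd (n−1)/median over valid voxels; Welch's unequal-variance
two-tailed t-test with Welch–Satterthwaite degrees of freedom for
cross-region and cross-day comparisons (pooled-variance testing was
deliberately not chosen; both zero-variance edge cases are handled by
convention); Pearson's r with the t-distributed two-sided p for the MD–σ
association, pooling matched per-region samples.  Raw p-values are
reported; Holm correction is available but off by default.

## What the synthetic data do and do not show

The generator reproduces the geometry, contrast structure, acquisition
constants (TR/TE schedule, matrix, b-values, directions) and noise
character of a 9.4 T rat glioma study, and the forward model is exactly
the equation the reconstruction inverts.  It does not include: B1-magnitude
inhomogeneity, motion or pulsation, susceptibility or eddy-current phase,
EPI distortion in the DWI, partial-volume mixtures, or anatomically
realistic shapes.  Passing tests therefore demonstrate correctness of the
processing chain and its noise behaviour under the stated model — not
in vivo accuracy, where the transceive assumption, coil-combination
residues and boundary blurring are all larger.

Known limitations measured on the default phantom: small high-contrast
regions (ventricles) reconstruct ~10–20 % low because boundary blurring
leaks the background value in; the thin tumor rim survives only mild
erosion; at noise levels several times the default (per-component SD 0.005+
on a ~unit signal) the phase-based Dirichlet estimates degrade and
reconstruction becomes unreliable — region ordering is preserved long
before absolute accuracy is.

## Problem sizes

Tests and the acceptance script run on one slice of the 128×64 grid (or
smaller analytic grids), 50–100 seeded replicates for Monte-Carlo checks,
and 10 000 replicates for the t-test calibration; these sizes were chosen
so the full suite completes in about a minute while keeping every
Monte-Carlo margin wide.
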