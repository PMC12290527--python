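# Methods

This note documents the models, parameter choices and numerical
conventions of the toolkit, what the synthetic phantom does and does not
emulate, and where genuinely open design choices were decided.

## Trajectory design

The variable-density spiral is the geometric curve
`k(τ) = k_max · τ^α · e^{i 2π n τ}`, τ ∈ [0, 1], with turn count
`n = N / (2 r_xy)` for matrix size `N = FOV/Δx`. At α = 1 this is the
uniform Archimedean spiral with N/2 revolutions per interleave and exact
edge undersampling `r_xy`; for α > 1 the same turns are redistributed
toward the k-space center, so the center stays Nyquist-oversampled while
the edge spacing grows to `α·r_xy / FOV`. The literature offers several
variable-density conventions; this fixed-turn-count one is adopted because
it reproduces the uniform closed form and, with the 7T protocol values
(FOV 192 mm, 0.8 mm, α = 1.6, r_xy = 3, 35 mT/m, 155 T/m/s, 2 µs dwell),
a 47 ms single-shot readout — within the ~10% spread that separates
published spiral-design tools for the same protocol. A consequence worth
knowing: with fixed `n`, raising α *shortens* the readout (shorter arc),
and a "fully sampled" design in the strict Nyquist sense requires α = 1.

Time-optimal traversal is computed by the standard arc-length
forward-backward sweep: the speed along the curve is capped by the
gradient limit `v ≤ γG_max` and the curvature limit `v ≤ √(γS_max/κ)`,
and the tangential acceleration budget `√((γS_max)² − κ²v⁴)` is enforced
in a forward (acceleration) and backward (deceleration) pass. Gradients
are emitted as forward differences on a 10 µs raster so that cumulative
integration reproduces `k` exactly at the raster nodes; slew feasibility
is verified numerically with a 1% discretization allowance.

The EPI trajectory exists for the PSF comparison and the acoustic
spectrum audit only: `partial_fourier · N / grappa` phase-encode lines
spaced by the echo spacing, unsampled lines zero-filled downstream; no
k-space interpolation (GRAPPA) kernel is implemented.

## Phantom and VASO signal model

The digital object is a cylindrical slab: CSF rim, gray-matter ribbon
split into L equidistant layers (default 5 at the default 32×32 matrix,
deep = layer 0), white-matter core. Default tissue values are
field-strength-typical assumptions, not measured constants: T1 = 1.9 /
1.2 / 4.3 / 2.1 s (GM/WM/CSF/blood), T2* = 25 / 22 / 60 ms, m0 = 0.8 /
0.65 / 1.0. The B0 map is a low-order random polynomial scaled to a
30 Hz peak plus Gaussian susceptibility foci (±60 Hz, σ ≈ 2.5 voxels);
coil sensitivities are analytic Gaussian lobes with smooth phase ramps,
normalized to unit sum-of-squares so that SENSE magnitudes compare
directly to m0.

Inversion recovery uses an ideal instantaneous inversion with efficiency
0.95 repeated every TR_effective (3.948 s); the blood-nulling TI is
computed from the steady-state zero crossing of blood magnetization
(≈1.12 s with these defaults) rather than taken from a printed protocol
value, because the protocol's underlying T1/efficiency assumptions are
not published; a configured TI that misses the null by > 1% of m0
triggers a warning with the residual. Activation multiplies resting CBV
(5% GM, 1% WM) by `1 + ΔCBV·active(t)` inside an angular sector of the
ribbon, with ΔCBV peaking mid-ribbon (microvasculature) and the BOLD
weighting ramping toward the superficial layers and CSF (draining veins).
Both volumes of a pair share the multiplicative BOLD factor, scaled
linearly with TE; this is exactly the structure the dynamic-division
correction assumes, so the BOCO test is a genuine identity check, not a
tautology (the correction operates on reconstructed, noisy, interpolated
series).

What the generator does **not** emulate: vascular anatomy, arterial
transit/CBF dynamics, motion (the data are motion-free by construction),
physiological noise (thermal complex Gaussian k-space noise only, default
2% of the blood-nulled series RMS — voxel tSNR is therefore higher and
purely thermal compared with in vivo), partial-volume mixtures at tissue
boundaries, and B1+ inhomogeneity. Passing tests demonstrate that the
algorithms invert the stated model, not that they are robust to effects
the model omits.

## Forward model and reconstruction

The encoding operator applies, per time segment, a static phase image
`e^{-z(r)·τ_l}` (complex rate `z = i2πf₀ + 1/T2*` when decay is modeled),
coil weighting, an FFT along the fully sampled kz direction, and a 2D
Kaiser-Bessel gridding NUFFT per partition (oversampling 2.0, width 6,
Beatty shape parameter; accuracy ~1e-6 against the dense DFT). The
interpolation matrix is stored sparsely, so the adjoint is the exact
conjugate transpose and inner-product tests pass at machine accuracy.
The brute-force DFT encoder (exact per-sample off-resonance phase) is
retained as the oracle and is used to generate test data independently of
the fast path.

Temporal interpolation across segments defaults to constrained
least-squares coefficients fitted to the histogram of rates present in
the object, with the row-sum-to-one constraint (exact fidelity at z = 0).
The classical Hanning interpolator is available but needs several times
more segments for the same error: at L = 24 over a 53 ms readout with
|f₀| ≤ 100 Hz the LS interpolator reaches ~2e-5 relative error where
Hanning sits near 1e-1. Segment centers are uniform over
[TE, TE + readout].

Density compensation: Pipe-Menon fixed point `w ← w/(C Cᴴ w)` with the
gridding kernel (30 iterations), or Voronoi cell areas with unbounded
edge cells capped at the largest bounded area; weights normalized to the
Nyquist sample count of the covered region (disk π/4·N² for spirals).

Solvers: CG on the normal equations (the objective is tracked by the CG
recurrence, so logging costs no extra operator applications and is
monotone by construction), and ADMM with identity sparsifying transform,
inner CG x-updates and soft-threshold shrinkage. β defaults to 0 in the
desk-scale configuration — at 2× in-plane undersampling with 6 coils the
SENSE system is well conditioned — and to a data-scaled heuristic
(`1e-3·max|Eᴴs|`) otherwise. On problems with a null space (any disk
acquisition leaves the square-grid corner frequencies unencoded) CG and
ADMM legitimately pick different minimizers; equivalence as β → 0 holds
on fully sampled Cartesian problems and is tested there.

## PSF and effective resolution

The point-source response is simulated by evaluating the decayed data
`e^{-t/T2*}` on the trajectory and applying the density-compensated
adjoint NUFFT. FWHM is measured on exact direct-DFT line profiles through
the PSF peak (1/32-pixel steps; grid images are too coarsely sampled at
~1.2 px lobes), averaged over x and y. Effective resolution is
`nominal · FWHM/FWHM_ideal` with the ideal taken from the same pipeline
on a fully sampled design of the same geometry without decay. Under this
convention the protocol spiral broadens isotropically to 1.875 px
(1.50 mm effective at 0.8 mm nominal) while the zero-filled
partial-Fourier EPI broadens only along phase encode (2.02 px); averaged
over axes the spiral comes out ~2% *better* than the EPI model. A
vendor-style homodyne partial-Fourier completion — out of scope here —
would narrow the EPI PSF and flip that comparison; the spiral-side
number is the robust one.

## Corrections

All three raw-data corrections are pure per-sample phase factors and
preserve magnitudes exactly. Eddy-current compensation phase and the k0
trace are treated as known inputs (stored alongside the data in the raw
container, as they would arrive from simulation or a field camera).
Repetition-DORK estimates one global frequency per volume from the FID
navigators (8 samples at k = 0 before the readout) via the
magnitude-weighted coil inner product against the first volume of the
scan — separately per contrast, because the blood-nulled and BOLD-weighted
volumes have different image content and hence different intrinsic
navigator phase. Offsets are assumed within (−π, π] per volume; a jump
> π/2 between successive volumes triggers a wrap warning. Within-volume
drift is not corrected.

## Analysis

Temporal upsampling uses linear interpolation at the true acquisition
offsets of the pair (VASO at the pair start, BOLD one TR_volume later)
onto the union grid, doubling the volume count; the BOCO division floors
the BOLD series at 1e-6 of its maximum. The high-pass filter is a
Gaussian-weighted running-line fit (trend removed, mean re-added) with
FWHM equal to one rest+activity cycle — that reading of "block duration"
attenuates the block amplitude < 10% while suppressing linear drift; the
single-block reading halves the cycle and costs ~40% of the signal. The
GLM uses a demeaned boxcar, intercept and linear drift column; t maps are
converted to z through the exact Student-t tail and sign-adjusted
(contrast −1 for VASO). Clustering is 6-connected with a 5-voxel minimum.
ROC specificity counts post-clustering suprathreshold fractions in GM
(true positives) and WM (false positives) within the stimulated-sector
ROI — restricting to the sector mirrors ROI-based specificity analyses
and is necessary for the curve to span [0, 1]; AUC is the trapezoid over
the false-positive axis with the curve closed at (0,0) and (1,1).

## Problem sizes

The default experiment runs at a 32×32×8 matrix (6 mm in-plane, same
192 mm FOV), 6 coils, r_xy = 2, 8 partitions, with the full 10-block
paradigm (160 VASO+BOLD pairs). The spatial scale-down keeps the in-plane
readout short, so the off-resonance machinery is exercised separately on
a weak-gradient spiral whose 16×16 readout is stretched to ~53 ms —
matching the phase accrual of the full-resolution acquisition — and the
oracle-based operator tests run at 16×16 to keep the brute-force DFT
tractable. PSF comparisons run at the full 240 matrix.

## Known limitations

- The spiral turn-count convention is one of several in use; readout
  durations of external design tools can differ by ~10% for identical
  constraints.
- No homodyne/POCS partial-Fourier completion for the EPI arm; its PSF is
  the zero-filled one.
- No ESPIRiT backend; sensitivities come from the smoothed-ratio
  estimator (adequate for the analytic phantom coils; eigen-method
  robustness on real multi-channel data is untested).
- Field-map estimation unwraps only temporally; spatial unwrapping for
  fields beyond ±1/(2ΔTE) is not implemented (such voxels are flagged).
- DORK corrects a single frequency per volume; higher-order dynamic
  fields and within-readout drift are out of scope.
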