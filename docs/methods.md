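# Methods

This note records the models, conventions and design choices behind
`widif`, in the spirit of a methods appendix: what is simulated, what
is assumed, and where the genuinely open choices were made.

## Coordinate and unit conventions

Images are kept in a canonical voxel order with the third axis axial
and the inferior (neck) end at index 0; `image_io.read_dynamic`
reorients arbitrary NIfTI orientations via the closest-canonical (RAS)
transform, which makes "the bottom third of the field of view" well
defined.  All activity concentrations are Bq/ml, all times seconds.
Flow F and clearance k₂ are carried per-minute externally
(ml/cm³/min, 1/min) and per-second internally.  Frame timing lives in
a JSON sidecar (`frame_start_s`, `frame_duration_s`) since NIfTI-1 has
no standard per-frame timing; TACs are stamped at frame mid-times
(start + duration/2) — the mid-time convention is an assumption, as
frame-sampled data do not dictate one.

## The arterial input model

The simulated arterial curve is a peak-normalised gamma variate with a
recirculation tail:

    C_a(t) = A·x^s·exp(s(1−x)) + f·A·(1−e^{−(t−t0)/θ})·e^{−λ(t−t0)},
    x = (t−t0)/(s·θ),  t > t0

with amplitude A (default 50 kBq/ml), appearance time t0 = 10 s, shape
s = 3, scale θ = 5 s (peak exactly A at t0 + s·θ = 25 s, i.e. 20–30 s
post-injection as seen after a 10-ml bolus at 1 ml/s with a saline
flush), tail fraction f = 0.15 and tail decay λ = 0.004 s⁻¹.  The
closed-form full-bolus area is A·θ·e^s·s^{−s}·Γ(s+1), which the tests
use as an oracle.  Real measured curves vary in all of these; the
defaults were chosen once for a realistic peak-to-tail ratio and are
configurable.

## Phantoms

**Dynamic phantom.** Two carotid-like tubes (default 5.5 mm diameter,
24 mm apart, running through the neck portion of the grid) carry
C_a(t); a brain ellipsoid in the upper field of view has a grey-matter
shell (F = 0.64 ml/cm³/min, V_d = 0.9 ml/cm³ — flow matching typical
baseline grey-matter values, V_d a physiological choice since tissue
water distribution volumes are not otherwise pinned down here) and a
white-matter core (F = 0.20, V_d = 0.8); low-flow neck soft tissue
(F = 0.05, muscle-like) surrounds the tubes so that spill-in is
non-trivial.  Default grid 96 × 96 × 48 at the clinical voxel size
0.98 × 0.98 × 2.79 mm — the matrix is cropped relative to a full
256 × 256 × 71 scanner matrix purely to keep the phantom compact; the
voxel geometry is untouched.  The acquisition uses the 26-frame
variable-duration schedule (8×5, 4×10, 1×15, 4×20, 2×30, 7×60 s;
655 s).

Image formation: tissue responses are computed by exact
piecewise-linear convolution on a 0.5-s grid, averaged over frame
intervals, mixed through the component maps, and blurred with a
separable Gaussian PSF (default 2.3 mm FWHM, slightly below a
2.6-mm capillary-derived resolution estimate because such estimates
overstate the true width).  The tube boundary is handled in continuous
space: the analytic indicator is supersampled 8× per in-plane axis,
blurred at sub-voxel resolution, then averaged back to the grid.
Because blurring and frame averaging are both linear they commute, and
the per-component formulation is exactly equivalent to blurring every
frame.  Noise is zero-mean Gaussian with SD = `noise_scale` ·
sqrt(max(value,0)/duration) — a frame-duration statistics proxy for
reconstructed-image noise, which is approximately Gaussian with
variance inversely proportional to counts.  `noise_scale = 30`
(calibrated qualitatively: ~4% jitter on early carotid-voxel frames)
is the default; no published noise figure exists for these
reconstructions, so this is a realism judgement, not a measurement.
What the phantom does **not** emulate: sinogram-level physics (scatter,
randoms, attenuation), reconstruction nonlinearity and its spatially
varying resolution, motion, and decay.  Passing tests therefore
demonstrate the correctness and self-consistency of the analysis chain
under a stationary-Gaussian-PSF image model, not robustness to scanner
physics.

**Static phantom.** A 6-mm tube at 2.1 MBq/ml inside a zero-activity
20-cm water cylinder, tube parallel to the axial axis.  The tube spans
the whole (24-slice) sub-grid; with the replicate boundary used by all
smoothing operations this is equivalent to analysing the central
portion of a longer tube.  Objects are centred on a voxel centre: on a
~1-mm grid the 42%-threshold mask of a 6-mm tube changes by ±2
voxels/slice with sub-voxel object placement (a discretisation
property of any threshold mask, worth knowing when comparing to
physical phantoms), and the voxel-centred placement is the canonical
symmetric geometry.

## Segmentation

Reference intensity = median (even count: mean of the two central
values) over axial slices of the per-slice maximum *within the user
VOI* — restricting maxima to the VOI is more robust to other hot
structures than whole-slice maxima, which the workflow leaves
ambiguous.  Early-frame averaging is unweighted; for the 5-s early
frames this equals duration weighting.  Thresholding uses strict `>`
(ties excluded — only relevant for degenerate synthetic inputs).  The
choice of early frames is an operator input, as in the manual
workflow; `suggest_early_frames` is an advisory heuristic (frames
before the whole-image activity peak whose within-neck maximum exceeds
20% of the early-frame maximum) because "carotids visually
distinguishable, little brain signal" cannot be encoded.  No
connected-component filtering by default; a minimum-component-size
flag exists for noisy data.

## Partial-volume correction

α and β are computed with a separable Gaussian (σ = FWHM/2.3548 per
axis in voxel units, kernel truncated at 4σ) in replicate
("nearest") boundary mode.  Replicate mode preserves constants, which
makes the complementarity α + β = 1 exact (G(M) + G(1−M) = G(1) = 1);
zero padding would bias α near image edges.  Factors are computed on
the full grid — for interior carotids there are no boundary effects.
The sleeve is `dilate(M, 10) \ dilate(M, 8)` with 6-connected
(face-neighbour) unit dilations counted in voxels; in millimetres this
shell is anisotropic (~7.8 mm in-plane, ~22 mm axially), which is
accepted because the background is smooth at that distance.
Connectivity is configurable (6/18/26); counts differ by connectivity
but the sleeve TAC is insensitive for smooth backgrounds.  The same
kernel is used for α, β and the correction, whose defining
self-consistency is: if the measured image is exactly
C_B·G(M) + C_T·G(1−M), then (C_B^PET − β·C_T)/α returns C_B at every
time point (tested to 1e-6).  Corrected curves may go negative under
noise; a negative early AUC triggers a warning rather than an error.

## Blood-curve conditioning

Calibration multiplies by the mean of per-sample ratios (typically two
late samples; a regression would be overkill for n = 2).  Dispersion is
the monoexponential model — measured = true ⊗ (1/τ)e^{−t/τ}, τ = 13 s
(8 s tubing + 5 s body) — inverted in derivative form
c + τ·dc/dt, with a 3-sample moving-average pre-smooth before the
central difference because the τ·dc/dt term amplifies sampler noise at
the 1-s readout. The round trip (disperse, then correct) recovers the
0–60 s AUC of a bolus to better than 2%.  Delay is estimated by grid
search (−5…+15 s, 0.5-s steps) minimising the squared difference
between peak-normalised curves over the first minute; positive delay
means later arrival at the sampler, and the curve is shifted earlier.
IDIFs receive no delay/dispersion correction — they are measured at
the target vasculature.

## Kinetics

The basis-function solution of dC_T/dt = F·C_a − k₂·C_T precomputes
B_i = C_a ⊗ e^{−k₂ᵢt} on a fine grid (exact for the piecewise-linear
interpolant, including k₂ = 0 as the running integral), frame-averages
it, and solves a one-parameter weighted least-squares fit per k₂,
keeping the minimiser.  Defaults, declared rather than inherited from
any reference implementation: 100 log-spaced k₂ in [0.01, 3] min⁻¹
(≈6% spacing, covering F 0.1–2 and V_d 0.3–1.2; noise-free recovery
over F ∈ [0.2, 1.2], V_d ∈ [0.4, 1.2] is ≤2% in F — the residual set
by grid density), frame-duration weights, fit window = frames with
mid-time ≤ 300 s (flow information in water scans is early), no
arterial blood-volume term (single-tissue model only; an extension
point, not implemented).  Negative fitted F is clamped to zero and
flagged.  The voxelwise fit shares one basis set and solves all voxels
per k₂ in closed form.

## Evaluation

AUC windows are 0–60 s (peak) and 60–300 s (tail), trapezoidal on the
linear interpolant with interpolated endpoints; frame-sampled curves
get a (0, 0) origin sample prepended, since the pre-bolus activity is
zero and the first frame mid-time is 2.5 s.  The grid search sweeps
thresholds 38–46% (1% steps) × kernels 2.0–2.4 mm (0.1-mm steps) —
step sizes chosen to give the conventional table granularity — and
re-runs segmentation → PVC → IDIF → GM CBF per cell; empty-mask cells
are NaN and the sweep continues.  Deming regression uses variance
ratio 1 (orthogonal) in closed form; sample SD (n−1) throughout;
Bland–Altman percent differences use the pairwise mean as denominator.
The CoV of paired differences defaults to the SD of pairwise
percentage differences (already normalised); the absolute variant
(100·SD(y−x)/grand mean) is available via `percent=False` — the two
agree to first order for small differences.

## Numerical notes and degenerate inputs

Exponential convolution uses the per-segment closed form with an
explicit k → 0 limit (plain trapezoid), so no step-size tuning is
involved.  Gaussian kernels follow the sampled-and-normalised
convention with radius ⌊4σ + 0.5⌋; truncation affects α below 1e-6.
Empty masks, all-zero VOIs, non-covering curves, overlapping frames and
NaN volumes raise `ValueError` early; frame-count mismatches between
image and sidecar raise a schema error.  All randomness flows from a
single integer seed through `numpy.random.default_rng`; analysis stages
are deterministic.

## Known limitations

The image model is a stationary, isotropic-in-plane Gaussian PSF; real
penalised-likelihood reconstructions have object-dependent resolution
and correlated noise, so phantom biases here bound method-intrinsic
error only.  The 42%-threshold mask of near-resolution vessels is
sensitive to sub-voxel object placement (see above).  The sleeve
assumes surrounding tissue is homogeneous at 8–10 voxels from the
carotid; sharp tissue gradients there would bias the spill-in term.
Delay estimation is curve alignment, not a joint kinetic fit.  No
motion, no metabolite or haematocrit handling (not needed for
¹⁵O-water), no atlas parcellation or spatial normalisation.
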