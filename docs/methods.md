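# Methods

This note documents the models, conventions and numerical choices behind
`kinemagree`, in the order data flows through the package.

## Containers and conventions

Positions are millimetres, times seconds, angles degrees; unit conversions
happen only at I/O boundaries (e.g. metre-unit TRC files). The canonical
joint set is head, shoulders, elbows, wrists, hips, knees, ankles, feet, plus
an optional whole-body centre of mass (CoM). A recording carries a per-frame
validity mask — "body detected" or not. Invalid frames are masked throughout:
no parameter value is ever produced from, or interpolated across, unobserved
data, with one deliberate exception (below). The world frame is right-handed
with the vertical axis opposing gravity.

## Comparing a 120 Hz stream with a 30 Hz stream

The two systems record on different grids, and the comparison needs a common
one. The reference stream is resampled onto the *test* stream's timestamps by
per-axis linear interpolation; downsampling the clean stream avoids
fabricating high-frequency content in the noisy one. Interpolation is allowed
to bridge invalid source frames (it uses the nearest valid neighbours), but a
resampled frame is only reported *valid* when both immediately bracketing
source frames were valid — the one place where values exist across a gap,
they are flagged so downstream statistics still exclude them. No
extrapolation: targets outside the source span are an error. Peak and
smoothness parameters are computed per system on its own native grid, since
they do not require frame-wise pairing.

## Rigid alignment and body axes

The test system reports positions in its own camera frame. A proper rigid
transform (Kabsch, SVD-based, reflections excluded) maps it into the
reference world, estimated from per-joint mean positions over the standing
window that precedes each movement (every joint is static there, so the
means are noise-averaged, well-spread 3D correspondences).

Body axes are built from the reference recording's standing window: vertical
opposes gravity; medio-lateral is the mean right-to-left shoulder direction
orthogonalised against vertical; anterio-posterior completes the
right-handed triad; the origin is the mean mid-hip point. The reference
system's world is taken as floor-calibrated (gravity = its −z axis), as is
standard for marker-based laboratory systems. A general least-squares ground
plane estimator from foot-joint positions is provided (and used where foot
positions span the floor), but the pipeline's per-recording ground plane is
the plane through the mean standing foot position orthogonal to the
calibrated vertical: during quiet standing the feet supply only two distinct
contact points, which cannot determine a plane orientation — fitting one
anyway would let sensor noise pick the normal.

## Motion parameters

* **Three-point angles** (elbow, knee, ankle, hip): the angle at the middle
  joint between the rays to its neighbours, computed with atan2 of
  cross/dot for stability near 0° and 180°. Identical for every system by
  construction.
* **Trunk rotation**: unsigned angle between the hip line and the shoulder
  line after projection onto the horizontal plane.
* **Displacements** (CoM weight shift, upper-trunk excursion): relative to
  the mean position over the pre-movement baseline window, reported in
  medio-lateral / vertical / anterio-posterior components. The CoM is the
  recorded CoM channel when the system provides one, otherwise a fixed-weight
  joint average (weights inspired by standard segment-mass tables; only
  relative geometry matters for displacement).
* **Speeds**: magnitude of the finite-difference velocity (central
  differences inside runs of valid frames, one-sided at series ends); frames
  bordering a dropout gap are invalidated because their derivative would
  straddle unobserved data.
* **Peaks**: extremum of the relevant series inside the annotated movement
  window; ties broken by the earliest frame. Maximum reach distance is the
  signed wrist excursion beyond the sagittal plane through the start-window
  mid-shoulder point, positive across the body midline. Maximum trunk angles
  project the mid-hip→mid-shoulder axis onto the frontal (lateral bends) or
  sagittal (ventral/dorsal) plane before measuring against vertical; the
  window confines each bend direction, so unsigned angles suffice. Jump
  height is the maximum perpendicular ankle-to-ground-plane distance over
  both ankles. The squat is scored by the knee angle at peak flexion, i.e.
  the minimum of the hip–knee–ankle angle over the movement.

No smoothing or filtering is applied before any parameter computation.

## SPARC smoothness

Modified spectral arc length of the movement-window speed profile: magnitude
spectrum by zero-padded FFT (padding exponent 4), normalized by its DC value;
adaptive cutoff at the end of the band where the normalized magnitude stays
above 0.05, capped at 10 Hz; the result is the negative arc length of the
spectrum over [0, ω_c] with the frequency axis normalized by ω_c. These are
the reference defaults of the metric, and all three are configurable because
published validity analyses do not always state their settings — absolute
SPARC values are therefore comparable only within one configuration.
Rhythmic movements (jumping jacks) are scored per repetition, using the
annotated repetition boundaries, and averaged; other tasks use the full
annotated movement window. A window containing any invalid frame is rejected
for SPARC (no gap-filling) and the recording is logged as excluded for that
parameter.

## Agreement statistics

Differences are oriented test − reference (the bias sign flips with this
choice; MAE, SDs and r do not). Sample SDs use the n−1 denominator. Limits
of agreement are bias ± 1.96·SD of differences. The bias p-value is a
two-sided one-sample t-test of the differences against zero; with zero
difference variance the test is degenerate and p is reported as 0 (nonzero
bias) or 1 (all differences zero) with a flag. Per-participant correlations
are aggregated by plain mean and SD — no Fisher-z transform, matching how
validity studies conventionally report the average r. p-values are
unadjusted for multiple testing.

## The synthetic study

The generator emulates the study conditions the pipeline is designed for:
23 participants with statures drawn uniformly from 110–189 cm, five tasks, a
120 Hz reference stream with 0.5 mm per-axis noise, and a 30 Hz test stream
with 7.3 mm per-axis noise — chosen so the mean 3D joint-position error,
σ·2·√(2/π) for isotropic Gaussian noise, is ≈11.7 mm, the test method's
reported position error — plus rare dropouts (p = 0.002/frame) and limb-jump
artifacts (p = 0.001/frame, 150 mm, 0.25 s, one limb displaced coherently),
the characteristic failure mode of consumer body trackers. The test camera
is yawed and offset so the rigid-alignment stage is exercised on every run.

Choreography: a stick-figure skeleton scaled from stature by fixed
anthropometric ratios (shoulder height 0.818·stature, hip 0.530, knee 0.285,
ankle 0.039, …) moves between key poses along minimum-jerk segments
(position profile 10τ³ − 15τ⁴ + 6τ⁵), giving C²-continuous trajectories with
zero velocity at key poses. Key poses sit on a 0.1 s grid so the internal
240 Hz sampling and both observation grids hit every pose extreme exactly:
programmed peaks (reach excursion 300 mm, trunk bend amplitudes
25/25/30/15°, squat peak-flexion knee angle 90°, jump apex 150 mm above
standing ankle height) are attained, not approached, on every grid, which is
what makes exact ground-truth recovery checks meaningful. The squat solves
the shank tilt for the programmed knee angle by root-finding on the
closed-form leg geometry; small lateral/forward torso coupling is added so
every displacement component carries signal. Task parameters without a
stated value in the emulated protocol (reach height, bend amplitudes, leg
raise 40° with a 3 s hold, weight shift 60 mm) were fixed once at values a
physiotherapist would call typical for these assessment tasks.

All randomness flows through one seeded generator (per-recording child
seeds from a SeedSequence); identical config + seed is bit-identical.
Standard-normal draws are made independently of the noise SD, so runs
differing only in SD share the same underlying noise — noise-ladder
comparisons are coupled, not re-randomised.

### What the generator does and does not emulate

It reproduces the *structure* of real paired recordings: two rates, two
noise scales, camera misalignment, task choreography with annotations,
dropout and limb-loss artifacts, anthropometric variation. It does not
attempt biomechanical validity (no joint-torque, balance or soft-tissue
modelling; limbs may violate rigid-body constraints during jumps), marker
occlusion patterns, or the autocorrelated, pose-dependent error structure of
real markerless trackers (noise here is i.i.d.). Passing tests therefore
demonstrate that the *analysis chain* is correct and well-behaved under
known conditions, not that any particular tracker is valid on real data; on
real recordings the agreement numbers themselves will differ.

## Problem sizes and numerical choices

The end-to-end identity checks run the full 23 × 5 study (a few seconds);
property checks use the smallest sizes that make their statistics sharp
(10⁵ draws for LoA coverage and bias/LoA recovery; 12 participants × 2 tasks
per rung of the 5-rung noise ladder). Tolerances: axes orthonormal to 1e-9;
angle/Pearson/Bland-Altman oracle agreement to 1e-9; SPARC oracle agreement
to 1e-6; ground-truth recovery to 0.1° / 0.5 mm; zero-noise correlations to
1e-6 of unity. Degenerate inputs (collinear alignment points, constant
series, all-zero speed profiles, empty windows) raise errors that the
pipeline converts into logged exclusions rather than aborting the study.

## Known limitations

* Annotations carry movement start/end and repetition boundaries only; the
  finer sub-movement windows a human rater might mark (e.g. onset to peak
  reach) are approximated by the full movement window for smoothness.
* Only the right-side limb parameters are scored for bilateral tasks; the
  choreography is left-right symmetric, so this loses no generality in the
  synthetic setting.
* The CoM fallback weights are a fixed table, not participant-specific
  segment masses.
* File input assumes recordings already share a gravity-aligned reference
  world (after the built-in rigid alignment of the test stream).
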