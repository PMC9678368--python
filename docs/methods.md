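# Methods

This note documents the models, conventions and numerical choices behind
`larvatrack`, what the synthetic scenes do and do not emulate, and the
decisions taken where the underlying system left the design open.

## Coordinate and unit conventions

All world coordinates are in mm with y increasing downward (image
convention); pixel coordinates are 0-based pixel centres. With the camera
above the plate, a bend of the head toward the animal's **left**
corresponds to a positive z-component of the cross product
direction_vector × direction_head_vector, and the `asymmetry` feature is
signed accordingly (left positive). Times are seconds from run start;
frames arrive at 20 Hz (Δt = 0.05 s), the control loop runs at the same
50 ms cadence.

## Synthetic scene

**Body model.** Each larva is an 11-point spine with a tapered half-width
profile, rendered as the filled offset polygon of the spine with rounded
end caps. The default body is 2.3 mm long with a 0.36 mm peak half-width.
Two constraints pin this down: (i) the rendered bounding box must stay
inside the detection stage's default 300–900 px² window at 72.92 µm/px in
*every* orientation and pose (measured range 360–841 px²), and (ii) the
traced contour must stay above the 63-point acceptance minimum. A real
third instar is longer; the box-area window, taken literally as box
width × height, forces this smaller stated body, and all downstream
defaults are calibrated to it. The anterior is drawn as a narrow,
near-cylindrical snout with a small end cap: this concentrates a full
half-turn of contour curvature at the head, so the curvature-based
head/tail detector identifies the head robustly both on exact geometry
and at pixel scale, while the blunt tail spreads its half-turn over a
much longer cap arc.

**Kinematics.** Poses are built analytically from a tail anchor and
heading: peristaltic crawling advances the tail anchor at
0.7 mm/s × (1 + 0.9 sin 2πφ) with the phase φ advancing at 1 Hz; bends
rotate the five anterior segments progressively about the neck
(default amplitude 60°, ramp 0.4 s); balls curl the body at 0.95 of a
full circle with a 0.90 body contraction (closing the C-gap into a
disc); rolls hold a C-shape (0.55 curl) while translating laterally at
1.4 mm/s; back-up reverses the wave at 0.6× speed. Per-frame
displacement is clamped to 1.5 mm/s. Plate-edge encounters rotate the
heading toward the plate centre at ≤0.12 rad/frame so poses stay
kinematically continuous. Behaviour is driven either by an explicit
script or by a dwell-time random walk (crawl runs of 2–6 s punctuated by
0.8–2.5 s head sweeps and 0.5–2 s pauses).

**Stimulus response.** A `ResponseModel` maps (light, temperature) to a
per-frame roll probability. The published record does not quantify the
dose–response of rolling; the defaults (0.05/frame above 50 µW/cm² or
28 ℃, stop probability 0.10/frame, 1 s refractory period) are free
simulator knobs chosen so a sustained 5 s stimulus triggers at least one
roll in >90% of responder agents. Control genotypes are modelled by
leaving the response flags off.

**Heating plant.** dT/dt = k₁·I − k₂·(T − T_ambient) with k₁ = 0.08 ℃/(s·%),
k₂ = 0.5 s⁻¹, ambient 22 ℃, integrated with the exact exponential update
(unconditionally stable, monotone). With the sigmoid controller in the
loop, a 22→30 ℃ step first crosses 29.5 ℃ at ≈2 s with no overshoot and
zero steady-state error; the gains were chosen once for the ≤4 s
settling contract and not revisited.

**Rendering and noise.** Bodies at intensity 110 on a background of 12
with additive Gaussian pixel noise (sd 2), clipped to 8-bit. What the
simulator does **not** emulate: photorealistic texture, translucency,
soft-body physics, mechanical collisions (touching larvae simply merge
into an ineligible blob, which is what loses identity), lens distortion
and illumination gradients. A green tracking test therefore establishes
algorithmic correctness on idealised imagery, not performance on real
video.

## Tracking pipeline

Detection runs every k-th frame (default 3, mirroring the original
host-computer cadence) with the contour stage reusing the last known
locations. Identity assignment is greedy in ascending centroid distance
with a hard 40 px gate; ties break toward the lower previous id; ids are
never reused, and undetected objects are dropped immediately (no
coasting), so contact or edge encounters cost the identity.

The Moore tracer scans the 8-neighbourhood clockwise starting just past
the backtracked entry pixel. "Small loops" are refusals to revisit any
of the last 16 contour points; closure onto the start pixel is only
accepted once the contour is longer than the 16-point backtrack window.
The comparison budget (default 10,000) counts one unit per
candidate-neighbour check, emulating the original one-comparison-per-
clock-cycle cap deterministically. Because the XOR edge band is two
pixels wide in places, the walk is start-dependent; on rejection
(<63 points) the pipeline retries once from the topmost-leftmost edge
pixel (which follows the longer outer ring) before substituting the
cached last-valid contour for that larva id.

Fourier regularization resamples the raw contour to uniform arclength
(256 samples), truncates the complex spectrum to ±12 harmonics (default;
it preserves the head taper while removing pixelation — higher counts
resolve polygon kinks on the end caps and destabilise end detection) and
evaluates the truncated series at exactly 100 points.

Head/tail: curvature is the unsigned turning angle over ±5 of the 100
contour points; the tail is the second maximum at least 25 points away
from the head; a curvature spread below 35% of the maximum flags a
near-circular (ball) contour. The vote system aligns each frame's
candidate to the previous output by the summed head+tail displacement
test, records agreement/disagreement in a 20-frame sliding window, and
flips the tracked orientation once 15 of the last 20 candidates disagree
(then clears the window). The 15-vote quorum (0.75 s latency for a true
persistent flip) was chosen after observing sub-second aliasing episodes
in which pixelation makes the tail momentarily sharper; a simple
majority flipped on those. Ball events reset the tallies; during
ambiguity the previous head/tail *positions* (not contour indices, which
shift between frames) anchor the landmarks.

Spine smoothing uses α = Δt/τ = 0.2 and resets whenever identity changes
or the contour came from the cache rather than a fresh trace.

## Features

Definitions follow the catalogue in the package docstrings. Choices made
where the source was silent or ambiguous:

- the delayed term of the convolution-squared second recurrence is read
  as one-step (f2_{t−Δt}); the printed multi-second delay is treated as a
  typo, with the history-buffer length (default 5 s) retained and
  configurable;
- the convolution accumulators start at the trapezoid equilibrium of the
  first sample (f1 = f2 = f₀/λ), so constant inputs give exactly zero;
- per-feature convolution gains k default to 1.0 (the original values
  were tuned by hand and never published);
- `s` = 1 − 1.5·θ/π with θ = angle_upper_lower, reproducing the stated
  [−0.5, 1] range and monotonicity;
- speed bounding is x ↦ X·tanh(x/X) with X = 1.5 mm/s;
  `speed_reduced` = bounded(neck_top_speed/(v_norm + 10⁻⁶) − 1);
- `damped_distance` discounts exponentially with τ_d = 5 s;
- the structure tensor for `eig_reduced` is the second-moment matrix of
  the 100 contour points about the neck landmark;
- landmark velocities use the 0.2 s (four-frame) difference; during the
  warm-up (fewer than four prior frames) velocities report 0 and the
  frame is flagged.

## Classifiers

All scalar thresholds were unpublished; the defaults in
`ClassifierThresholds` were calibrated once against the simulator and
then frozen: bend when the smoothed body-bend angle exceeds 20° (the
bend flag itself smoothed with α = 0.2 and re-thresholded at 0.5);
left/right by the sign of smoothed asymmetry; back/forward at ∓0.25/+0.45
mm/s of smoothed tail parallel velocity; forward_peristaltic crest at
0.9 mm/s; roll requires a C-like shape (smoothed eig_reduced < 0.55)
moving laterally (|smoothed crab_speed| > 0.6 mm/s) without a concurrent
ball. Suppression windows are 1.5 s: recent balls veto back/forward and
lock the bend side to the last pre-ball side; recent rolls reset
back/forward/forward_peristaltic.

The ball network is the fixed 3→5(tanh)→1(sigmoid) architecture over
z-normalised (eig_reduced, larva_arc_ratio, larva_area_ratio), trained
by seeded full-batch gradient descent on cross-entropy for 500 epochs
(the original scaled-conjugate-gradient optimizer is treated as an
implementation detail; plain gradient descent keeps the weights bitwise
reproducible). When no trained network is supplied the pipeline uses a
rule-based score (1 − eig_reduced)·area_ratio/arc_ratio ≥ 0.52, which
separates balls (≥0.63 on the simulator) from rolls (≤0.44).

Event evaluation matches predicted to truth events one-to-one, greedily
by descending interval overlap (≥1 frame); run-level evaluation matches
each track's events only against the larva that track follows.

## Stimulation and protocols

DMD spatial calibration is a least-squares affine fit; intensity
normalisation scales commands by min(measured)/measured(x, y) via
bilinear interpolation (scale 1 at the dimmest point), clamped to the
sampled box outside it. Overlapping 1 cm² squares resolve to the minimum
command, which is associative/commutative and hence order-invariant.
Light plans are applied on the next 50 ms control frame (latency 50 ms,
within the ≤50 ms contract); thermo latency is logged as 100 ms. The
galvanometer dwell is (50 − n·1.5)/n ms; the printed 8-larva dwell of the
original system is inconsistent with its 4-larva value under any single
formula, so the 4-larva anchor (11 ms) defines the rule, and missing
objects aim at the plate centre with zero power. The thermal controller
reads the sigmoid exponent as x/2 (the printed form is typographically
ambiguous); x and x² are selectable.

The two physical DMDs are modelled as one additive field with per-
protocol combined intensities (285 µW/cm² proof/operant, 550 classical,
385 single-larva). Protocol schedules are built to the stated durations;
`params` can scale them down for desk-sized runs (the tests and the
acceptance script do this — frame rate, pixel scale, body model and all
thresholds are unchanged). Recentring teleports agents to a ring around
the plate centre one minute into each operant break; the identity reset
falls out of the 40 px gate. The uncorrelated control samples donor
stimulus trains per 60 s bin uniformly with the run seed, with
replacement when recipients outnumber donors.

## Analysis

Valid-object filters, binned fractions with exact Clopper–Pearson
intervals, Fisher tests (two-sided, p = Σ of hypergeometric
probabilities ≤ the observed table's), Bonferroni m = 24, PRE/ON/OFF
percentage-bending differences (ON pooled across the three test rounds
before differencing), 200 ms bend smoothing in the stated order (merge
same-side gaps < 200 ms first, then drop bends < 200 ms — the order
matters: two 150 ms bends 100 ms apart survive as one), initiation-bin
bend rates, and rank tests. Wilcoxon discards zero differences (classic
convention; all-zero samples return p = 1 with a warning); exact methods
are used for small tie-free samples, normal approximation otherwise.
CLES counts ties at half weight.

## Known limitations

- The spine flattens bends: a commanded 60° C-bend measures ≈30° through
  the midpoint construction, so classifier thresholds are calibrated to
  measured, not commanded, angles.
- The tail landmark can sit anywhere within the blunt tail cap
  (≤0.3 mm off-axis), and the two spine points nearest the tail inherit
  that wobble.
- Identity is intentionally fragile across contact; no re-identification
  is attempted.
- Table-style precision/recall on the simulator does not transfer to
  real video; it validates the algorithmic chain, not the imaging model.
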