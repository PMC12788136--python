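# Methods

## Kinematic model

The hand is represented as a rooted kinematic tree of 21 keypoints: the
wrist plus four joints (MCP, PIP, DIP, TIP) on each of five fingers, the
thumb's anatomical TM–MCP–IP chain occupying the same slots. Each finger is
a planar four-segment chain: all of its joints flex in a single plane given
by a unit normal stored on the skeleton. This is a deliberate
simplification — the toolkit targets single-finger flexion–extension, where
abduction/adduction is negligible; it cannot represent thumb opposition or
finger splay changes over time.

Angles use the interior-angle convention: the angle at a joint between its
incoming and outgoing segments, measured through the hand, so 180° is full
extension, flexion decreases the angle, and the geometric domain is
(0°, 180°]. The convention is fixed so that measured ROM maxima of nearly
straight fingers sit near 179°. Forward kinematics rotates each successive
segment by (180° − θ) about the finger-plane normal; inverse extraction
computes arccos of the normalised dot product of the two segment vectors at
each joint, clamped to [−1, 1] to absorb floating-point drift. The two maps
are exact inverses on the open domain; round-trip error is at the 1e-12°
level in practice and tested at 1e-6°.

Bone lengths are configuration, not claims: a packaged table of
order-of-magnitude adult-hand segment lengths (mm) fills any segments a
user does not specify. Root position and finger splay directions affect
only the keypoint layout; every angle-based metric is invariant to them,
and angle extraction is invariant to rigid transforms and uniform scaling
of the keypoint data.

## Metrics

**MPJAE** is the mean of |θᵢ − θᵢ*| over all selected (joint, frame)
samples with both sides present. All spreads reported in this package are
sample standard deviations (ddof = 1), since they describe finite test
sets; a single-sample cell reports std 0.

**APCK** counts errors strictly below the threshold. Strictness makes the
zero-noise bias case crisp: with a pure bias b, APCK(τ) is exactly the step
function 1{τ > b}. Ties have measure zero in continuous data, so the choice
is otherwise inconsequential. The default threshold grid is 0–30° in 0.5°
steps; the AUC is the trapezoidal area divided by the grid span, making it
a [0, 1] quantity comparable across grids. Neither the grid nor the
normalisation is standardised in the literature; both are exposed.

**MPJPE** pools Euclidean distances in mm over (keypoint, frame). The
default compares absolute positions in the shared world frame — appropriate
when prediction and ground truth are already calibrated to one coordinate
system, and the only mode in which wrist error is meaningful. A per-frame
similarity (Kabsch–Umeyama rotation + scale + translation) alignment is
available as `alignment="procrustes"` for trackers with arbitrary output
frames.

**MPJAVE** differentiates both angle trajectories with central differences
on interior frames and one-sided differences at the ends (exact for linear
signals; truncation error A·ω³/(6·fps²) for a sinusoid of amplitude A and
angular frequency ω — about 0.11°/s for a 20°, 0.5 Hz motion at 30 fps),
then averages the absolute velocity differences. No smoothing is applied by
default; an optional moving-average pre-filter (window in frames) is
exposed for noisy series. Differentiation annihilates constant bias, so
MPJAVE isolates temporal consistency from static offset.

**SPARC** measures smoothness as the negative arc length of the normalised
magnitude spectrum of the angular speed profile |dθ/dt|. The series is
zero-padded to `padding_factor` × the next power of two (default 4), the
spectrum normalised by its DC value, and an adaptive cutoff ω_c chosen as
the smaller of `max_cutoff_hz` (default 10 Hz) and the highest frequency
where the normalised spectrum still reaches `amplitude_threshold` (default
0.05). The reported value is the polyline arc length of the normalised
spectrum on the grid up to ω_c with the frequency axis normalised by ω_c —
i.e. the discrete trapezoidal evaluation of
−∫₀^ωc √((1/ω_c)² + (dV̂/dω)²) dω. These defaults are the standard choices
in the movement-smoothness literature. SPARC is defined on speed profiles;
a raw-angle mode exists (`on="angle"`) but the speed mode is the default
and the one used everywhere. A constant angle has an all-zero speed profile
and no defined spectrum: the function returns NaN as a flagged sentinel and
aggregation excludes such joints. The **angular SPARC error** is the
absolute per-joint SPARC difference between prediction and ground truth,
aggregated across joints.

**Losses.** The training loss is the weighted sum of 3D-keypoint,
2D-keypoint and MANO-parameter terms with default weights
(0.05, 0.01, 0.0005); fine-tuning uses the 3D term alone. The norm ‖·‖ is
not standardised; the default is the per-element mean L1, with RMS ("l2")
selectable — the choice affects no evaluation metric, only the loss values
themselves. These are pure array functions for scoring and regression
tests; no gradients or training loop.

**Aggregation.** Reports group joints into MCP/PIP/DIP classes (plus Wrist
and Tip when position metrics are present), thumb joints mapping onto the
same slots. The Overall row pools samples across classes
(sample-weighted), not a mean of class means; with unequal per-class counts
the two differ, and pooling was chosen so Overall.n equals the sum of class
counts. Velocity and smoothness cells at the wrist and fingertip are
structurally undefined — no flexion–extension angle exists there — and are
emitted as `N/A`, never as zeros.

**MCP offset.** A wrist marker mounted above the skin biases the measured
MCP angle; a constant correction (default +40°) can be added to MCP angles
post hoc. Corrected values may exceed 180°; they are kept un-clamped by
default (clamping would bias MPJAE toward zero) and counted in an
over-extension flag, with clamping available as an option. The offset is
applied only at evaluation time, never inside a loss.

**Missing data.** Missing samples are NaN end to end: metrics use
pairwise-complete samples, ROM and aggregation report exclusion counts,
velocity stencils that touch a missing angle produce missing velocities,
and resampling propagates gaps rather than interpolating across them.

## Synthetic data

The generator emulates the bench conditions under which such toolkits are
validated: isolated single-finger flexion–extension cycles at 30 fps, 10 s
(300 frames) per clip, with per-joint ROM bounds from packaged per-finger
presets of measured ground-truth motion (e.g. middle-finger MCP
148.0–179.3°). Joints oscillate between their bounds as a sinusoid (default)
or as minimum-jerk half-cycles; joints without a prescribed ROM rest at
178°. Keypoints follow by forward kinematics.

The error model applies, in order: constant per-joint bias, i.i.d. Gaussian
angle noise (an optional AR(1) correlation parameter exists because real
tracker errors are temporally correlated, but all closed-form checks use
the i.i.d. mode), sinusoidal high-frequency ripple, keypoint regeneration
through forward kinematics (so angle-domain and position-domain errors stay
kinematically consistent), i.i.d. Gaussian keypoint noise, and whole-frame
dropout. One integer seed spawns independent substreams for angle noise,
keypoint noise and dropout. Corrupted angles near full extension can exceed
180°; the returned angle trajectory keeps those values un-clamped (matching
the no-clamp policy above), and the clamp into (0°, 180°] happens only
inside the internal forward-kinematics call, whose domain is bounded.

What the generator does *not* emulate: occlusion-driven structured error,
temporally correlated tracker drift (beyond the optional AR(1) term),
marker-offset geometry beyond the constant angle bias, soft-tissue
artefacts, or multi-finger coordination. Passing tests therefore validate
the *metrics and kinematics* — that each quantity measures what it claims
on data with known structure — not any claim about a specific tracker's
real-world error distribution.

## Numerical and design choices

- Dot products are clamped to [−1, 1] before arccos; adjacent keypoints
  closer than 1e-9 mm make the angle at that joint missing rather than
  amplifying noise through a degenerate normalisation.
- `np.gradient` supplies the difference stencils; fps scaling converts
  per-frame differences to °/s.
- Resampling is linear interpolation onto a uniform grid spanning the
  source range; it is exact for linear signals and reproduces source
  samples bitwise when the grids coincide.
- Validation sizes in the test suite and acceptance script: kinematic
  round-trips use 1000 random poses; statistical recovery checks use about
  10⁵ (joint, frame) or (keypoint, frame) samples, where the half-normal
  and chi(3) sampling error is a fraction of the 2% check tolerance; SPARC
  cross-checks run 50 seeded signals of 32–400 frames against a naive-DFT
  oracle at 1e-6.
- Serialised outputs (CSV, TSV, JSON) contain no timestamps and use sorted
  keys, so identical seeded runs are byte-identical.

## Known limitations

- Planar per-finger flexion only: no abduction/adduction, no wrist
  orientation angles, no palm arching; the fingertip has no angle, so tip
  accuracy is only assessed positionally.
- Whether ground-truth angles in external datasets were computed with the
  same interior-angle formula cannot be verified from file contents alone;
  the CSV sidecar carries a convention tag (`interior-angle-deg-180ext`) to
  make the assumption explicit.
- SPARC values depend on the cutoff parameters; comparisons are only
  meaningful at fixed `SparcParams`.
- MPJPE in the default mode conflates global calibration error with pose
  error; use the Procrustes mode when the coordinate frames are not shared.
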