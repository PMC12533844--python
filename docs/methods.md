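# Methods

This note documents the models, conventions and design choices behind
`fishbout`, in the spirit of a methods appendix: enough detail to judge
what the pipeline computes, what the simulator emulates, and where the
open choices were made.

## Coordinate and windowing conventions

Pose files store keypoints as image `(row, col)` pairs, the native order
of pose-estimation software.  On read they are converted once to a
right-handed Cartesian frame (`x = col`, `y = -row`) so that "up" in the
well image is +y; all geometry downstream uses this one convention, and
the conversion is inverted on write (round-tripping either dialect is the
identity, exercised to the last bit in the tests).  Frames are 0-based and
every interval is half-open `[start, stop)`.

A track of T frames yields **T − W** overlapping windows with starts
0 … T−W−1 (W = 40 by default).  Note that T−W+1 complete windows exist;
the T−W convention is retained deliberately so that the canonical
1600-frame acquisition produces exactly 1560 windows, at the cost of the
final frame being covered by no window (majority voting reports it as
`unknown`).  This off-by-one quirk is intentional and documented rather
than "fixed".

Egocentric alignment applies a single rigid transform per window, computed
from frame 0: rotate about the center keypoint so center→snout points
along +y, then translate the center to the origin.  Rotation before
translation about the same pivot makes the two operations commute cleanly;
aligning to the origin rather than an "image center" is equivalent up to a
constant offset that the mean-subtraction of normalization removes anyway.
Alignment preserves intra-frame pairwise distances exactly, is idempotent,
and is invariant to any rigid motion of the input (tolerance 1e-6 of a
body length in the property tests).  A window whose frame-0 center and
snout coincide has no defined heading; the single-window API raises, the
batch path flags the window unusable.

Feature vectors flatten windows timepoint-major, then keypoint, then
(x, y) — the order is recorded in every saved model so bundles are
portable.  Normalization uses two *scalar* statistics over the whole
training corpus (not per-coordinate): divide by the maximum absolute
coordinate, then subtract the mean of the max-scaled data, in that order.
Scalars are computed over usable windows only, frozen at training time,
and shipped in the classifier bundle; the 24- and 96-well models carry
different scalars because the two optics differ in spatial spread.

## Discovery, classification, smoothing

The discovery stage exists to bootstrap labeling, not to name behaviors:
KMeans (k = 9, k-means++ with an explicit seed) partitions windows, and
each cluster gets a `stationary` or `movement` role from a displacement
rule — mean implied center-keypoint speed strictly below 2 mm/s is
stationary (the same threshold used for speed-defined bouts; a borderline
cluster counts as movement, and at least one cluster per role is
guaranteed by falling back to the extreme cluster).  Cluster identities
beyond the role split are deliberately uninterpreted.

Classification is deliberately plain: stratified 90/10 split; PCA fit on
the training split only, retaining components for 95 % of variance, no
whitening, random state 2023; then a random forest (100 trees, Gini,
unbounded depth, seeded).  No hyperparameter search stage exists by
design.  The two plate formats are ordinary instances of the same code
differing only in class set (24-well: stationary/scoot/turn/AsLB/VsLB;
96-well merges scoot+turn into `movement`, since wall-following in small
wells makes the two indistinguishable) and in frozen normalization
scalars.  Reported F1 is the macro average over classes present in the
test set; per-class F1 is always reported alongside so either convention
is inspectable, and a class absent from the test set is reported as
missing, never as zero.

Majority voting assigns frame t the most frequent call among all windows
covering t (starts in `[t−W+1, t]` clipped to valid starts); every
overlapping window votes once, unweighted.  Ties break by class-set
order with `stationary` first, so ties default to the least eventful
call — conservative for startle detection.  Unusable windows do not vote,
and frames with no votes are `unknown`.  The implementation is checked
against a brute-force enumeration oracle on a thousand random sequences,
plus the guarantees that any strict majority always wins, that voting
never invents a label absent from the overlapping windows, and that an
isolated single-window flip flanked by W consistent windows never
survives.

Bouts are maximal same-label runs **strictly longer** than 5 frames;
speed-defined bouts (speed > 2 mm/s) instead use an *at least* 5-frame
rule.  The strict/non-strict asymmetry between the two definitions is
preserved deliberately; both thresholds are parameters.  Short runs are
dropped, never merged into neighbors, so bouts plus gaps always partition
the frame axis, and an `unknown` frame terminates a run.

## Kinematics

Speed is the per-frame displacement of the body-center keypoint (index 3 —
the alignment anchor, hence the natural reference point) scaled to mm/s.
Heading is the angle of the center→snout vector; "instantaneous" heading
change is its wrapped per-frame first difference in (−180°, 180°].  The
caudal tail angle is the signed angle between the trunk axis (snout→center
direction) and the caudal-most segment (keypoint 6→7), zero for a straight
body; the keypoint pair is configurable since different rigs emphasize
different tail landmarks.  First-difference series define frame 0 as 0 so
all series keep length T.  Stimulus-locked interval maxima use 200 ms
windows (32 frames at 160 fps).

## The synthetic simulator

The simulator exists because the source recordings are tied to proprietary
hardware.  It emulates: a 7-segment rigid-length body (total length
3.56 mm in 24-well, 3.85 mm in 96-well) whose bends are distributed
caudally; a circular well (radii 7.75 / 3.2 mm, standard plate geometry)
with specular heading reflection and wall sliding at shallow incidence;
160 fps, 10 s acquisitions; and five motor archetypes with
literature-informed kinematic envelopes:

| archetype  | duration (frames) | peak speed (mm/s) | net heading (deg) | bend time-to-peak (frames) |
|------------|-------------------|-------------------|-------------------|-----------------------------|
| stationary | —                 | 0                 | 0                 | —                           |
| scoot      | 20–40             | 5–20              | 2–25              | whole bout                  |
| turn       | 15–35             | 2–4.5             | 30–88             | 8–16                        |
| AsLB       | 25–40             | 32–60             | 95–175            | 3–6 (≤ 40 ms)               |
| VsLB       | 30–40             | 12–25             | 95–160            | 16–38 (100–240 ms)          |

Propulsion is a half-sine burst: for scoots it spans the bout, for the
other maneuvers it spans roughly twice the bend time (capped at 150 ms),
followed by a glide — concentrating displacement the way real C-starts do
and keeping startle bouts from crossing a whole well.  Heading follows a
smoothstep ramp that reaches the drawn net change at the bend's
time-to-peak; tail curvature follows a single C-/O-like bend with a
damped counter-flexion for turns and startles, and a ~22 Hz beat for
scoots.  These envelopes make the classes separable by construction —
net heading change splits startle-like from routine maneuvers with zero
overlap at zero noise, and peak speed splits AsLB from everything
slower — which is what lets simulator ground truth act as an oracle.

Tracking noise is an AR(1) ("jitter with memory") process per keypoint,
σ = 8 µm, ρ = 0.98.  Two honest caveats follow.  First, real keypoint
placement error on comparable rigs is an order of magnitude larger
(~70–130 µm); white noise of that amplitude at 160 fps would however imply
apparent stationary speeds far above the 2 mm/s movement threshold, so the
simulator keeps jitter temporally correlated and small enough that
stationary frames never cross that threshold — a property the pipeline's
own stationary/movement split depends on.  Second, the simulator's
within-class variability (drawn uniformly from the envelopes above) is
surely narrower than biological variability.  Both mean that passing
synthetic benchmarks demonstrates the *pipeline machinery* — alignment,
normalization, training, voting, bout and assay logic — recovers known
ground truth; they do not certify classifier accuracy on real animals,
which depends on real labeled clips.

The labeled-window generator stands in for a manually reviewed clip
library.  Each window contains one archetypal bout at a random phase,
constrained so the window keeps the bend phase and at least half the bout
in view — the way a human reviewer accepts any clip that clearly shows the
behavior, not only clips that start on it.  The constraint matters
downstream: sliding windows at inference meet bouts at arbitrary phase,
and majority voting can only reach plurality if such windows are
in-distribution for the classifier; windows showing only the post-bend
glide are excluded because a reviewer could not identify the behavior
from them either.

## Problem sizes and numerical choices

The shipped benchmarks use 200 windows per class per plate format for
training (1000 / 800 windows), a 24-fish × 6-trial response assay with
startles injected in exactly half the trials, and 6 ten-second
free-swimming tracks for spontaneous summaries — sizes chosen so the full
suite and the acceptance script each complete in well under a minute on a
single core while keeping per-class test counts meaningful (20 held-out
windows per class).  Determinism is end-to-end: every stochastic step
(simulation, splitting, k-means, forest) takes an explicit seed, the PCA
seed defaults to 2023, and the orchestrated runner writes a manifest with
SHA-256 hashes of every output so reruns are verifiably identical.

Degenerate inputs are handled explicitly rather than silently: an
all-masked track is returned unchanged with a warning; gaps longer than
`max_gap` (default 5 frames) stay masked after cleaning, and windows
overlapping them are excluded from statistics and inference; edge gaps
are never extrapolated; an all-zero feature corpus raises a normalization
error; an empty response table raises rather than reporting 0 %.

## Known limitations

* Synthetic jitter amplitude is below real tracking error (see above);
  robustness to realistic keypoint noise is untested by construction.
* The simulator has no hydrodynamics, no habituation across trials, and
  no photorealistic appearance; wall interaction is specular reflection
  plus sliding.
* Group statistics (t-tests, ANOVA) are out of scope: the pipeline emits
  tidy tables for statistics software instead of re-implementing them.
* Cluster count k = 9 and the 2 mm/s role threshold are defaults carried
  from the assay design, not optimized quantities.
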