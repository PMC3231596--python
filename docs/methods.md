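# Methods

This note documents the models, conventions and numerical choices behind
`floorgait`, in the order the pipeline runs.

## Floor model and coordinates

The floor is a 12 x 2 array of 30 cm tiles, each with 64 photo-
interrupter sensors taken to be a uniform 8 x 8 grid (any uniform layout
summing to 64 is conceivable; 8 x 8 is the natural reading and fixes the
pitch at 30/8 = 3.75 cm).  Axes: Y is the walking direction (96 sensor
rows), X lateral (16 columns); the origin is the floor's bottom-left
corner and a sensor's position is its cell centre, `(idx + 0.5) * pitch`.
"Backmost" therefore means minimal Y.  Contact intervals are half-open
`[press, release)`: a sensor queried exactly at its release time is
released.  Contacts still open at the end of a recording are auto-closed
1 ms after the last event and counted as a warning rather than rejected,
because recordings truncate when a walk leaves the floor.

The event-log format is one event per line (`time  x_idx  y_idx  state`)
with `#` header lines; it exists for diffability and trivial parsing.
Validation enforces per-sensor pressed/released alternation and reports
offending sensors, times and line numbers.

## Gait simulator

The simulator is the package's stand-in for a physical floor: it
generates event streams with the statistical structure the identification
method assumes, namely per-user-stable spatiotemporal gait parameters
with smaller within-user variation.  It is a contact phenomenology, not
a biomechanical model — no forces, masses or joint kinematics, only what
binary presence sensors can observe.

Population defaults (mean, between-user sd, within-user sd) were chosen
once as plausible for a small adult cohort walking at natural pace:

| trait | mean | between | within | notes |
|---|---|---|---|---|
| step length | 65 cm | 6 | 2 | clamped to [48, 78] so five steps fit the floor |
| lateral half-separation | 9 cm | 1 | 0.5 | floor of 7.5 cm keeps feet ≥ 1 empty sensor column apart |
| toe-out angle | 7° | 3 | 1.5 | sign is outward per side |
| stance time | 0.55 s | 0.05 | 0.02 | clamped so stance stays below the 0.8 s stepping horizon |
| step interval | 0.55 s | 0.05 | 0.02 | heel-strike to next heel-strike |
| foot length | 25.5 cm | 1.3 | — | ≤ 8 cells (30 cm) so the footprint model fits |
| foot width | 9.5 cm | 0.6 | — | ≤ 4 cells (15 cm) |
| rollover fraction | 0.60 | 0.06 | — | fraction of stance spent rolling heel→toe |

The lateral separation is wider than typical natural step width; it is
deliberately constrained from below by the 3.75 cm sensor pitch so that
the two feet never produce grid-adjacent footprints during double
support, which is the regime the segmentation algorithm (and, implicitly,
any floor of this resolution) requires.

A sole is a heel disc plus a forefoot ellipse joined by a narrow midfoot
band; the band guarantees the printed footprint is spatially connected at
sensor pitch.  Rollover is modelled as a contact window of length
`foot_length / 2` sweeping heel→toe over the first `rollover_fraction` of
stance and resting on the forefoot afterwards, so rear-half sensors press
exactly at heel-strike and front-half sensors release exactly at toe-off;
the footstep's total contact span equals its stance time.  Noise is
per-sensor dropout (default 2%) and Gaussian event-time jitter (default
8 ms).  Steps are placed by *step* length with alternating sides (a
stride is two steps); walks plan six steps, and a step that would land
beyond the floor is dropped with a warning, leaving at least the five
steps the walking features need.

Seeding: user `u`'s profile derives from `SeedSequence((master, 0, u))`
and walk `s` of user `u` from `SeedSequence((master, 1, u, s))`, so any
single sample is reproducible in isolation and datasets are byte-stable.

What the simulator does not emulate: anthropometric correlations (height
vs foot size), gait drift over time, footwear, partial sensor failures
beyond i.i.d. dropout, and multi-occupant traffic.  Consequently,
passing tests show the *method* recovers identity when gait parameters
are individually stable, not that real humans are this stable; published
results on real floors of this type are the evidence for the latter.

## Segmentation and the footprint model

The grouping rule is spatio-temporal connected components over contacts:
two contacts join iff their sensors are 8-neighbourhood-adjacent and
their intervals overlap or gap by less than `t_link` = 0.05 s.  This
keeps one rolling foot together (heel sensors release before toe sensors
press, but the intervals chain spatially) while separating double
support, which overlaps in time but never in space.  Components with
fewer than 3 sensors are discarded as noise.  The implementation is
union-find over per-cell buckets; the test suite checks it against an
exhaustive transitive-closure oracle.

The 8 x 4 footprint model is axis-aligned to the floor — foot angle shows
up in the activation pattern, not in a rotated window.  The seed sensor
(minimal y, then minimal x) fixes the heel row; laterally the window is
centred on the mean x of the footprint's sensors and clamped on-floor.
Out-of-window contacts are clipped and counted (zero for feet within the
default dimensions).

Transitional frames are *instantaneous* states at `fStart + k dt`, not
cumulative unions — matching the sensor physics.  The array always has
`floor(T_max / dt)` frames with `T_max` = 0.8 s: short footsteps pad
naturally with all-inactive frames (post-toe-off is genuinely inactive),
and longer footsteps are clipped with a warning.  `frame_count` computes
`floor(T_max/dt + 1e-9)`; the tolerance makes exact rational divisions
(0.8/0.04 = 20) survive binary floating point while genuinely fractional
ratios still floor (0.8/0.06 → 13).

## Features

The compensated centre (com_FX, com_FY) is the physical centroid of the
active footprint-model cells — the only quantity computable from binary
sensors that summarises where the foot actually lay; it blends stride
length, lateral placement and foot angle.  Walking features use absolute
floor coordinates; step-to-step differences are left to the classifier.
Vector layout is feature-major (`[f1 over 5 steps][f2 over 5 steps]…`),
frozen so trained models are portable.  Normalisation is per-coordinate
min-max to [-1, 1], fitted on training data only; constant coordinates
map to 0 and out-of-range test values are clipped and counted.
z-scoring would also be defensible; min-max was chosen because the
network inputs then share the exact range of the ±1 stepping inputs.

Stepping encodings scan each 8 x 4 frame heel row → toe row, low x →
high x within a row, active → +1, inactive → −1.  The encoding is
injective on grids and needs no normalisation.

## Classifier

Both modalities use the same three-layer network: P1 inputs, a logistic-
sigmoid hidden layer (default 30 nodes — the accuracy plateau for
ten-user cohorts), and one tanh output per enrolled user.  The tanh
output is forced by the fusion design: scores must live in (−1, 1) with
±1 one-vs-rest targets so that fusing needs no score normalisation.

Training minimises full-batch MSE by nonlinear conjugate gradient
(Polak-Ribiere with a Wolfe line search) and stops at an MSE goal or an
iteration cap: walking 1e-3 / 800, stepping 1e-5 / 115.  When a line
search stalls, optimisation restarts from the current iterate (fresh
steepest-descent direction) until the budget is spent, so the stopping
rule remains exactly (goal, cap).  The per-iterate MSE trace is recorded
and non-increasing.  Initial weights are seeded uniform
±1/√fan_in; everything is deterministic given the config seed.
Curvature-aware training matters here: first-order methods with
per-parameter step sizes fail to escape the all-negative base-rate
solution on the raw 2560-dimensional ±1 stepping inputs, whereas
conjugate gradient fits them directly.

PCA (scikit-learn) optionally reduces stepping vectors; 248 components
is the default operating point for 2560 inputs.  With k = dimension the
projection is an isometry, so the PCA pipeline reproduces the raw
pipeline's decisions exactly.

## Fusion and evaluation

Fused scores are `O_G(i) = W_W O_W(i) + W_S O_S(i)`; the decision is the
argmax (ties to the lowest index).  Decisions are invariant to joint
positive rescaling of the weights, so only the weight *ratio* matters;
the default grid is {0, 0.02, …, 1}² minus the origin.  Weights are
selected by grid search on an inner validation split (25%) carved from
each training fold — never on test data; ties break toward the smaller
weight norm, then lexicographically.

Evaluation is repeated stratified k-fold cross-validation.  All fitting
(normalisation, PCA, both MLPs, weight selection) happens inside each
training fold.  Confusion matrices accumulate counts over repetitions,
so row i sums to repetitions x n_samples(user i).  The acceptance
protocol runs the default cohort (10 users x 50 walks, master seed
fixed) at 10 folds x 3 repetitions — a scale chosen so the whole suite
runs comfortably on one CPU while keeping 30 independent fold estimates.

## Degenerate inputs and edge cases

Walks with fewer than five segmentable footsteps raise a feature error
naming the sample.  Empty footprints under extreme dropout are flagged,
not fatal.  A footstep whose duration exceeds 0.8 s is clipped into the
sampling horizon with a warning.  Classes with fewer samples than folds
are rejected before evaluation.  NaN/infinite feature values are
rejected before training.

## Known limitations

Left/right foot labelling is not attempted (the features never use it).
Verification-mode metrics (FAR/FRR, EER) are out of scope —
identification only.  Only the MLP classifier is built in; the training
and scoring surface is small and deliberately pluggable, and comparison
classifiers from scikit-learn can be wired in by the user.  The
synthetic cohort's accuracies characterise this pipeline under the
simulator's assumptions and should not be read as predictions for any
physical deployment.
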