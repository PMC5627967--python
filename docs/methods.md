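# Methods

`fabricsense` simulates a bench apparatus for studying whether the motion of
loose fabric *helps* rather than hurts wearable motion sensing, and
implements the two analyses used to quantify the effect: cluster-similarity
statistics and online windowed classification. This note records the model,
its assumptions, the calibrated constants, and the design choices made where
the problem was genuinely open.

## The apparatus model

### Rigid pendulum

The rig is a weighted compound pendulum of length L = 0.57 m swinging in a
vertical plane: a uniform rod (`rod_mass`, default 0.1 kg) plus a permanent
bob at the tip (`bob_mass`, default 2.5 kg), optionally loaded with a test
weight (`tip_load`, 0–3 N, converted to mass through standard gravity).
With angle θ measured from the hanging vertical, the equation of motion
about the pivot is

    I θ̈ = −M g d_com sin θ − c θ̇

with I and M·d_com those of rod + bob + load, and c the viscous pivot
damping (default 0.04 N·m·s/rad). It is integrated with an adaptive
high-order Runge–Kutta method (DOP853, rtol 1e-8) with dense output
evaluated exactly at the 600 Hz sample instants.

The tip-heavy mass distribution is deliberate and load-bearing for the whole
study design:

- The tip sensor R1 sits very close to the centre of percussion
  (equivalent length ≈ 0.566 m vs. L = 0.57 m), so its tangential specific
  force `(L θ̈ + g sin θ)/g` nearly cancels — R1's clean signal is only a
  few hundredths of a g, the regime in which a rigidly attached sensor
  genuinely struggles.
- A 3 N tip load barely changes the frequency (≈0.09 %) but changes the
  pivot inertia by ≈12 %, and with it the viscous decay rate. The two
  classes of motion therefore differ mainly in their slowly diverging
  amplitude envelope and the phase offset that accumulates through the
  amplitude-dependent period — a subtle, growing difference, large at the
  drive level but strongly suppressed at R1 by the centre-of-percussion
  geometry.

A light rod with no bob would instead let the load double the sensor gain
and shift the frequency by several percent, making the two motions
trivially distinguishable from the rigid sensor — the opposite of the
phenomenon under study.

### Fabric strip

The 0.18 m fabric strip hanging from the tip is a serial chain of K = 6
rigid links joined by torsional springs (bending stiffness κ per joint) and
dampers, with quadratic aerodynamic drag acting at each link centre and
optional point masses (the 2 g sensor boards) at the attachment nodes.
Coupling is one-way: the pendulum drives the chain root and the chain does
not back-react, which guarantees by construction that R1 is identical with
and without fabric — the experimental control for fabric not altering the
carrier motion. Within the chain, links are fully coupled through the
standard serial-chain mass matrix in absolute angles

    M_ab = l² μ_ab cos(φ_a − φ_b),   μ computed from link and node masses,

with generalized forces collecting centrifugal coupling, gravity plus the
base pseudo-force, joint spring/damper torques and drag. A one-way cascade
*inside* the chain (each link ignoring the inertia below it) was tried
first and rejected: it pumps energy outward and produces unbounded whip
(tip rates above 1000 rad/s). Quadratic rather than linear drag is used
because fabric at whip speeds is firmly in the high-Reynolds regime; it is
also what self-limits the whip.

The chain starts from its static equilibrium with the pendulum held at the
release angle (a floppy strip dangles; a stiff one sticks out along the
pendulum), found by a torque-balance root solve, taking the lowest-energy
solution.

Integration uses a fixed-step classical RK4 in a compiled kernel with step
`min(1/4800 s, 0.2/ω_max)`, where ω_max bounds the fastest joint, gravity
and damping rates; the pendulum drive is pre-evaluated on the half-step
stage grid so no interpolation occurs inside the stepper. When every
elastic mode lies above the sensor Nyquist rate (quasi-rigid chains, used
by the stiff-limit validation), transients are unresolvable by
construction; the chain is then solved as its instantaneous quasi-static
shape per sample, and node accelerations follow from rigid-body kinematics
on that shape. Direct torque evaluation in that regime would multiply
solver state noise by κ/I and was measured to corrupt the readings.

### Virtual accelerometer

Each sensor reads the specific force (point acceleration minus the gravity
vector) projected on the tangential axis of its carrying element — the axis
that is horizontal with the rig at rest, matching a single-axis
accelerometer sewn flat on the strip. Readings are expressed in standard
gravities, given additive white Gaussian noise, then quantized to a
symmetric 16-bit grid over ±3 g (the grid includes ±full scale exactly) and
clipped.

### Trial-to-trial variability

Two sources, both seeded: per-trial release-angle jitter (sd 0.3°) and
per-sample sensor noise (sd 0.015 g, representing sensor, acquisition and
residual environmental noise together). Release jitter feeds through the
amplitude-dependent period into a small phase spread within a class;
sensor noise sets the detection floor at the rigid sensor. The defaults
were calibrated once, during model design, so that the bench phenomenology
emerges: weight classes statistically invisible at R1, strongly separated
at the fabric sensors, and material responses ordered roma > jersey >
denim. They were frozen before the acceptance tests were written.

### Fabric presets

The garments were never characterised mechanically; the presets are
surrogates with the documented ordering denim > jersey > roma in bending
stiffness and mass:

| material | κ (N·m/rad) | density (kg/m) | joint damping | drag (N·s²/m²) |
|----------|-------------|----------------|---------------|-----------------|
| denim    | 2.0e-3      | 0.12           | 1.0e-4        | 0.005           |
| jersey   | 1.2e-4      | 0.06           | 8.0e-6        | 0.005           |
| roma     | 3.0e-5      | 0.04           | 3.0e-6        | 0.005           |

All three are drive-dominated (far from rigid at this length scale, as real
18 cm strips are); stiffness and mass control how strongly the strip
amplifies the drive difference between weighted and unweighted swings.

## Similarity analysis

A motion class is the cluster matrix Ψ (P×M, columns are trials) and its
column mean ψ, the class prototype. Similarity is the Euclidean distance
s = ‖ψ − φ′‖; scores are min–max normalised over the collection being
compared.

`class_separation_report` scores, per sensor and condition pair: each
trial against its own class prototype *leave-one-out* (within-class;
scoring against a prototype containing the trial itself is biased), and
each trial against the full opposing prototype (between-class). The
separation statistic is the mean normalised between-class minus
within-class score. The accompanying one-way ANOVA groups scores to the
reference-class prototype by condition — a direct test of whether the two
motions can be told apart from that sensor. An alternative scalar (distance
to the pooled grand-mean prototype) was considered and rejected: with equal
class sizes its expectation is identical for both groups regardless of the
mean separation, so it can only detect dispersion differences.

For material comparisons the min–max normalisation pools the raw scores of
all materials into one range. Normalising per material would erase exactly
the quantity of interest: the between/within score ratio is scale-free, so
per-material normalisation maps every fabric onto nearly the same interval.
One common scale preserves the response amplitudes, the way box-plot panels
on a shared axis read.

The one-way ANOVA itself is computed from standard sums of squares with the
upper-tail F probability; it is cross-checked in the tests against an
independent implementation.

## Online windowed classification

Signals are segmented into n-sample windows at stride n/2 (offsets 0, n/2,
n, …; trailing partial windows dropped; odd n rounded down). For each
window index a fresh binary SVM (linear or Gaussian kernel; Gaussian
parametrised as K(x,y) = exp(−‖x−y‖²/σ²)) is trained on the training
trials' windows at that index — features are the raw n acceleration
samples, since the fabric itself is the feature map — and predicts the
held-out trials' windows.

Evaluation is *paired* leave-one-out: each fold holds out one trial of each
class, so the training split always contains equally many trials per class
and every trial is evaluated exactly once. This matters: with an unpaired
19/1 split, the training classes are always 10-vs-9 and any margin
classifier resolves uninformative windows toward one class in a way that is
correlated with the held-out label — unweighted SVMs pick the majority
(systematically the wrong class, far-below-chance accuracy), and
class-weight-balanced SVMs pick the minority (systematically the right
class, far-above-chance accuracy). Chance-level behaviour on uninformative
data is only recovered when the training ratio carries no information.

Hyperparameters (box constraint C and kernel scale σ) are tuned once per
fold by stratified 5-fold cross-validation on a spread of five window
indices of the training split, with folds drawn at the trial level so
windows of one trial never straddle a fold boundary. Tuning on the first
window alone fails — the first window is the release instant where the
classes are still identical. The grid is C ∈ {1e-2 … 1e2} and σ ∈
{0.1, 1, 10, 100} × the median pairwise window distance; ties break toward
smaller C then smaller σ. When no grid point beats the majority baseline by
more than 0.05 the tuner returns the neutral canonical setting (C = 1,
σ = median distance) — otherwise the tie-break would select an arbitrary
extreme such as a kernel scale so small the Gram matrix is the identity,
whose constant predictions interact pathologically with leave-one-out.

Accuracy is reported as mean ± sd over held-out trials of the per-trial
window accuracy, plus the accuracy-vs-window-index curve.

## What the simulation does and does not show

Passing tests demonstrate that, under this physically grounded surrogate of
the bench: rigidly sensed weighted/unweighted swings are statistically
indistinguishable while fabric-mounted sensors separate them (ANOVA
p < 0.01 at the fabric tip, p > 0.05 at the rigid tip); fabric sensors
classify far better than the rigid tip at 250 ms windows; rigid-tip
accuracy grows with window size; and softer/lighter fabrics separate
classes more strongly (roma > jersey > denim).

They do not show waveform-level agreement with the physical recordings
(never deposited), nor the bench's reported rigid-sensor accuracy at large
windows: in this simulator the rigid-tip class difference stays near the
supervised-learnability threshold at every window size (≈50→60 % across the
sweep), whereas the physical rig reached high rigid-sensor accuracy at
windows above 300 ms. Reproducing that would require a rigid-channel class
signal large enough that the similarity ANOVA would detect it too — with
whole-record distance statistics, detection is strictly easier than
learning a discriminant from 18 trials, so both cannot hold at once in
this model. Out-of-plane fabric motion, wind, yarn-level mechanics and
two-way fabric–pendulum coupling are not modelled.

## Problem sizes

Default analyses use the full study conditions: 10 trials per condition,
6000 samples per trial, leave-one-out over 20 trials, 79 windows at 250 ms.
The window-size sweep in the validation suite samples three sizes (15 ms,
250 ms, 1.5 s) of the 15 ms–1.5 s range; the experiment runner exposes the
full grid.
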