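# Methods

`cpgdrnn` models a locomotor central pattern generator (CPG) as a fully
connected continuous-time recurrent neural network that transforms a small
set of sinusoidal "command" oscillations into the six sagittal elevation-angle
trajectories of the lower limbs (left/right thigh, shank, foot).  This note
documents the model, the synthetic data it is exercised on, the numerical
choices, and the limits of what the accompanying tests demonstrate.

## Network model

Each unit *i* carries a state `y_i` governed by

    T_i dy_i/dt = -y_i + F(x_i) + I_i,        x_i = sum_j w_ij y_j,

with logistic squashing `F(a) = 1/(1 + exp(-a))`, trainable synaptic weights
`w_ij` (fully connected, signed, self-connections allowed), trainable per-unit
time constants `T_i > 0` (seconds), and external input `I_i`.  Units are
partitioned into 6 input units (driven by the oscillator channels through
`I_i(t)`), N hidden units, and 6 output units; biases of hidden and output
units are fixed at zero.  The time constants give each unit its own relaxation
dynamics, which is what lets a static weight matrix produce phase-shifted,
frequency-structured output.

Integration is explicit Euler with step `dt` equal to the kinematic sample
interval (0.01 s at the 100 Hz sample rate used throughout).  The forward
pass refuses to run when `dt >= min(T_i)`; the trainer additionally clamps
`T_i >= 1.5 dt` so the discrete update remains monotone-stable.  All units
start at the sigmoid midpoint, `y_i(0) = 0.5`, an unbiased state inside F's
range.

### Cost and adjoint gradients

Training minimizes the integrated squared output error
`E = int q dt`, `q = 1/2 sum_out (y_i - d_i)^2`, discretized as a
left-endpoint sum `E = dt sum_{t=0}^{N-1} q(y_t)`.  Gradients with respect to
every `w_ij` and `T_i` come from an adjoint (backward-in-time) pass.  Rather
than discretizing the continuous adjoint ODE separately — whose printed forms
are ambiguous about index placement of the `1/T` factors — the implementation
computes the **exact discrete adjoint of the Euler forward recursion**
(backpropagation through the update).  This has two consequences:

* the gradients match central finite differences to rounding error at any
  `dt` (enforced by a 20-seed oracle test at relative error ≤ 1e-4), and
* as `dt -> 0` the adjoint recursion converges to the continuous adjoint
  equation with boundary condition `p_i(t_1) = 0`, which the left-endpoint
  cost quadrature makes hold exactly in discrete time as well.

The per-step recursions (with `a_i = dt / T_i`):

    g_i(t)   = p_i(t+1) a_i F'(x_i(t))
    p_j(t)   = e_j(t) dt + p_j(t+1)(1 - a_j) + sum_i g_i(t) w_ij
    dE/dw_ij = sum_t g_i(t) y_j(t)
    dE/dT_i  = -(dt/T_i^2) sum_t p_i(t+1) (-y_i(t) + F(x_i(t)) + I_i(t))

with `e_i = dq/dy_i` (nonzero on output units only).

### Optimizer

The trainer uses resilient per-parameter adaptive steps: each parameter moves
against the sign of its gradient by its own step size, which is multiplied by
an up-factor (1.2) while successive gradient signs agree and by a down-factor
(0.5) on a reversal (the gradient memory is cleared after a reversal, so no
step is taken in the iteration immediately following a flip).  Step sizes are
initialized at 5e-3 and clamped to [1e-7, 5e-2].  Sign-based steps were chosen
over raw-gradient steps because the gradient magnitudes of a fully connected
recurrent network span many orders of magnitude across parameters, which
leaves most weights effectively frozen under a single global rate; the
adaptive sign step reaches the same loss in roughly a third of the
iterations in pilot runs on this task family.

Time constants are optimized as `log T_i` (chain rule applied to the `T`
gradient), which keeps them positive by construction; initialization is
log-uniform on [0.03, 0.3] s, weights i.i.d. uniform on [-0.5, 0.5].

A restart whose loss or parameters become non-finite is re-initialized with
halved initial step sizes, up to three times, before being abandoned;
`train_restarts` raises only if every restart is lost.  Multi-restart training
runs all restarts in lockstep (batched linear algebra) and selects the
restart with the highest mean similarity index over all patterns and output
channels, ties broken by lower loss.

### Output range

Unit activations relax toward the (0, 1) range of F, while kinematic targets
are normalized to [-1, 1].  Targets are therefore trained against their
affine image in [0.1, 0.9] and predictions are mapped back before any
similarity or covariation analysis, which always happens in the [-1, 1]
convention.  The 0.1/0.9 margins keep the optimum away from sigmoid
saturation.

### Training precision

The training loop runs in single precision by default (configurable via
`TrainingConfig.precision`); this halves the wall time of the large runs and
the sign-based updates are insensitive to the extra rounding.  The public
`forward` / `backward_adjoint` functions always compute in double precision —
the gradient oracle is checked there — and an internal consistency test
verifies that the batched training-path gradients equal the public adjoint
gradients exactly when run at float64.

## Synthetic gait generator

No recordings are distributed, so the package generates elevation-angle
trials with the structural properties the analysis relies on:

* each channel is a three-harmonic series
  `theta(t) = sum_k A_k sin(k phi(t) + phi_k)` of a stride phase `phi(t)`;
  harmonics 1–2 carry ≥ 98 % of the waveform variance (enforced at config
  validation);
* the stride fundamental grows linearly with treadmill speed (0.6 Hz at
  1 km/h to 1.0 Hz at 6 km/h — plausible human stride rates) and the harmonic
  amplitudes grow by 6 %/km/h around per-segment references of roughly
  20–30 degrees;
* right-side channels are the left-side waveforms delayed by half a cycle
  (a phase-domain shift, exact even under period jitter);
* the first-harmonic phase lags across thigh → shank → foot are (0, -0.9,
  -1.5) rad with a common second-harmonic phase, chosen once (analytically,
  via the 3x3 harmonic Gram matrix) so that the thigh/shank/foot trajectory
  of one leg is planar to ≥ 98 % — the planar-covariation structure of human
  walking — while remaining an open elliptic loop;
* optional white measurement noise (default SD 0.5 deg) and per-cycle period
  jitter (default SD 2 % of the period, a realistic stride-time variability)
  are added, with all randomness drawn from one explicit seed.

What the generator does **not** emulate: stance/swing asymmetries beyond
three harmonics, double-support timing, ground-contact transients, EMG,
inter-subject morphology, fatigue or other non-stationarity.  Passing tests
on this data therefore demonstrate that the pipeline recovers the structure
the generator encodes — spectra, velocity trends, planarity — not that it
reproduces every property of motion-capture recordings.

## Feature pipeline

A trial is reduced to a representative two-gait-cycle segment: cycle
boundaries are successive maxima of the low-pass-filtered right-thigh angle
(the most sinusoidal channel), and among all consecutive cycle pairs the one
whose pooled FFT peaks best match the full recording (summed relative
frequency + amplitude error over the three harmonics, earliest pair on ties)
is excised.  Harmonic extraction uses a rectangular window — leakage-free on
integer-period segments — with 4x zero-padding for peak localization; the
fundamental is the largest peak in a 0.3–2 Hz physiologic band, and harmonics
2 and 3 are read at the maximal bins near `k f1`, searching ± 2 unpadded bins
but never far enough to reach a neighbouring harmonic (on a two-cycle segment
one bin is `f1/2`).  Per-trial specs pool the six channels by median
frequency and mean amplitude, which tolerates one noisy channel.

Oscillator inputs come in four variants: SEA uses the extracted harmonic
frequencies at unit amplitude, each as a sine and its sign-flipped twin
(six channels); SEB and SEC shift the fundamental by +0.25 / -0.25 Hz (and
its harmonics by twice and three times that); AM scales each harmonic's
channel pair by its extracted amplitude.  Amplitudes are in degrees, so the
experiment layer rescales the whole AM input set by one global gain (largest
amplitude over the pattern set mapped to 1) — preserving the across-velocity
amplitude ratios that carry the speed information while keeping the drive in
the sigmoid's sensitive range.

The harmonic-amplitude convention is linear magnitude (a pure sine of
amplitude A yields a peak of ~A); spec files record this choice.

**Washout lead-in.**  The oscillator drive starts one second before the
scored two-cycle window (configurable via ``prepare_pattern(washout_s=...)``)
and the lead-in carries zero cost weight.  The network is thereby trained
and evaluated on its driven oscillatory regime — the limit cycle that the
similarity index's period refers to — rather than on the cold-start
transient from the uniform initial state, which otherwise dominates the
residual (about five-fold higher RMS error in the first fifth of the window
in pilot runs).  One second is at least three relaxation times of the
slowest unit at initialization.

One deliberate inconsistency in the emulated phenomenology is documented
rather than resolved: with `f_k = k f1` and `f1` increasing with speed, the
third-harmonic frequency necessarily increases with speed as well; a
decrease of `f3` cannot coexist with the verified harmonic relation, so the
generator enforces `f3 = 3 f1`.

## Evaluation metrics

**Similarity index (SI).**  `SI = int p1 p2 / sqrt(int p1^2 int p2^2)` over
exactly one cycle period `Tc`, after circularly shifting `p2` so its maximum
coincides with `p1`'s (earliest maximum on ties; integration anchored at the
reference maximum; trapezoidal quadrature at sample resolution, no
sub-sample interpolation).  `|SI| <= 1` by Cauchy–Schwarz and `SI = 1` iff the
aligned patterns are positively proportional.  The maxima used for
synchronization are located on zero-phase low-passed copies (second-order
Butterworth, cutoff `4/Tc` — above the third gait harmonic): on a noisy
flat-topped peak the raw argmax jitters by several samples, and because the
resulting shift rotates the entire window, that jitter alone caps the SI of
a *perfect* periodic model near 0.98 on default-noise synthetic targets.
Locating the maximum robustly removes this measurement artifact; the inner
product itself is always taken on the raw patterns.  Note that maximum-based
synchronization makes the index a *shape* comparison: for a pure sine, a
sign flip is indistinguishable from a half-period shift and is realigned to
`SI = 1`.  For six-channel comparisons `Tc` is the reference pattern's
spectral stride period (`1 / f1`); two-cycle segments have too few interior
maxima for the peak-based detector, and a spectral period estimate is the
robust equivalent.

**Planar covariation.**  Covariance PCA of the mean-centered
(thigh, shank, foot) trajectory of one leg; the planarity index is the
variance fraction of the first two principal components (1 for an exact
plane, ~2/3 for an isotropic cloud).

**Structure.**  Connectivity statistics count positive (excitatory) and
negative (inhibitory) entries of the full weight matrix, self-connections
included; exact zeros are counted separately and excluded from the
percentage denominators (they have measure zero after training).  Time
constants are summarized by median, quartiles and range.

## Experiment layer and problem sizes

Experiment 1 (proof of concept) trains single-pattern networks (default 30
hidden units) at one speed from SEA/SEB/SEC inputs and compares best-restart
SIs; Experiment 2 trains one network per hidden-unit count on AM inputs at
five speeds simultaneously (multi-pattern: gradients summed over patterns
each iteration) and tests prediction at four unlearned intermediate speeds,
recording connectivity and time-constant statistics.  Generator seeds play
the role individual subjects played in the original protocol.

The package's default problem sizes are desk-scale: 5–10 restarts and
1,500–10,000 iterations rather than the 100 restarts x 50,000 iterations of
a cluster-scale study.  At these sizes a full 80-hidden-unit multi-pattern
training (5 restarts x 5,000 iterations) takes on the order of two minutes on
one core.  The acceptance script repeats that training over five generator
seeds.

Per-pattern time grids differ across velocities (two cycles at a slower
speed span more samples); multi-pattern batches pad to the longest pattern
with zero cost weight beyond each pattern's length, which leaves gradients
exactly equal to the unpadded per-pattern sums.

## Known limitations

* **Inhibitory dominance is budget-limited.**  At the desk-scale training
  length the trained networks show only a slight excess of inhibitory over
  excitatory weights: the weight matrix stays close to its sign-balanced
  initialization, and the strong inhibitory majority reported for
  cluster-scale training lengths should not be expected to re-emerge fully
  within 5,000 iterations.  The directional effect (more inhibition than
  excitation at large hidden counts) is what the tests assert.
* The prediction test at unlearned speeds inherits the generator's idealized
  velocity interpolation; real inter-velocity generalization is harder.
* No sensory feedback: the network is a pure feedforward-in-time oscillator
  transformer; closed-loop gait control is out of scope.
* Cycle detection assumes a dominant, near-sinusoidal thigh channel; heavily
  corrupted channels would require a different boundary definition.
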