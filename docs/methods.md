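# Methods

`numreach` simulates and analyzes two-alternative numerosity comparisons
reported with a reaching movement: two dot arrays appear briefly, and the
index finger travels ~29 cm from a start button to one of two lateral
targets on a screen.  The package's core is a *threshold-free* account of
that behaviour: no decision bound is ever crossed; the reach starts with
the first unit of evidence and is throttled continuously by statistical
certainty.

## The threshold-free model

**Evidence.** The internal representation of the numerical difference is
Gaussian with Weber scaling,

    s(i) ~ Normal(|n_L - n_R|,  (ω √(n_L² + n_R²))²),

sampled every `R` ms (`R ∈ [1, 100]`).  Samples are expressed in
numerical-difference units in a larger-side-positive frame; a negative
sample favours the wrong side.  The per-sample misclassification
probability is exactly the erfc psychometric function

    err = ½ erfc( |n_L − n_R| / (ω √2 √(n_L² + n_R²)) ),

which is also the function used to estimate ω from accuracies
(`evidence.fit_weber`, least squares on error rates, R² reported).  The
second parameter of the sampling distribution is interpreted as a
*standard deviation*; this is what makes the erfc expression the exact
per-sample error probability, and it is verified by simulation in the
test suite.

**Memory.** The stimulus is visible for only 200 ms, so sampling continues
from memory for the whole flight.  Memory is modelled by exponentially
weighting the stream, `EMA(i) = D·s(i) + (1−D)·EMA(i−1)` with
`EMA(0) = s(1)`.  `D = 1` is memory-free sampling; `D → 0` pins the
stream to the first sample (primacy; a noise-reduced linear accumulator).

**Inference.** With a flat prior over the difference μ and a normal
likelihood of *variance* `W` (the acuity parameter), the posterior after
`n` EMA samples with mean ē is `Normal(ē, W/n)`; the probability that the
positive-frame side is larger is `Φ(ē √(n/W))`.  Treating `W` as a
variance (not an SD) makes `W/n` the textbook flat-prior conjugate
result; the notation `N(ē, W/n)` is otherwise ambiguous, so this is
stated prominently here.  Certainty is the rescaled binary entropy of the
side probabilities,

    certainty = (H(½) − H(p)) / H(½)  ∈ [0, 1],

zero at p = ½ and saturating near 0 or 1.  Probabilities are clipped at
1e−12 before the entropy evaluation; certainty saturates at 1 long before
the clip matters.  At exactly p = ½ the heading tie-breaks to the
positive-frame side — certainty is 0 there, so the motor update vanishes
and nothing downstream depends on the tie rule.

**Control.** The effector follows a finite-horizon jerk-minimizing
feedback law: with remaining time δ = t_f − t,

    x⃛ = 60(x_f − x)/δ³ − 36ẋ/δ² − 9ẍ/δ,

integrated by explicit Euler at dt = 1 ms, with δ clamped at dt to avoid
the end-of-horizon singularity.  (The gain vector's horizon symbol is
read as δ throughout; dimensional consistency requires it.)  Certainty
multiplies the *entire* state derivative — both axes, all orders — so
uncertainty delays the movement without changing its jerk-optimal
character.  Movement time t_f is drawn per trial from a per-ratio
distribution (below); the movement clock runs even while the effector
holds still before the first sample.  The simulation is 2-D (horizontal
toward ±10 cm targets, depth toward the screen 29 cm away); by linearity
of the law the behavioural properties are invariant to the target scale.

**Choice, RT, changes of mind.** The choice is the endpoint side.  RT is
the time for the cumulative path length to reach 0.28 mm (the median
pre-release micro-movement of the recorded sample) plus a non-decision
time set manually in 200–500 ms (default 300 ms; it is not a fitted
parameter).  A change of mind is an excursion penetrating ≥ 1 cm into the
half-plane opposite the endpoint side before returning; penetration is
measured from the midline.

## Accumulation-gated extension

To ask whether a threshold is *needed*, the same machinery can be gated:
EMA samples are summed and motor updates (not inference — the posterior
uses pre- and post-gate samples alike) are withheld until the running sum
clears ±threshold.  A gate of 0 reproduces the threshold-free model tick
for tick.  For a 5-vs-10 comparison at ω = 0.17 the probability that a
sample fails a 0.27 gate is ≈ 0.006, i.e. a gate of that size is
practically zero — any first sample starts the movement.  Sweeping the
gate upward (`simulator.threshold_sweep`) withholds movement until
certainty is high, so reaches become direct and the across-ratio spread
of mid-flight positions collapses; that spread is summarized at the
mid-flight point (index 50 of the 101-point normalization).

## Satisficing variant

Certainty weighting alone cannot finish a reach when evidence is
ambiguous: on equal-count trials the posterior hovers near ½ and the
finger stalls between the targets.  The satisficing variant raises
certainty to the normalized remaining distance to the screen,

    weight = certainty^distance,   distance: 1 at the start button → 0 at the screen,

with 0⁰ ≡ 1: physical proximity does not change certainty, only how much
it matters, and at screen arrival the brake is fully released so the
finger settles onto the nearest target.  One implementation subtlety: if
`distance` is read from a depth coordinate that is itself certainty-gated,
a maximally uncertain reach never approaches the screen and the brake
never releases — the variant would inherit exactly the gridlock it exists
to solve.  The default therefore tracks distance on the movement clock
(`1 − t/t_f`, the depth schedule of an unimpeded reach), which guarantees
release by arrival; the literal depth-coupled reading is available as
`ModelParams(satisficing_distance="depth")` for comparison.

## Traditional collapsing-bound accumulator

For comparison the package implements the classical five-parameter
scheme: per-ms Gaussian samples with drift set by the numerical ratio,

    drift(ratio) = 1 − erfc( |ratio − 1| / (√2 · dft · √(ratio² + 1)) ),

variance `sig2`, accumulated to a bound `thr/(1 + t)^k` that collapses
every ms, plus a non-decision time.  Time in the collapse law is in
seconds by default: with collapse rates of order 3–4 a per-ms unit
flattens the bound within a few ticks, which is incompatible with the
RT structure the parameterization is meant to produce; the per-ms unit is
available behind `DDMParams(time_unit="ms")`.  The drift map uses a
single drift functionally tied to ratio (the per-ratio-drift variant
behaves practically the same).  Movement begins only at the crossing —
these models were built for discrete choice, not motor positioning — and
is driven through the same certainty-weighted controller, with certainty
read from the two-hypothesis posterior
`p(correct | samples) = logistic(2·dft·Σs / sig2)` on samples that
continue to arrive in flight.  The optional post-lift-off second bound
flips the target when the opposing evidence total crosses it, and the
optional deadline stops accumulation and locks the higher-posterior
target.

## Fitting

The objective mirrors how the data are summarized: simulate a block (480
trajectories per ratio by default), time-normalize to 101 points,
truncate at 99% of the depth travel (the recording stopped ~4 cm short of
the screen), keep correct trials, flip left reaches, and score

    loss = MSE(per-ratio mean horizontal position) + MSE(per-ratio accuracy).

The accumulator is scored on accuracy plus RT quantiles
{0.1, 0.25, 0.5, 0.75, 0.9}.  The objective is made deterministic per
(parameters, seed) with common random numbers; optimization is scipy's
DIRECT space partitioning followed by a bounded Powell polish of the best
point on the same surface, and the best point is afterwards re-scored on
fresh seeds to report an honest mean ± SD loss.  `W` and `D` act
multiplicatively and are searched in log10 space — in a linear box the
strong-primacy basin (D of order 0.05) occupies a sliver that a global
partitioning search rarely refines, and fits stall on a shallow
compensation ridge (larger R and D, smaller W); the log parameterization
makes that basin findable at realistic budgets.  Recovery remains
imperfect by the nature of the problem: (R, W, D) trade off, and
individual replicate fits can land on a near-equivalent compensation
(e.g. faster sampling with more primacy and a wider likelihood), which is
why recovery is judged by the median over replicate fits.  Non-decision
time is not searched for the threshold-free model; it is fixed manually.

## Synthetic data

`synthetic.generate_dataset` emulates the *structure* of the recorded
sample with generator-side constructs, deliberately independent of the
model so that analysis tests do not presuppose simulator correctness: 22
subjects × 420 trials over ratios {0.1, 0.25, 0.5, 0.75, 0.9} (ratio 1
optional), counterbalanced sides, dot counts ≤ 25, error rates drawn from
the erfc psychometric function at a known ω (default 0.17), per-ratio
lognormal movement times rising from ~0.56 s to ~0.65 s (CV 0.1),
piecewise minimum-jerk paths on a 200 Hz grid, smooth positional noise
(SD 0.05 cm, enveloped by depth progress so paths start pinned at the
midline), injected change-of-mind excursions (1.2–2 cm deep, turning at
15–25% of the movement — brief enough to respect the 50%-of-points
correctness rule) at rate 0.03, and injected pull-backs (2–3 cm depth
retreat) at the observed 7.66% dropout rate.  Every latent is recorded in
the trial metadata.  The generator reproduces the data's *bookkeeping*,
not its physiology: no motor noise spectrum, no force dynamics, no
subject-level parameter variation — so pipeline-closure tests certify the
analysis code, not realism of the paths.

## Numerical and design choices

- Euler at dt = 1 ms; δ clamped at dt.  With weight ≡ 1 the integrated
  trajectory matches the minimum-jerk polynomial to < 0.25% of the
  movement amplitude for t_f between 0.4 and 1 s.
- Screen coordinates are right-positive with the midline at x = 0; the
  101 normalized points include both endpoints; a correct trial needs
  ≥ 50% of points *and* the endpoint strictly on the correct side.
- Equal-count trials default to a left-positive internal frame; all
  statistics are invariant to that choice (verified by the mirror test).
- Per-trial RNG streams are spawned from one seed sequence (pair, t_f,
  evidence drawn in that order), so blocks are bit-reproducible and any
  trial can be regenerated alone.
- Pull-backs are operationalized as depth velocity < −0.5 cm/s sustained
  for ≥ 10 ms (the observed dropout is a fraction, not a definition;
  both thresholds are configurable).
- HP is the mean of all 101 points of the mean flipped trajectory; a
  sub-window can be configured.

## Problem sizes

Simulation sizes in the test suite are chosen to bound the full run to a
few minutes of CPU: behavioural surfaces use 480 trials/ratio (averaged
over 10 seeds for the ordering checks), the gate sweep uses 6 levels ×
480 trials/ratio, change-of-mind phenomenology uses 2 000 trials/ratio
for rate ordering plus a 10 000-trial hard-ratio block for double-change
counts, and parameter recovery uses 5 replicate fits at 480
simulations/ratio with a budget of 150 DIRECT evaluations plus polish.

## Limitations

- Movement times are sampled, not generated: the model inherits whatever
  t_f distribution it is given.
- No button/force model; RT rests on the 0.28 mm displacement criterion.
- The certainty-only model cannot complete ambiguous reaches (by design);
  the satisficing extension is one resolution, not a claim of uniqueness.
- Fitted parameters are identified only up to the (R, W, D) compensation
  structure discussed above; conclusions should rest on the recovered
  regime (e.g. strong primacy) rather than point values.
- Change-of-mind rates at fitted parameters are small; the change-of-mind
  analyses use a deliberately change-rich parameterization.
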