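# Methods

## Models

All three learners map an experienced outcome history for a single cue to
a predictive expectancy (the expected value of the *next* outcome, in
outcome units). Expectancies are always read before a trial's outcome is
experienced; an outcome enters a learner's state only after it has been
observed, and in the choice task only the chosen option's learner is ever
updated.

**Window learner.** `EV_t` is the arithmetic mean of the most recent `W`
experienced outcomes. `W ≥ 1` (dimensionless trial count) is the only
structural parameter. Two degenerate regimes need a rule the averaging
formula does not supply:

* *Partial window* (`0 < n < W` outcomes experienced): the mean of the
  `n` available outcomes. This keeps the expectancy inside the convex
  hull of real experience rather than padding with phantom observations.
* *Cold start* (`n = 0`): a configurable `prior_ev`, default 0 — neutral
  between the ±1 win/loss coding and below any positive base rate.

**Delta rule.** `ev ← ev + L·(O − ev)` with learning rate `L ∈ (0, 1]`
and initial expectancy 0. This is the canonical prediction-error
(Rescorla–Wagner) recurrence.

**Decay rule.** Stored associative strength `s ← (1 − D)·(s + O)` with
decay rate `D ∈ (0, 1)` and initial strength 0. Under constant unit input
the fixed point is `(1 − D)/D`; multiplying by `D/(1 − D)` therefore maps
the asymptote to exactly 1 and puts decay output on the same scale as the
other learners. This particular recurrence was chosen precisely because
its constant-input fixed point matches that normaliser; other decay
variants (e.g. decaying before adding the outcome) have different fixed
points and would not normalise to 1. The engine compares decay
expectancies on the normalised scale throughout.

Under i.i.d. outcomes with mean `p`, all three expectancies are
asymptotically unbiased for `p` (the decay learner after normalisation),
which is what makes them comparable on the change-point stream.

## Environments

**Change-point Bernoulli stream.** `n_before` trials at base rate
`p_before` followed by `n_after` at `p_after`, outcomes coded 1/0 by
default (configurable). A stationary stream is the `p_after = p_before`
special case. Defaults used in demonstrations and checks: base rate 0.50
for the stationary case; 0.25 → 0.75 with 400 + 400 trials for the
change-point case; narrow/wide window widths 4 and 32 paired with
fast/slow rates `L = D ∈ {0.5, 0.05}`.

**Discrimination/reversal choice task.** Two stimulus pairs, labelled by
their reward percentages (100:0 and 80:20 by default), interleaved over
270 trials in a seeded random order balanced to within one trial per
pair. Choosing an option wins (+1) with that option's current programmed
probability and otherwise loses (−1); wins and losses are treated
identically by every learner. At the reversal trial — default 136, the
session midpoint, chosen for symmetric phases since the source procedure's
exact reversal point is configurable in any case — the correct/incorrect
assignment swaps simultaneously for all pairs. Learner state persists
across the boundary; the reversal deficit *is* the persistence of stale
state. Each of the four options carries an independent learner.

## Choice policy

Default: greedy over the presented pair's expectancies, exact ties broken
uniformly at random. Greedy is the simplest rule under which an "error"
is exactly a choice of the currently lower-valued option, and the
headline reversal-error pattern is required to hold under it. A softmax
policy (`P(i) ∝ exp(ev_i/τ)`, `τ > 0`) is available by config for
probabilistic responding. Per trial the policy consumes at most one
random draw (greedy: one integer draw only on a tie; softmax: one
uniform) followed by exactly one uniform for the outcome — a fixed
contract that makes runs replayable by an independent step-through.

## Errors to criterion

Within one (pair × phase) cell, trials are taken in session order and the
statistic is the number of incorrect choices strictly before the first
run of `k = 8` consecutive correct choices. Phases are scored
independently — a correct run may not straddle the reversal boundary.
Participants who never produce a `k`-run are censored: their error count
is the cell's total error count and they are flagged as non-attainers.
Cohort summaries default to averaging over **all** participants with
censored counts, reporting the attainment rate alongside; an
attainers-only switch exists so any selection is explicit. With a single
value in a cell the SD is reported as 0.

## Seeding and reproducibility

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`). Cohort participant `i` uses seed
`SeedSequence(master_seed).generate_state(n)[i]` — a counter-based
derivation, so participant streams are independent of execution order and
any prefix of a cohort is reproducible on its own. Identical configs are
bit-identical on re-execution. Output CSVs carry the config hash and
seeds as `#` header comments.

## Numerical choices

* Window means use exact compensated summation (`math.fsum`); with the
  task's outcome codings (0/1, ±1) every sum is exact, so the stateful
  learner, the pure function, and a brute-force slice-mean agree to the
  last bit.
* Closed-form comparisons (geometric delta/decay paths, normalisation
  identities) are asserted at relative 1e−12; Monte-Carlo means at 3
  standard errors (binomial SE for single streams, replicate-SD SE for
  replicated designs).
* Softmax subtracts the max expectancy before exponentiation; this leaves
  choice probabilities unchanged and avoids overflow.

## Problem sizes used in checks

Stationary convergence uses a single 10,000-trial stream per window
width; change-point asymptotes use 200–500 replicate streams of 400 + 400
trials; the adaptation-law check uses 2,000 replicate streams; the
reversal-task pattern check uses cohorts of 200 participants (the worked
example in the README uses 1,000). These sizes put Monte-Carlo error well
inside the tested tolerances while keeping the default suite fast.

## What the generator does and does not emulate

The synthetic environments reproduce the *programmed* structure of the
tasks: stationary and step-change Bernoulli contingencies, probabilistic
±1 point feedback, balanced interleaved pair presentation, simultaneous
mid-session reversal. They deliberately omit features of real behavioural
data — reaction times, perseveration and other choice-history biases,
attention or perceptual noise, within-session drift in individual
parameters, and per-pair criterion-triggered phase changes. Passing tests
therefore establish the internal behaviour of the models under their own
assumptions (convergence, adaptation speed ordering in `W`, the
reversal-error pattern), not that any particular parameter value fits
human data; fitting to data is out of scope.

## Known limitations

* Two options per trial; no more-than-two-alternative schedules.
* The reversal is simultaneous and trial-indexed; criterion-triggered
  reversal is not implemented.
* Greedy/softmax only; no epsilon-greedy, UCB or perseverative policies.
* `W`, `L`, `D` are fixed within a run — no volatility tracking or
  uncertainty-weighted adaptation of the learning parameters.
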