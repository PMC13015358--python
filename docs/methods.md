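# Methods

## Generative task model

The decision variable is the horizontal position of a pigeon performing a
discrete-time biased random walk: one increment per 200 ms step, drawn
i.i.d. from N(s·μ, σ²) with the drift side s = ±1 chosen 50/50 per trial.
Positions are in screen-normalized units; the seed piles at ±0.8 are the
farthest reachable points.  Clipping is applied sequentially — the pigeon
stops at a pile and may walk back — and a trial ends only at the keypress,
never by touching a pile.  Block accounting charges 1 step at each trial
start, 1 per pigeon step before the keypress, and an optional error penalty
in steps; a block ends on the first trial at which the cumulative count
reaches the 600-step budget, with that trial played to completion.

Task parameter rows for the three study-style cohorts (σ = 0.15 with μ ∈
{0.05, 0.1, 0.15} and payoffs +1/0, +1/−4 or +1 with a 30-step error
penalty; σ = 0.05 with μ ∈ {0.01, 0.02} and +1/−1 for the changepoint
cohort) ship as a packaged YAML table.

Choices are scored against the latent drift side.  The alternative —
scoring against the pile the pigeon would eventually reach — changes
reward-rate functions only slightly (it saturates accuracy faster); the
drift-side convention is used throughout because it makes the trial's
correct answer well-defined at every moment.

## Simulated agents

An agent is a bound schedule (constant, linearly collapsing, or piecewise
around a changepoint), an integer non-decision time (NDT, 0–4 steps), a
fast-guess probability, and an optional per-trial Gaussian jitter of the
whole schedule.  The agent commits at the first step whose position
magnitude reaches the bound (fast guesses commit at step 1); the choice is
fixed at commitment and never revised; the keypress occurs NDT steps later
while the walk continues, which is what produces incongruent trials.
Trials that never cross within the 60-step cap are forced at the cap and
flagged; analyses exclude them.  A trial cap is needed because low-SNR
walks with high bounds can wander indefinitely; 60 steps is an order of
magnitude above typical decision times in every shipped condition.

Default cohort heterogeneity: per-agent constant bounds uniform on
[0.1, 0.6], NDT uniform on {1, 2}, fast-guess probability uniform on
[0, 0.3], no trial jitter.  For the low-σ changepoint cohort the bound
range is [0.1, 0.3]: with σ = 0.05 and per-step SNR 0.2–0.4 this yields
decision times of roughly 3–20 steps and median changepoint times near
8–15 steps, the scale that design operates at; higher bounds would stall
single trials for much of a block.  Changepoint times are participant-
specific: the ceiling of the median (or mean) RT from that participant's
earlier fixed-SNR block with the same starting μ.

These defaults describe what the generator *does* emulate: heterogeneous
speed–accuracy preferences, motor delays, lapses, and measurement noise
from discrete steps.  They do not emulate learning within a session,
sequential (post-error) adjustments, attention lapses longer than one
trial, or any coupling between payoff condition and bound unless a
payoff-sensitive policy is constructed explicitly.  Passing recovery tests
therefore demonstrates calibration of the estimation chain under the
stated agent family, not validity of those behavioral assumptions for real
participants.

## Estimation chain

*Non-decision time.*  For each candidate delay d ∈ {0..4}, congruence is
the fraction of trials whose position sign d steps before the keypress
matches the choice; positions exactly at zero (or probes before trial
start) leave that delay's denominator.  The estimate is the smallest delay
attaining the maximum, one estimate per participant and SNR context
(fixed-SNR blocks sharing an SNR pool their trials; mixed blocks split by
the trial's cued SNR; each changepoint direction forms its own context).
With agents that never lapse and high bounds, congruence ties at exactly
1.0 for all delays up to the true NDT and the smallest-delay tie-break
under-estimates; fast guesses break these ties physically, so recovery
statements are made under the default cohort (≈98% exact recovery at 200
trials per agent).

*Decision time and bound.*  DT = max(RT − NDT, 1); floored trials are
flagged and excluded from bound analyses.  The trial bound is
|(x_{DT−1} + x_{DT})/2| — the expected crossing point within the final
decision step.  Bounds at DT ≤ 2 are flagged unreliable and excluded from
regressions and participant averages.

*Bias correction.*  For each (μ, σ) pair, fixed-bound decisions are
simulated at 16 true bounds (0.01:0.05:0.76; default 10⁵ trials per bound,
10⁶ available via the config), pooled by DT, and an OLS line of measured on
true bound is fitted per DT cell (≥30 trials, else identity).  Corrections
invert the fit: corrected = (raw − intercept)/slope, clipped to [0, 0.8].
Per-trial motor delays are drawn uniformly from 0–2 steps in these
simulations, but the DT used for pooling is the commitment step itself,
matching the application regime in which the congruence estimator recovers
session NDTs exactly.  At DT = 1 the fitted slope is ≈0.4 (the first step
follows the generative distribution regardless of the bound); by DT = 15
the map is near identity, though not exactly: pile clipping keeps
top-of-grid bounds slightly underestimated at any DT (slope ≈ 0.92,
intercept ≈ +0.03).  What the correction is accountable for is calibration,
and that is tested directly: corrected mean bounds are unbiased within 0.01
(tolerance 0.03) across true bounds 0.1–0.6.

*Diagnostics.*  Bound-vs-DT regressions use OLS on per-DT medians (per-
trial points available via a flag); the bound-change diagnostic regresses
(b_t − b_{t+1}) on b_t, with slope 1 for i.i.d. variation around a constant
mean and 0 for a true random walk.  Z-scoring uses the sample SD (n−1)
within participant × block.

## Reward-rate functions

RR functions simulate full blocks for a deterministic fixed-bound agent
(no motor delay — the choice is fixed at commitment, and adding NDT steps
to the cost only shifts all curves; the zero-NDT observer is the cleanest
ideal benchmark) at each of 16 grid bounds, 500 repetitions by default,
summarized by the median coins/step and a percentile 95% CI.  Two-SNR
surfaces: block-wise mode pairs one low- and one high-SNR block rep and
divides total coins by total steps; trial-mixed mode assembles single
blocks whose trials draw the SNR 50/50, with the agent applying the bound
matching the trial's cued SNR (the normative upper envelope, since the cue
is assumed used).  Changepoint functions fix the pre-changepoint bound and
scan the post bound, which takes effect at the changepoint step — the same
step at which the new μ first applies.  Pools of i.i.d. trials are
simulated vectorized and partitioned sequentially into blocks; the final
block trial completes (budget overshoot allowed), matching the cohort
simulator.

The gradient at a pre bound is (RR(b*) − RR(pre))/(b* − pre) toward the
grid argmax b*, zero at the optimum; its sign prescribes raising or
lowering the bound.  The bonus threshold is 80% of the median coin total
of an agent playing the RR-optimal fixed bound.

Two properties of these landscapes matter for interpretation.  First, with
σ = 0.15 steps, the discrete first-passage overshoot (≈0.58σ ≈ 0.09) makes
the effective bound exceed the nominal one, so simulated accuracy and mean
DT sit above the continuous Wald-diffusion formulas at moderate bounds;
the formulas are recovered (within ~10%) only when the bound is many step
SDs away (tested at σ = 0.05).  Second, the RR maxima are extremely flat:
for the +1/−4 low-SNR block, the median RR between bounds 0.41 and 0.56
varies by under 5% of its value, so the grid argmax of a 500-rep estimate
moves between 0.46 and 0.56 across seeds.  Reported peak locations should
be read with that plateau in mind; satisficing anywhere on it costs almost
nothing.

## Changepoint validation experiment

The gradient-following experiment builds cohort-3-style agents whose
post-changepoint bound is pre + gain × gradient, with the gradient
estimated from that agent's own pre bound and changepoint time.  Pre
bounds span the regimes each direction distinguishes (low→high includes
bounds below the post optimum, where the prescription is an increase;
high→low starts at 0.08 so pre-changepoint bounds stay measurable), and
the gain is scaled per direction (high→low gradients are several-fold
larger) to keep post bounds off the physical floor — saturating at the
floor provably inverts the rank relation between prescribed gradient and
realized change.  The analysis chain then measures each agent's realized
pre→post bound change (mean corrected bound over reliable trials ending
before vs after the changepoint) and recomputes the gradient at the
*measured* pre bound; the Spearman correlation between the two is ≈0.7 in
both directions at 60 agents.

Under block-level reward rate with the ±1-coin payoffs of the changepoint
cohort, both fixed-SNR optima sit near bound 0.06, and the optimal
post-changepoint bound exceeds the pre bound only when the pre bound is
below that level; for typical pre bounds the normative prescription in
*both* changepoint directions is a decrease of varying size.  The
correlation analysis is agnostic to this (it compares prescribed and
realized changes), but summaries of "bounds should rise after low→high
changepoints" hold here only for low pre bounds.

## Numerical choices

- One RNG stream per participant (spawned from the master seed); the
  simulation layer is bit-reproducible under a fixed seed.
- Grid argmax ties break toward the lowest bound; sign ties at zero
  positions resolve by a fair coin; congruence ties break toward the
  smallest delay.
- Positions are serialized to 6 decimals in trial tables; analysis
  re-parses them, so all reported statistics are recomputable from the CSV.
- Default problem sizes — 500 block repetitions per RR grid point, 10⁵
  correction simulations per bound, 60-agent cohorts — run in seconds to a
  few minutes on one CPU and are all configurable upward.

## Known limitations

- The estimation chain assumes the no-revision convention (choice fixed at
  commitment); if real decision-makers revise during the motor delay,
  congruence-based NDT estimates conflate revision with delay.
- The linear per-DT correction cannot fix the DT = 1–2 cells (slope ≪ 1
  amplifies noise), which is why short-DT trials are excluded from bound
  summaries rather than corrected.
- Trial-mixed optima depend on RR differences of ~0.003 coins/step near
  the diagonal of the bound surface; at realistic repetition counts the
  argmax there is not a stable object, and analyses should compare RR
  values, not argmax coordinates.
- No hierarchical or likelihood-based estimation: all estimators are the
  direct trialwise measurements the explicit-evidence design permits.
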