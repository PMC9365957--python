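# Methods

## Task model

One trial has two phases. In the **decision phase** the participant chooses,
within 3 s, between a smaller immediate and a larger delayed monetary outcome
(wins in the reward condition, losses in the loss condition; the delayed
outcome is always two weeks away). In the **anticipation phase** the chosen
outcome is cued for 6 s, a 50 ms flash prompts a speeded button press, and
feedback is shown for 1.5 s. A response within an adaptive window earns the
chosen outcome; otherwise wins are replaced with €0 and losses are doubled.
Inter-stimulus and inter-trial intervals are jittered uniformly on [1, 2] s
and [1.5, 5] s (the uniform law is this package's choice; only "jittered" is
specified by the design).

The trial grid crosses eight immediate amounts (€1.00–€2.75 in €0.25 steps)
with four immediate/delayed ratios (0.2, 0.4, 0.6, 0.8). The delayed amount
is immediate/ratio **floored to whole cents** — the convention that
reproduces the €1.66 delayed option for €1.00 at ratio 0.6 (a
nearest-cent variant is available via the `rounding` argument). Losses are
subtracted from asymmetric balances, €8.20 for immediate and €10.00 for
delayed choices; on the full grid the delayed loss yields the strictly larger
final win in exactly 16 of 32 trials, which is the design property the
balances were chosen for (an equal balance would make the smaller loss always
optimal).

### Adaptive response window

The MID response window starts at 300 ms and is multiplied by 1.05 after a
slow or missing response and by 0.95 after a fast one (a missing response is
treated as slow; the additive variant, ±15 ms steps, is behind a flag). With
multiplicative steps the equilibrium success probability solves
p·|log 0.95| = (1−p)·log 1.05, i.e. p = log(1.05)/(log(1.05) − log(0.95)) ≈
0.4875 — slightly below one half because the up- and down-steps are equal on
the raw scale but not on the log scale. Simulated long-run success against
i.i.d. log-normal reaction times lands at 48.7–48.8 %, within the ±3
percentage-point tracking band around 50 % that such 1-up/1-down procedures
target. Because the staircase is strongly self-correcting, the success count
over 10⁴ trials is nearly deterministic (it varies by only a few trials
across seeds).

## Valuation and choice model

Subjective value is hyperbolic, V = r/(1 + κD), with the immediate option at
D = 0 worth its face value. Losses enter as **negative outcomes**, so a
single formula serves both conditions and reproduces the observed sign
structure: a steeper discounter finds a delayed loss *less* aversive, so
higher κ produces more delayed loss choices — the discounted choice in that
condition. For reporting, loss-condition values are also exposed as absolute
magnitudes (a larger absolute subjective value = a larger prospective loss).

Choices follow a two-option softmax with exponent V/β. It is computed as a
logistic of the value difference (log-sum-exp algebra), which makes it
overflow-safe and exactly shift-invariant; per-trial likelihoods are floored
at 10⁻³⁰⁰.

### Parameters

| parameter | meaning | unit | bounds | default rationale |
|---|---|---|---|---|
| κ | discount rate | 1/week | [0, 10] | delay is fixed at 2 weeks, so κ is reported per week; 10 is far above the steepest trial's indifference rate (2/week at ratio 0.2) |
| β | choice noise | dimensionless | [10⁻⁴, 1] | floor keeps 1/β finite; the cap matches the estimation convention for this task |
| D | delay | weeks | fixed 2 | stored on each trial; configurable per trial object |

The indifference rate for a ratio r is (1/r − 1)/D: 2.0, 0.75, 1/3, 0.125 per
week for the four ratios. Cohort-typical κ values (≈0.3/week) therefore sit
near the ratio-0.6 indifference point, which is why most simulated choices
are patient and per-session information about κ is limited.

### Estimation

(κ, β) are fitted per participant and condition by constrained maximum
likelihood: bounded L-BFGS-B from 10 seeded starts (one anchor at
(0.3, 0.3), the rest log-uniform in κ and uniform in β). Multi-start matters
because the two-parameter likelihood of 32 binary choices is flat or
multi-modal for extreme choosers. Trials without a recorded decision are
excluded from the likelihood. Estimates within 10⁻³ of a bound are
boundary-flagged: an all-patient or all-impatient session identifies κ only
up to a half-line, and downstream analyses can exclude such participants (the
no-variability exclusion). Model comparison against exponential or hyperboloid
discounting is deliberately out of scope — with a single delay the
alternatives are not distinguishable.

Correctness of the optimiser is checked two ways: fitted NLL must not exceed
the minimum of an independently coded 200×200 (κ, β) grid search on any
tested session (tolerance 10⁻⁶ nats), and κ must be recovered from synthetic
cohorts (below).

## Synthetic cohorts

The generator reproduces the study conditions so every pipeline stage is
testable without data: 30 participants × 2 conditions × 32 trials.

- **κ marginals** are log-normal — non-negative and right-skewed, as required
  by SDs exceeding means (reward 0.33 ± 0.48, loss 0.30 ± 0.32 per week) —
  moment-matched on the natural scale, with the log-scale cross-correlation
  chosen to reproduce the natural-scale correlation of 0.56 between reward
  and loss κ. Infeasible moment/correlation combinations raise immediately.
- **β** is truncated-normal on [10⁻⁴, 1] (0.38 ± 0.41 reward, 0.39 ± 0.39
  loss, parent-scale parameters).
- **Missed decisions** occur at rate 0.0156 (≈30 of 1920 trials).
- **Decision RTs** follow the linear structure intercept ≈ 1043 ms + ratio
  slope ≈ 242 ms (reward offset ≈ −35 ms), with independent per-subject
  intercept/condition/ratio effects (SDs 167/181/279 ms) and residual SD
  ≈ 300 ms, truncated to [200, 3000] ms. The random effects are drawn
  independently; their mutual correlations are not reproduced — the package
  needs realistic RT marginals, not an RT process theory, so no
  sequential-sampling model is used.
- **MID RTs** are per-subject log-normal: subject medians normal around
  240 ms (SD 19 ms) and a log-scale SD equal to the residual coefficient of
  variation (≈0.20, i.e. ≈47 ms at the mean).
- **BIS-15 subscales** are truncated normals at the subscale level
  (9.50 ± 2.81, 10.83 ± 2.29, 8.73 ± 1.64 on [5, 20]); item-level reverse
  coding is not modelled, and the total is the subscale sum.
- An optional point mass of non-discounters (κ ≈ 0) can be mixed in to
  emulate the roughly one-third of participants who never choose the
  discounted option; it is **off by default** so recovery calibration sees a
  continuous κ distribution.

One global seed fans out through `SeedSequence` substreams (population draw,
then one stream per session), so any session is reproducible in isolation and
identical seeds yield byte-identical output tables. Each participant reuses
one presentation-order permutation across both sessions, and session order is
counterbalanced.

**What passing tests show — and don't.** The generator samples choices from
the same softmax family the estimator assumes, so recovery results certify
the estimation machinery, not the model's adequacy for human data. Real
cohorts bring model misspecification (non-hyperbolic discounting, sequential
dependencies, attention lapses) that these tests cannot surface.

### Recovery calibration

On a 30-participant cohort the Spearman correlation between true and
recovered κ (both conditions pooled) is ≈0.85 at 32 trials per session,
rising monotonically through 128 to 512 trials while the median absolute κ
error shrinks; recovered κ correlates ≥ 0.85 (Pearson) with the
discounted-choice count among participants with choice variability in both
conditions. These sizes (30 × {32, 128, 512}) keep the full calibration under
about a minute and are fixed in `tests/test_acceptance.py`.

## Behavioural statistics

Discounted-choice counts and the per-participant × condition × ratio relative
frequencies (missing trials dropped from numerator and denominator) are
produced as the exact long tables a mixed model of the form
`relative_frequency ~ condition + ratio + (condition + ratio | subject)`
consumes; the mixed models themselves are routine and left to standard
software. Pearson correlations carry Fisher-z 95 % intervals (r = 0.56 at
n = 30 gives [0.25, 0.77]); paired t-tests use df = n − 1 with t = 0, p = 1
by convention for identical samples and an error for degenerate
constant-nonzero differences.

### Power

`power_correlation` offers four methods: **exact** (numerical integration of
the exact sampling density of r under bivariate normality; the reference),
**nct** (noncentral-t approximation with noncentrality ρ√n/√(1−ρ²), df = n−2
— the convention of common power software), **fisher** (normal approximation)
and **montecarlo** (seeded simulation). At n = 30, α = 0.05 one-tailed, the
exact method gives 0.948 for ρ = 0.55 and 0.705 for ρ = 0.39, while the nct
convention gives 0.970 and 0.732 — conventional power-software figures of
"96 %" and "73 %" for these inputs sit between the two conventions, so the
method is an explicit argument and no default is silently reported.
`power_paired_t` is the standard noncentral-t computation (d = 0.3, n = 30,
one-tailed: 0.484). Both reduce to α at zero effect and are monotone in
effect size and n (property-tested).

## fMRI event tables

Per session, regressors of interest are the decision phase (duration = that
trial's RT) and the anticipation cue (fixed 6 s); button presses, the flash
(0.05 s) and feedback (1.5 s) are non-interest events. Missed-decision trials
become a single `missed_dummy` event spanning the decision window and
contribute no anticipation events (no option was chosen and cued).
Subjective-value modulators attach to the relevant rows: `sv_diff` =
|V(immediate) − V(delayed)| on decision events (small = difficult, near
indifference) and `sv` = the chosen option's value on anticipation events,
absolute-valued for losses. Both raw and within-session mean-centered columns
are written, since analysis environments differ in whether they center
parametric modulators. Choice-split regressors
(`decision_immediate`, …) are produced unless the session has fewer than 6
discounted choices (the 20 % criterion), in which case an exclusion flag is
returned instead of a table.

Files are BIDS-style `events.tsv`, onsets in seconds from the first trial
onset, numeric columns rounded to 4 decimals **before** writing so a
write/read cycle is an exact round trip; missing values are `n/a`. HRF
convolution, design matrices and GLM estimation are out of scope.

## Numerical and degenerate-input conventions

- Softmax arguments are clipped at ±709 before exponentiation; likelihood
  floored at 10⁻³⁰⁰/trial.
- Cent rounding floors with a 10⁻⁹ guard against binary-float artefacts
  (so 1.00/0.2 yields exactly 5.00, not 4.99).
- β below the floor is clamped with a warning in direct probability calls and
  hard-bounded in optimisation.
- All-missing sessions, zero-variance correlations, constant-nonzero paired
  differences, empty grids and mixed-condition grids raise typed errors
  rather than returning NaNs.

## Known limitations

- A single fixed delay means κ is only weakly identified per 32-trial
  session; estimates lean on the four indifference points the ratios define.
  Boundary flags, the no-variability exclusion and the recovery calibration
  quantify (rather than remove) this limit.
- The simulated RT model is descriptive (linear/log-normal marginals), not a
  process model; random-effect correlations are not reproduced.
- The loss condition models losses as negative amounts against fixed
  balances; framing effects (whether participants experience the task as
  losing vs. winning less) are outside the model.
- Hierarchical/Bayesian estimation and alternative discount functions are
  out of scope by design.
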