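# Methods

## Model structure

The engine is a six-state Markov cohort model of post-revascularization
coronary disease: Stable, RepeatCABG, RepeatPCI, CVA (stroke), CADDeath and
OtherDeath, with both death states absorbing. One arm is simulated per
strategy (CABG, PCI-with-drug-eluting-stent); the whole cohort enters the
arm's Stable state at age 59 and advances in 6-month cycles.

The base-case table prints, per arm, the six per-cycle probabilities out of
the Stable state; the two printed rows sum to 0.9997 (CABG) and 0.9996
(PCI). Each row is renormalized by its sum at matrix-construction time,
preserving the printed ratios while giving a valid stochastic matrix (the
correction is logged at debug level). The remaining rows are derived:

- **Repeat-procedure states are one-cycle tunnels.** The table gives no
  outgoing probabilities for them, so the RepeatCABG row equals the CABG
  arm's Stable row and the RepeatPCI row the PCI arm's, in both matrices.
  After one cycle in the repeat state the cohort rejoins the arm's Stable
  dynamics.
- **CVA survivors return to Stable.** The CVA row carries the printed
  post-stroke coronary mortality (0.074) and background mortality (0.004);
  the remainder (0.922) returns to Stable.
- The printed "coronary death after stable" probability (0.009) is loaded,
  validated and sampled like every other ranged entry but does not enter
  the matrix: the per-arm Stable rows already carry their own coronary
  mortality, and the construction contract derives the Stable row solely
  from those six entries. Its tornado swing is therefore structurally zero.
- Background mortality is the constant printed value, not age-indexed; no
  life table is available at this granularity.

## Rewards and discounting

Living states accrue a per-cycle utility (instrument-specific: SAQ or
SF-36) and a per-cycle cost in USD on the occupancy at cycle start, cycle 0
included; there is **no half-cycle correction by default** (the source
analysis does not state its convention), but a flag switches recurring
accrual to the average of cycle-start and cycle-end occupancy. Death states
carry zero recurring reward; entering one charges that state's one-time
cost on the newly absorbed cohort fraction, discounted at the end of the
transition cycle. Both streams discount at `(1 + r)^(−k·0.5)` with `r` the
annual rate (default 3%).

**Horizon.** The published analysis never states its model horizon. The
default is 30 cycles (15 years): the published QALY totals divided by the
stable-state utilities imply roughly 25 discounted stable-cycle
equivalents, and 30 cycles of the fitted dynamics reproduce that order of
magnitude. This is a calibration, not ground truth; consequently the
package treats the published *absolute* QALY/cost levels as
non-reproducible and asserts only their ratio arithmetic (computed from the
printed inputs) and sign-level agreement (CABG more effective, cheaper,
dominant under both instruments), which hold at the default and are
insensitive to the horizon over a wide range.

## Decision statistics

Incrementals are CABG − PCI. ICER = ΔC/ΔE with dominance flags evaluated on
unrounded deltas (dominant ⇔ ΔC < 0 and ΔE > 0); ratios are *reported*
rounded to integer USD/QALY. ACER = C/E requires E > 0. The threshold rule
classes an intervention cost-effective iff ICER < 3 × GDP per capita
($8,329 in 2012, threshold $24,987/QALY), with dominance short-circuiting;
an undefined ICER (ΔE = 0 without dominance) is conservatively classed
above-threshold, since the four-value verdict set has no "undefined" member.

The net-monetary-benefit sample-size formula is exposed with a `z_term`
switch: the formula as printed leaves the z-sum (1.64 + 1.28) unsquared and
yields 69 per group, inconsistent with the study's recruitment of 215 per
arm; the conventional squared form yields 201, consistent with it. Default:
squared; both are computed in the tests.

## Sensitivity analysis

**One-way / tornado.** Each ranged parameter is set to its low and high
bound (all else at base case; probability bounds clamped to [0, 1], e.g.
the printed 1.04236 upper stability bound; renormalization reapplied) and
the incremental NMB at the reference willingness-to-pay ($24,987/QALY)
recorded; entries sort by absolute swing. The published claim that no
single-parameter excursion changes the verdict is checked as a soft report
(a warning on any flip), since it is a property of the calibrated model,
not of the arithmetic.

**Probabilistic.** Distributions are moment-matched with sd = range/3.92
(ranges read as 95% CIs): gamma (shape = (mean/sd)², scale = sd²/mean) for
costs; beta for probabilities and utilities. Utility entries whose support
leaves [0, 1] — the negative repeat-CABG-after-PCI utilities — are affinely
rescaled onto their own (low, high) before beta fitting and mapped back on
sampling, so the analytic mean always equals the table value (enforced to
1e−9 in tests). A degenerate range yields a fixed (point-mass) spec. Each
trial draws every ranged parameter, rebuilds both matrices and reruns both
arms. Randomness uses one `SeedSequence.spawn` child per trial, so trial
*i* is bit-reproducible independently of the total trial count. The CE
acceptance region is operationalized as positive incremental NMB (the
dominant quadrant plus the below-threshold northeast quadrant); the CEAC at
a single WTP equals the acceptance fraction by construction. At the default
calibration the 5,000-trial acceptance fraction at $24,987/QALY is
effectively 1.0, comfortably consistent with the reported ">85% of trial
points"; this is reported, not hard-asserted, given the horizon ambiguity.

## Questionnaire scoring and QALYs

SF-36 (8 dimensions) and SAQ (5 dimensions) are scored 0–100 per dimension;
the summary is the unweighted mean (no weights are published) and the
utility mapping is linear, summary/100. This mapping is a package
convention: the source reports no valuation tariff, and its per-state
effectiveness values are already on a 0–1-like scale (one is negative,
which the model accepts). The scoring path exists for the synthetic-cohort
round trip; the Markov model consumes the packaged per-state utilities
directly. Discounted QALY gains use
`Qi·(1−e^(−r·Li))/r − Q·(1−e^(−r·L))/r`, with the analytic limit
`Qi·Li − Q·L` below r = 1e−9 (continuity at 0 is tested to 1e−6).

## Costing

Four categories in 2014 USD (26,509 rials/dollar): hospitalization,
medication, travel/hotel, lost productivity. Lost productivity is
`days × $311 / 26` (the 2014 min–max wage midpoint over 26 working days).
Medication present value doubles the six-month bill to an annual cost and
discounts 10 annual payments at 3%; payments default to year starts
(annuity-due, factor 8.786) with an in-arrears flag. Reporting rounds
totals to 1 decimal and per-capita to 2; internal arithmetic is unrounded.
Two published per-capita cells (321.74, 96.32) are truncations rather than
roundings; the package rounds and documents the ≤ 0.01 discrepancy. The
published model costs and the observed ledger totals are kept as separate
surfaces (they differ and even reverse the arm ordering in the source); the
package does not force agreement.

## Synthetic cohort

The generator replaces the study's raw hospital records with draws matching
the published marginal structure — arm sizes 210/200, age 60.23±12.53 /
58.65±11.19 (normal, truncated ≥ 18), length of stay 8.05±5.438 /
3.19±2.843 days (gamma, truncated ≥ 0.5 days with the scale recalibrated so
the truncated mean still hits the target), per-capita billing targets from
the published ledger (gamma marginals: billing data are nonnegative and
right-skewed). Billing dispersion is not published; the coefficient of
variation is fixed once at 0.5, a realistic spread for hospital bills.
Questionnaire dimensions are logit-normal on [0, 100] (per-dimension logit
sd 0.6), with the pre-treatment summary centered at the scale midpoint (50)
and the post-treatment target offset by the arm's stable-state utility, so
the mean post−pre utility gain recovers the table value. Lost productivity
is *derived* from the drawn length of stay through the wage formula — an
exact identity, tested as such. Sex/diabetes/hypertension flags follow the
published shares but drive nothing (the model attaches no covariate
effects). What the generator does **not** emulate: within-patient
correlation beyond the stay→productivity link, follow-up events (the Markov
model is parameter-driven, not fitted to these records), item-level
questionnaire structure. Passing round-trip tests therefore demonstrates
pipeline correctness and calibration, not validity on real patients.

At n = 10,000/arm every calibrated mean is recovered within 5% (tested over
multiple seeds); at the study's own n (210/200) errors of a few percent to
~15% on the smallest targets are expected sampling noise.

## Numerical choices and problem sizes

Matrix stochasticity is enforced to 1e−9 (rows), occupancy conservation
tested to 1e−10 against an explicit matrix-power oracle for horizons ≤ 100.
Distribution-fit means are exact to 1e−9 by construction. The default test
suite runs the full 5,000-trial PSA once (a few seconds; each trial is two
30-cycle 6×6 cohort runs) and two 10,000/arm cohort generations; unit-level
sensitivity tests use 6–10-cycle horizons to keep the suite fast.

## Known limitations

- Cohort-level (not microsimulation) dynamics; no age-dependent or
  parametric survival extrapolation.
- A single Stable state per arm: after a repeat procedure the cohort
  follows its arm's Stable dynamics, not the repeated procedure's.
- No correlation structure in PSA sampling (none is published) and no EVPI.
- The score→utility mapping is a documented convention, not an estimated
  tariff; results using it enter only the synthetic round trip.
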