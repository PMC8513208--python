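# Methods

## Model

Each decision-making unit (a country's health system) is a two-division
network observed over three periods.  Division inputs/outputs, the
within-period links and the between-period carry-overs are declared per
variable (`VariableSpec`), so the engine is generic in the network shape;
the shipped schema is:

| division | inputs | outputs | links out | carry-over |
|---|---|---|---|---|
| public health | alcohol, tobacco | HALE | immunisation, breast and cervical screening → medical care | infant mortality (bad) |
| medical care | CT devices, health employment | discharges, consultations | — | cancer incidence (bad) |

The efficiency measure is input-oriented and slacks-based: the score of a
(division, period) cell is one minus the average of its normalised excess
slacks — own inputs, received as-input links, and bad carry-overs, each
divided by the observed value — and the overall score is the
period/division weighted average of the cells.  Because the measure is
built from slack/observation ratios it is invariant to the units of every
variable, and because the four score families are read off one optimal
slack allocation, the aggregation identities (overall = weighted mean of
cells, etc.) hold to machine precision by construction.

The program is a plain LP (the input-oriented objective needs no
fractional transform) solved with HiGHS through
`scipy.optimize.linprog`.  With 7 DMUs × 2 divisions × 3 periods an
instance has 42 intensity variables and ~30 slacks; solves take
milliseconds.

## Defaults and why

* **Weights** `W^t = 1/T`, `w^k = 1/K` (uniform).  Both divisions are
  treated as equally important parts of the system; weights are exogenous
  and configurable.
* **Returns to scale** CRS by default; VRS adds one convexity constraint
  per (division, period).  VRS scores weakly dominate CRS scores
  (feasible-set inclusion), which the suite checks.
* **Link handling.**  The three preventive-service links are treated
  `as_output` of public health (they are goods the public-health division
  supplies), with the cross-division continuity tie
  `Z λ_emitting = Z λ_receiving` enabled.  `as_input` mode (excess charged
  to the receiving division and entering its objective term) is retained
  and tested, because a consuming-division reading of the link constraint
  is equally defensible; the constraint is attached to the *receiving*
  division's intensities in that mode.
* **Carry-over timing** `start_of_interval`: the value observed at period
  t forms the (t, t+1) carry-over, reflecting that a stock like infant
  mortality affects the next period with a delay.  The final period's
  observation is unused by default (`terminal_carryover="ignored"`); an
  optional `last_period_bad_term` adds it as a bad-excess term in the
  final period.
* **Carry-over classes**: infant mortality and cancer incidence are `bad`
  (their excesses penalise the score).  `good`, `free` and `fixed` classes
  are implemented for generality.
* **Carry-over continuity** `Σ_j z_j^{(t,t+1)} λ_jk^t = Σ_j z_j^{(t,t+1)}
  λ_jk^{t+1}` is included by default: it is what makes the periods of one
  DMU a single dynamic problem rather than T independent ones.  It is
  switchable (`carryover_continuity=False`) for sensitivity analysis.
* **Objective denominators** count only the division's own inputs,
  received as-input links and bad carry-overs (`m_k + linkin_k + nbad_k`);
  a division with none of these contributes the constant 1.  The
  denominator is constant across periods even where a period has no
  carry-over slack (the final period under start-of-interval timing), so a
  cell score is always an average over the same term count.
* **Slack tie-breaks.**  The optimal score is unique but the slack
  allocation need not be; the default reports the solver's optimum.  A
  diagnostic secondary pass (`slack_tiebreak="max_total_slack_then_report"`)
  re-solves at the fixed optimal score maximising total slack.
* **Rounding** only happens in the reporting layer (scores 4 decimals,
  Malmquist components and percent changes 2); the library never rounds.

## Malmquist productivity

The index is computed per division from standalone single-division
slacks-based distances on period cross-sections (links and carry-overs
excluded by default, so each division's index is self-contained):
CU = E¹(1)/E⁰(0), FS = √([E⁰(1)/E¹(1)]·[E⁰(0)/E¹(0)]), MI = CU·FS.  The
overall index is the geometric mean across divisions — on the published
two-division rows this reproduces the printed overall MI (e.g.
√(1.40 × 1.04) = 1.21) — and the comparison is the direct first-vs-last
period pair, not a chained index.  The published table's *overall* CU and
FS columns do not satisfy MI = CU × FS nor the geometric-mean relation
under any aggregation we could verify; the package reports divisional
CU/FS plus their geometric means and documents the divergence rather than
reproducing those two columns.

Mixed-period slacks-based programs can be infeasible (an input-oriented
frontier may be unable to reach an observation with strictly smaller
inputs).  Infeasible components are flagged with a warning and dropped
from the geometric means; if both frontier-shift ratios are infeasible the
index is reported as NaN.  This is more conservative than switching to a
radial distance for the cross-period step and keeps one efficiency concept
throughout.

## Outlier screen

Tukey fences with k = 1.5 and linear-interpolation quartiles, computed per
(variable, period) over DMUs; a DMU is removed if flagged anywhere (union
rule).  Both k and the removal rule are deliberate choices documented in
the run log; the union rule is what produces a drastic reduction (13 of 36
units in the published analysis) from per-indicator flags.  Summary
standard deviations use the population (divide-by-N) form, which exactly
reproduces the published reduced-sample value 0.0738 from the printed 23
scores.  Fewer than 4 DMUs yields a warning and no flags.

## Density-equality test

Integrated squared difference between Gaussian KDEs of the two score
samples, with one shared Silverman bandwidth from the pooled sample
(floored at 1e-3), reflection at the upper boundary 1, and the point mass
at exactly 1 spread deterministically just below the boundary before
testing.  The p-value is a bootstrap under the pooled null (both
pseudo-samples redrawn from the pool, bandwidth held fixed), with the +1
correction, so it is reproducible bit-for-bit given the seed.  Monte-Carlo
calibration in the suite: the 5%-level type-I error over 200 seeded
replicates (n = 80 per sample, 199 bootstrap reps) falls in [0.02, 0.08],
and samples with disjoint bulks are rejected in >95% of replicates.

## Synthetic generator

`generate_panel` plants `n_frontier` identical copies of one anchor
observation (mutually non-dominating by identity, hence scoring exactly 1
under CRS and VRS) and inflates the inputs and bad carry-overs of the
remaining units by factors exp(|N(0, scale)|) ≥ 1, one factor per
(DMU, division, period).  Dominated units therefore have strictly positive
feasible slacks and score < 1 under CRS, and the planted inefficiency
depth is recoverable (Spearman correlation between mean inflation and
1 − score above 0.9 at the default n = 20, scale 0.3).  Indicator
envelopes default to the published per-year min/max ranges.

What the generator does **not** emulate: realistic co-movement of
indicators over time, country-specific trends, measurement error, or a
multi-point frontier (copies of a single anchor avoid the possibility of
sampled "frontier" points dominating each other under a slacks-based
measure).  Passing recovery tests therefore demonstrates correctness of
the scoring machinery, not calibration to real OECD dynamics.

## Embedded data

The seven-country × three-period panel (twelve model variables at printed
precision, plus the OECD-average column stored as a non-DMU reference row
that never enters a frontier) is embedded in `dndea.panel`; health
expenditure is printed alongside the source tables but is not a model
variable and is not included.  The re-keyed published 36-country score
tables live in `dndea.reference` and support exact arithmetic checks only
— the model itself cannot be re-run on 36 countries without an OECD
extract, which users can supply as a long CSV.  Period labels are opaque
ordered tokens: the engine never computes calendar gaps.  In the published
CRS/VRS tables the Estonia row prints eight numbers where nine cells are
expected; the re-keyed tables take the first number of each three-column
group as the overall column, a reading confirmed by the 2000 column means
(0.8801 CRS, 0.9320 VRS).

## Problem sizes and determinism

The test suite and the acceptance script run the fixture (7 DMUs), small
random networks (≤ 3 DMUs, ≤ 2 divisions/periods) against a brute-force
LP oracle, 20-DMU synthetic recoveries, and 200-replicate Monte-Carlo
calibrations; everything is seeded and completes in about a minute on one
CPU.  Two pipeline runs with the same config and seed produce
byte-identical artifacts.

## Known limitations

* Output-oriented and non-oriented variants, super-efficiency and weight
  restrictions are out of scope.
* Mixed-period infeasibility can leave Malmquist aggregates undefined on
  small panels (reported as NaN with a count of dropped units).
* The box-plot screen is single-pass; it does not re-screen after
  removal.
* The density test's published-scale statistic depends on unrecoverable
  implementation details (kernel, bandwidth, inputs), so only its
  calibration — not a printed statistic value — is validated.
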