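# Methods

## Model structure

The package models two strategies for SAH patients whose initial
CTA + DSA found no aneurysm.  A short-term decision tree resolves the
diagnostic pathway at time zero; a four-state Markov cohort model
(at-risk, favorable, unfavorable, dead — the outcome states follow the
modified Rankin Scale grouping 0–2 / 3–5 / 6) then runs in one-year
cycles from the cohort start age (default 55) to `stop_age` (default
100, with the terminal cycle forcing background mortality to 1 so the
horizon is computably "lifetime").  Perspective is the UK NHS; all
costs are 2020 GBP; costs and QALYs are discounted at 3.5%/year.

Decision tree, no-repeat arm: a fraction `prevalence_aneurysm` (0.173)
enters at-risk; the rest split per the no-aneurysm outcome distribution
(0.8708 favorable / 0.0792 unfavorable / remainder dead).  No upfront
cost.  Repeat-CTA arm: everyone pays the 7-day pre-imaging stay
(7 × £380.75) plus the CTA (£331); test-positives (sensitivity 0.98
among aneurysm carriers, 1 − specificity among the rest) pay a
confirmatory DSA (£1,919); confirmed aneurysms are repaired electively
(coiling/clipping cost mix, default 50/50 — the source gives both
prices but no mix, so symmetric ignorance is assumed and the fraction
is sweepable over [0, 1]) and enter per the elective outcome split
(0.51/0.34/0.15); false negatives stay at-risk.  DSA specificity is
fixed at 1, so false positives incur only the DSA cost.

Markov cycles: at-risk patients re-bleed with the schedule probability
for that year since presentation; re-bleeders pay the emergency repair
cost (coiling/clipping mix) in that cycle and split per the re-bleed
outcome distribution.  The published re-bleed triple (0.0752, 0.3948,
0.4700) does not sum to 1; the base case uses favorable/unfavorable as
printed with death as the remainder (0.5300), while the PSA Dirichlet
keeps the printed concentrations verbatim.  Non-re-bleeding at-risk
patients face background mortality only and carry utility 0.60 and no
cost.  Favorable and unfavorable patients die at the annual rates read
from the first two elements of the "state mortality" triple (0.1067
and 0.7778; the third element is a residual kept only so the Dirichlet
draw is well-formed), combined with the age-indexed life-table hazard
as independent risks, `1 − (1 − p)(1 − qx)`.  Alternatively a full
3×3 outcome-state matrix (from/to/prob CSV) may be supplied, which
also permits favorable↔unfavorable moves.

## Accounting conventions

* State rewards (utilities; nursing cost on the unfavorable state)
  accrue on end-of-cycle occupancy, discounted with exponent equal to
  the cycle index (first cycle t = 1).
* Upfront decision-tree costs sit at t = 0, undiscounted.
* A re-bleed's emergency cost is discounted at the cycle in which it
  occurs.  Survivors' outcome-state rewards begin the **following**
  cycle (a one-cycle zero-reward tunnel).  The alternative — earning
  the new state's full annual reward in the re-bleed cycle itself — is
  available via `rebleed_reward_same_cycle`, but is not the default:
  because annual unfavorable mortality is 0.7778, an immediate full
  nursing year would make a re-bleed-to-unfavorable transition several
  times more expensive than an identical state entered at time zero,
  and with that asymmetry no re-bleed schedule lets the two arms'
  incremental cost and incremental QALYs carry the signs and
  magnitudes of the published comparison.
* Half-cycle correction is off by default and available as a flag
  (rewards then use the average of pre- and post-transition occupancy).
* A cohort run stops early once living mass falls below 1e−9; traces
  maintain occupancy sums within 1e−9 of 1 with non-decreasing dead
  mass, which the test suite fuzzes across randomized configurations.

## Synthetic stand-in inputs

Three tabular inputs of the original analysis come from supplementary
or external sources that are not shipped.  `sahcea.fixtures` generates
documented placeholders, each emitted with a `source: fixture` header;
replication against the real tables is a supported user path via the
CSV loaders, not a packaged asset.

* **Life table** — Gompertz hazard `qx(age) = min(1, a·e^{b·age})`
  with a = 2.3e−5, b = 0.095, closed at age 110.  An adult-mortality
  shape of the right order for a high-income population; not a
  national life table.
* **Re-bleed schedule** — 10 annual probabilities, front-loaded and
  declining (0.58 in year one, geometric decay floored at 0.16), with
  a constant tail thereafter.  The shape family (front-loaded,
  declining, constant tail) was fixed a priori; its three parameters
  were calibrated once against the published base-case cost/QALY
  table and then frozen.  This is the single strongest assumption in
  the package: the schedule is *not* the unpublished cohort data, and
  every replication-grade number depends on it.
* **Outcome transition matrix** — the default-mode matrix implied by
  the state-mortality triple (no favorable↔unfavorable moves).

Because the stand-ins reproduce the published *economics* (increments
and ICER) rather than the unpublished *inputs*, passing replication
checks shows internal consistency of the model logic, not that the
original supplementary values were recovered.  Under these inputs the
per-strategy cost and QALY levels sit roughly 15% below the published
table — the QALY levels are bounded structurally: with annual
favorable-state mortality of 0.1067 and the printed utilities, the
repeat arm's lifetime QALYs cannot exceed ≈4.17 under *any* re-bleed
schedule, versus 4.939 published — while the incremental cost,
incremental QALYs and ICER agree to within about 10%.

## Probabilistic sensitivity analysis

Exactly the parameters with a published distribution are drawn:
Beta for probabilities and utilities, Gamma for costs, Dirichlet
jointly for each outcome triple; age, discount rates, length of stay
and the no-re-bleed utility stay fixed.  All published cost
distributions share Gamma shape 144, i.e. sd = mean/12
(`derive_gamma_spec`); the 7-day stay is drawn as one block and
divided by the length of stay, matching the published rate for that
row.  Draws are independent across fields, consumed from a single
seeded `numpy` Generator in a documented fixed order, so a seed fully
determines the result.  The distributions are reproduced verbatim even
where their means disagree with the base-case column (prevalence,
CTA specificity, the utilities); `audit_distributions` tabulates these
known mismatches rather than failing.  Note that the published
Dirichlet concentration triples sum to ≈1, which makes their draws
extremely dispersed (mass near the simplex vertices); this materially
widens the acceptability-curve spread relative to the published curve,
and is the main reason the PSA probability at £20,000/QALY computed
here is lower than the published one.

The CEAC assigns each iteration to the strategy with the strictly
larger net monetary benefit, splitting ties equally, so the two
probabilities sum to 1 at every threshold.  The default WTP grid is
£0–50,000 in £1,000 steps.

## Deterministic sensitivity analysis

One-way sweeps hold everything else at base case.  Published ranges
are used where they exist (age 50–80, prevalence 5–35%, CTA accuracy,
the utilities, nursing cost); costs default to ±25% of base.  Simplex
components are swept with complementary renormalization (the remaining
shares rescale proportionally onto 1 − v); sweeping a component to its
current value is an exact identity, so sweeps reproduce the base-case
comparison bit-identically at the base point.  Sweeping age shifts the
life-table lookup and the remaining horizon and nothing else.

Threshold search bisects `g(x) = ΔC − λ·ΔQ` (the negated NMB), whose
root coincides with ICER = λ whenever ΔQ ≠ 0 and whose sign encodes
dominance consistently; a 33-point scan brackets sign changes first,
multiple crossings are resolved toward the base-case value and
flagged, and bisection stops when the interval is below 1e−4 relative
to the parameter scale.

## Validation

An individual-level microsimulation (`microsim_oracle`) re-implements
both strategies by direct sampling of every branch and transition
under the same accounting conventions, sharing no propagation code
with the cohort engine; the suite requires agreement within 3
Monte-Carlo standard errors at n = 200,000 on the base case and on
five PSA-drawn parameter sets.  Closed-form checks pin the engine to
the geometric-series total for a single living state with constant
hazard (1e−9 relative), and degenerate-input checks cover an
uninformative repeat test (arms must then differ only by the stay+CTA
cost), all-dead entry, zero utilities and zero discounting.

## Problem sizes

The default analyses use a 45-cycle horizon (ages 55–100),
5,000 PSA iterations, 200,000 microsimulation trajectories for oracle
comparisons, and 200-point grids for sweep-consistency checks; the
full suite and the reproduction script each complete in well under a
minute on one CPU.

## Known limitations

* The re-bleed schedule and life table are calibrated fixtures, not
  data; absolute cost/QALY levels inherit their uncertainty.
* The meaning of the published state-mortality Dirichlet triple is
  ambiguous; the annual-death-probability reading adopted here is one
  of several defensible ones, and the matrix mode exists precisely so
  users can substitute the real follow-up transition table.
* No correlation between PSA parameters (beyond within-Dirichlet
  structure); no value-of-information analysis; at most two strategies
  per comparison; no individual heterogeneity in the cohort engine.
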