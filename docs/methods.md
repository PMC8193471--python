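# Methods

## The monitoring engine

The engine treats intrapartum decision support as a total function
from a finite scenario space to action sets. Two layers are kept
deliberately separate:

1. **Observation classification.** Each of the six monitored
   parameters has a classification map from a raw value to a named
   state. Continuous parameters use ordered bins (`below` = strict
   upper bound, `upto` = inclusive, trailing catch-all); categorical
   parameters use a label → state map. Defaults follow WHO intrapartum
   norms: FHR 110–160 bpm normal, systolic BP < 140 mm Hg normal
   (< 90 flagged hypotensive), 3–5 contractions per 10 min adequate,
   active-phase dilatation ≥ 1 cm/h adequate, fetal station ≥ 0
   (engaged and descending) normal in the second stage. Monitoring
   intervals default to 30 min for FHR, contractions and second-stage
   station, and 4 h for BP, dilatation and fluid review; the loader
   restricts intervals to {30, 60, 120, 240} minutes. All of this is
   configuration, not clinical truth: the YAML ruleset is the contract
   and any value can be overridden.

2. **Scenario management.** A patient scenario is one point in the
   Cartesian product of categorical factors. The default factorization
   is amniotic status (3) × FHR pattern (4) × cervical progress (4) ×
   contraction adequacy (4) × blood pressure (2) × fetal descent (3) =
   1152 scenarios. The published description of the algorithm fixes
   only this total and the three amniotic strata, so the remaining
   cardinalities are a reconstruction; the loader asserts the product
   against a named config flag (`meta.expected_scenario_count`) that
   can be nulled to load alternative reconstructions.

   Recursive abnormality management is encoded *statically*: instead
   of simulating re-examination over time, each factor distinguishes
   "responding/recovered" states (first-line management succeeded)
   from "persistent/arrested" states (it failed). This makes the whole
   logic a finite pure function that can be enumerated and property-
   tested exhaustively — determinism, coverage, the ≤ 16-action cap
   and monotone escalation are each checked over all 1152 scenarios.

   The final decision tier is the maximum over per-abnormality
   outcomes (routine < escalate < deliver), and the tier action sets
   are cumulative (`deliver ⊇ escalate`), which together with
   set-union rule aggregation guarantees monotone escalation: adding
   an unresolved abnormality can never remove an escalation or
   delivery action.

   The 22 action labels in the default catalog are authored here (the
   original catalog text is unpublished); every statistic depends only
   on action ids, so labels are cosmetic. Rule action sets were chosen
   so the worst-case scenario unions to 15 ≤ 16 actions.
   `meta.active_phase_start_cm` (default 5) records the recommended
   partograph starting point as metadata; it does not affect
   enumeration.

## Sampling design

Validation cases are drawn by stratifying the scenario space on
amniotic fluid status (membranes intact / fluid clear / opaque or
foul; 384 scenarios each under the default ruleset) and sampling
uniformly without replacement within each stratum — default two per
stratum, six cases total. The original study used an external online
random number generator; here a seeded partial Fisher–Yates shuffle is
used instead, trading fidelity to the original tool for exact
uniformity and bit-for-bit reproducibility (the seed is recorded in
the sample). Rater dropout is not modeled at the sampler; cases not
answered by every expert are dropped later by completeness filtering.

## Agreement statistics

All statistics operate on a binary rater × case × action selection
matrix (at most `max_select` = 16 of `n_actions` = 22 per block).
Conventions that matter:

- **Consensus weights** are computed from the *human* raters only
  (weight = selecting fraction of k experts), so algorithm-only
  selections carry weight 0. Each human's weighted selection total is
  therefore bounded in [raw/k, raw].
- **Sensitivity is directional** (reference → test) and group scores
  average over *ordered* pairs; `r^selection` is the geometric mean of
  the two directions and hence symmetric. This statistic is preferred
  over kappa/pi here because action selections are strongly
  non-independent, which breaks chance-correction assumptions.
- **FPR denominator** is `n_actions − |reference|` — the actions the
  reference deemed unnecessary — i.e. standard 2×2 contingency
  semantics with the reference as truth. (The published definition
  leaves the denominator implicit.)
- **Undefined scores** (empty reference set, or a reference who
  selected everything for FPR) are flagged `None` and excluded from
  averages with an exclusion count. Imputing 0 would conflate
  disagreement with missingness.
- **Summaries** use the sample SD (n−1) and the t-based 95% CI
  `mean ± t(0.975, n−1)·sd/√n`. This convention is pinned by the
  published per-case rows: it reproduces every printed mean, SD and CI
  bound at print precision (1 decimal).
- **Reliability**: per reference expert, R is the mean of that
  expert's pairwise `r^selection` values over all partners and cases,
  and α = kR/(1+(k−1)R); the overall coefficient is the mean of the
  per-expert α values. Recomputed from the published correlations this
  yields .925/.923/.919/.861/.922 and overall .910.
- **Ranking** compares the sensitivity CI lower border (descending)
  and the FPR CI upper border (ascending); evaluators whose intervals
  overlap on both criteria are reported as statistically
  indistinguishable — which is the published outcome for experts vs
  the algorithm.

### Known discrepancies in the published numbers

Two published quantities cannot be recovered from the printed per-case
values under any standard convention, and are deliberately *not*
reproduction targets:

- the difference-of-means CIs (e.g. "SD 11.0; 95% CI 2.8–21.2,
  P = .01") match neither paired-t, pooled-t nor z intervals computed
  from the printed rows. `difference_of_means` implements Welch's
  unpaired t as a transparent default.
- the SD 0.06 attached to the overall mean correlation 0.67: per-case
  grouping of the printed correlations gives SD ≈ 0.077 and per-pair
  grouping ≈ 0.114. The mean itself reproduces (0.674).

A few printed correlation pairs also differ in the third decimal
between their two directions (rounding artifacts); the fixtures keep
them verbatim and symmetry is asserted only for computed values.

## Synthetic expert panels

The generator emulates the validation design (k = 5 raters, 5 cases,
22 actions, ≤ 16 selections) with a single consensus dial. Per
(case, action) a latent selection probability is drawn as
`p ~ Beta(1/c, 1/c)`; each rater selects independently with
probability p. Large `c` concentrates p at {0, 1} (a shared,
near-deterministic signal → perfect agreement); `c → 0` concentrates p
at 1/2 (independent coin flips → chance agreement). E[p] = 1/2 at
every c, so expected selections per block are n_actions/2 = 11;
blocks exceeding the cap drop their lowest-p selections, a
deterministic rule that preserves high-consensus actions and trims
well under one selection on average at the default settings. A
`fixed_p` override realizes the analytic corner cases (p ≡ 0, p ≡ ½)
exactly. Calibration: concentration ≈ 1.1 produces a mean
`r^selection` ≈ 0.67 — the level observed in the real panel — and,
through the reliability formula, α ≈ 0.91 for k = 5; this is a
self-consistency check of the formula, not a claim that the generator
models real experts.

What the generator does *not* emulate: systematic rater styles
("fast" vs "slow" actors), action–action dependence beyond the shared
latent p, case difficulty heterogeneity, and dropout. Passing
recovery tests therefore show the statistics are implemented
correctly and respond to consensus as designed — not that real expert
panels behave like the model.

## Problem sizes and numerics

The reproduction suite runs entirely from the shipped per-case
fixtures (printed score rows, the 100 pairwise correlations, selection
totals) and the default ruleset — seconds on one CPU. Stochastic
checks use fixed seeds: 10,000 draws for sampling uniformity (each
pair within 3 SE of 1/6), 1000 replicate panels for the selection-mean
check, 200 replicate panels per consensus level (3 levels) for the
α-ordering check. Comparisons against printed values use the printing
precision: ±0.05 on means, ±0.01 on SDs, ±0.1 on CI bounds (1 printed
decimal), ±0.001 on correlations and α (3 printed decimals).
Reported percentages are rounded to one decimal and correlations to
three only at the reporting layer; internal computation is full
double precision.
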