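# Methods

## Model

`tdcea` is a cost-of-illness decision model for travelers' diarrhea (TD) in a
deployed military cohort. A deployment-year produces

    episodes = deployment_size × duration_months × monthly_incidence

independent TD episodes (base case: 50,000 persons × 3.5 months × 0.289
episodes per person-month ≈ 50,575). Each episode resolves through exactly one
of eight terminal care pathways arranged as a two-level decision tree:

| disposition (prob.) | conditional split | unit cost (USD) | unit DDL (days) |
|---|---|---|---|
| outpatient MH treatment (0.30) | suboptimal 0.278 / optimal 0.351 / bed rest 0.371 | 70 / 82 / 104 | 0.70 / 0.37 / 1.60 |
| no MH treatment (0.6907) | run course 0.60 / self-tx success 0.32 / self-tx failure 0.08 | 0 / 0 / 27 | 0.37 / 0.18 / 0.48 |
| hospitalization (0.009) | — | 2,907 | 1.70 |
| medical evacuation (0.0003) | — | 16,938 | 7.00 |

DDL (duty days lost) is the effectiveness unit: time non-mission-capable,
combining latrine time (0.25 DDL per diarrheal day), pre-treatment symptom
duration and post-treatment recovery. The DDL parameter values encode that
derivation chain; the model consumes them as given and does not recompute it.

Cohort burden is the plain expectation: total cost = episodes × Σ pᵢ·costᵢ,
total DDL = episodes × Σ pᵢ·DDLᵢ, and the cost ratio is USD per DDL.
Internal arithmetic is never rounded; reported integers are rounded half away
from zero at the final step only. There is no discounting, no time horizon
beyond one deployment-year, no QALYs, and no transmission dynamics.

Modeling choices where the structure was genuinely open:

* **Self-treatment failure is a terminal leaf** with its own cost ($27) and
  DDL (0.48); it does not cascade into a second outpatient encounter. This
  reproduces the published annual-DDL totals exactly; cost totals then sit
  within 0.2% of the published figures (base case $2,973,006 vs. published
  $2,974,311, a 0.04% residual). The exact published cost accounting for the
  self-treatment arm is not recoverable, and the engine does not force
  agreement; consequently CERs are reproduced to within ±$2/DDL.
* **Hospitalization and medevac are top-level dispositions** (the four
  disposition probabilities sum to 100%), not nested under care-seeking.
* The published base cost ratio appears both as $115 (rounded) and $114
  (truncated); the engine carries the unrounded 114.71 and reports both
  roundings where relevant.

## Scenarios

Three management strategies are modeled against the base case, each at three
implementation levels:

* **HCSB** (health-care-seeking behavior): P(outpatient MH treatment) rises
  from 30% to 40/55/70% with an equal complement reduction of the
  no-treatment arm (59.07/44.07/29.07%); earlier presentation cuts
  pre-treatment duration from 1.5 days to ~8 h, so optimal-care DDL → 0.31
  and bed-rest DDL → 1.41.
* **OPB** (optimized provider behavior): the optimal:(optimal+suboptimal)
  prescribing ratio rises from the base 55.8% to 65/75/85%. The therapeutic
  pool (1 − P(bed rest) = 0.629) is split as P(optimal) = level × 0.629
  rounded half-up to 3 decimals — the published one-decimal percentage
  convention, required to reproduce the published outcome rows — with
  suboptimal taking the remainder. Optimal care becomes a $30 blended
  medic/facility cost; optimal DDL → 0.33 (15 h time-to-last-unformed-stool),
  bed-rest DDL → 0.88 (12 h bed rest).
* **combination**: both, paired level-for-level; optimal DDL → 0.11 (8 h
  pre-treatment + 15 h TLUS) and bed-rest DDL → 0.69.

The scenario DDL overrides are *reconciled* values: the published description
of this model is internally inconsistent about them (one table prints HCSB
0.25/1.38 and combination 0.08/0.66 where the accompanying text gives
0.31/1.41 and 0.11). The values above are the only set that reproduces every
published annual-DDL outcome exactly at all nine scenario-levels; the
combination bed-rest value 0.69 is derived as the OPB value 0.88 minus the
0.19-day HCSB pre-treatment reduction (1.60 − 1.41) and verified against the
three published combination totals.

Comparison metrics: DDL-averted = base DDL − scenario DDL (negative values
are DDL-*gained*), and CER = (scenario cost − base cost)/|DDL-averted|, so a
harmful costlier scenario reports a positive $/DDL-gained and a cost-saving
beneficial one a negative $/DDL-averted. When a scenario changes nothing the
CER is undefined and reported as NaN.

## Parameter uncertainty

Each parameter carries a low/high range and a distribution:

* **triangular**(low, base, high) for most parameters;
* **normal** for monthly incidence and four DDL outcomes, with mean = base
  and sd = (high − low)/3.92 — the printed range is read as a central 95%
  interval, matching the one range that is explicitly a 95% CI (monthly
  incidence 28.9%, CI 16.2–41.6% → sd 0.0648). Normal draws are truncated by
  rejection to [0, 1] for probabilities and [0, ∞) for costs and durations,
  since negative values are physically meaningless;
* **point** when low = high.

**Tornado (one-way) analysis** sets one parameter at a time to its low and
high value and records the base cost ratio at each end; sibling probabilities
are *not* renormalized, so branch mass transiently differs from 1. This
mirrors conventional spreadsheet one-way sensitivity tools and is what
reproduces the published hospitalization-probability endpoints ($82/$190);
renormalizing does not. Entries sort by swing, ties alphabetically. Cohort
scalars rescale cost and DDL identically and so have zero swing on the ratio.

**Probabilistic sensitivity analysis** (default 3,000 iterations): every
parameter is drawn from its distribution, each sibling probability group is
rescaled proportionally to sum to 100%, and the base case and the scenario
are evaluated on the *same* draw (common random numbers — the standard
variance-reduction choice for incremental comparisons). Scenario overrides
are applied after sampling as fixed point values: they are policy targets,
not uncertain inputs. For HCSB on a sampled draw the complement transfer is
taken relative to the sampled care-seeking probability, which preserves unit
branch mass. DDL-averted and CER are summarized by median and IQR using
numpy's linear-interpolation quantile convention, so summaries are
bit-reproducible given a seed (recorded in every summary). Iterations with
exactly zero DDL-averted enter the DDL summaries but are excluded from CER
summaries (count reported).

The cohort multiplier (size × months × incidence) is held at its point
estimate by default (`sample_cohort=True` enables drawing it). The size and
duration triangulars are strongly right-skewed (means 55,000 and 5.5 months
versus modes 50,000 and 3.5), so sampling them scales the episode count by
~1.7× on average and inflates every absolute PSA output far beyond the
published uncertainty intervals this package is checked against; holding the
cohort fixed keeps the PSA a statement about *per-cohort* parameter
uncertainty, which is how the published intervals behave.

Known limitation: the published Monte Carlo medians cannot be matched
point-for-point. Because triangular means differ from modes (e.g. P(no MH
treatment) has mode 0.6907 but mean 0.747), proportional renormalization
shifts the sampled disposition mix relative to the base case, and the
published medians imply sampling conventions that shift it the opposite way
and are not documented. The PSA is therefore validated at interval level:
with the conventions above, the sampled medians fall inside the published
IQRs for eight of the nine scenario-levels; HCSB 40% lands near −2,100
against a published IQR of (−1,538, 161). The corresponding acceptance test
asserts all nine and is expected to fail on that one scenario-level; it is
left failing rather than loosened.

## Microsimulator

The per-episode microsimulator draws each episode's pathway from the
categorical distribution of leaf probabilities and accrues that leaf's cost
and DDL. Costs and DDL are deterministic given the pathway (the model has no
within-pathway variance), and episodes are independent. It serves two roles:
a generator of episode-level synthetic data, and a brute-force oracle — its
per-episode means must agree with the deterministic expectations within
Monte Carlo error (tested at 4 standard errors, n = 2×10⁶, across 50 random
valid parameterizations). `random_parameter_set` draws those
parameterizations with uniform-simplex probability groups, log-uniform costs
on [1, 20000] USD, uniform DDL on [0, 10] days, and cohort scalars uniform
within their base ranges, so engine–oracle equivalence is exercised across
the whole space rather than only at the base case.

What the synthetic data does *not* emulate: real TD surveillance data has
overdispersion across units and time, correlated care-seeking behavior,
within-pathway cost/duration variance and regional etiology differences.
Passing tests therefore demonstrate internal consistency of the model and
its published parameterization, not predictive validity for any particular
deployment.

## Problem sizes and numerics

Default test/analysis sizes: PSA 3,000 iterations per scenario (the
convention the published intervals use); oracle equivalence n = 2×10⁶
episodes (4-SE bands are then a fraction of a percent); goodness-of-fit
n = 10⁵ with a χ² test at α = 0.001. Group-sum validation tolerance is 10⁻⁶
(10⁻⁹ for the assembled tree's unit mass). Reported integers use half-up
(away-from-zero) rounding; percentages printed to one decimal in scenario
definitions are reproduced by rounding the optimal share to 3 decimals.
Degenerate inputs: zero total DDL raises on cost-ratio access; an HCSB level
that would drive the no-treatment probability negative raises a scenario
error; truncated-normal rejection sampling aborts after 100 rounds.
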