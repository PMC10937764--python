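# Methods

## Scope and model form

`stonecea` implements a single-acute-episode decision-analytic comparison of
two management strategies for CT-confirmed obstructing ureteric stones:
emergency ureteroscopic laser fragmentation (EUL) and emergency JJ-stent
insertion followed by delayed elective ureteroscopy (DUL). The model is a
plain decision tree — a decision between two strategy subtrees, each a
finite tree of chance and terminal nodes — not a Markov/state-transition
model: there are no cycles, no discounting and no multi-year horizon,
because the episode being costed is a single acute presentation with its
follow-up events. Quality-of-life weights are out of scope (no utility data
exist for the underlying cohorts), so the effect measure is mean inpatient
days and the ICER is expressed in £ per inpatient-day averted.

## The strategy trees and their parameters

Both trees share one skeleton of event classes, in sequence:

1. **Index admission** (root payload): initial procedure cost plus mean
   length of stay × £262/bed-day. For DUL the payload also carries the
   second (elective) procedure and the outpatient stent removal, since every
   DUL patient is stented and returns electively.
2. **Stent in situ after the index procedure** (EUL only): probability
   `p_stent_eul`, the stented arm adding the £171.42 stent-removal tariff.
3. **Clearance confirmation**: intra-operative confidence versus follow-up
   imaging, with the imaging probability fixed at the observed shares (0.30
   EUL, 0.90 DUL); imaging splits ultrasound vs CT with a free share.
4. **Re-admission** at the observed rates (0.18 EUL, 0.20 DUL), with a free
   episode cost.
5. **Re-intervention** at the observed rates (0.09 EUL, 0.15 DUL), with a
   free modality mix encoded as nested binary splits (repeat ureteroscopy
   vs other; within other, ESWL vs PCNL) and a free PCNL episode cost
   spanning the CC 0–1 and CC 2+ tariffs (£2546.12–£7202.79).

Unit costs come from the two NHS reference-cost tables shipped verbatim as
CSV fixtures (one per strategy, since the elective and non-elective tariffs
of the same HRG codes differ). The ultrasound tariff appears with two
slightly different values in the two tables (£65.64 vs £65.54); each
strategy uses its own table's value and the loader logs the collision.

### Free parameters and calibration

The numeric branch probabilities of the original tree are not published, so
parameters that no table pins down are declared *free* with bounds and
resolved by calibrating each strategy's rollback to its published total
(£4915 EUL, £7783 DUL). Free parameters and bounds:

| parameter | bounds | meaning |
|---|---|---|
| `p_stent_eul` | [0, 1] | stent left in situ after index EUL |
| `us_share_eul`, `us_share_dul` | [0, 1] | ultrasound share of follow-up imaging |
| `c_readm_eul`, `c_readm_dul` | [£77.56, £695.38] | re-admission episode cost |
| `m_urs_*`, `m_eswl_*` | [0, 1] | re-intervention modality mix |
| `c_pcnl_eul`, `c_pcnl_dul` | [£2546.12, £7202.79] | PCNL case-mix cost |

The re-admission bound runs from a non-admitted follow-up attendance
(WF02C, £77.56) to **two** bed-days plus a diagnostic cystoscopy (£695.38).
A one-bed-day cap would make the published DUL total unattainable (maximum
rollback £7756 < £7783), and the cohorts did contain re-admissions requiring
a full procedure under general anaesthesia, so episodes above one bed-day
demonstrably occurred.

Calibration exploits the multilinearity of the expected cost: restricted to
one parameter it is affine and monotone, so the solver cycles through the
free coordinates, solving by Brent bracketed root finding whenever the
target is bracketed and otherwise moving to the endpoint nearest the target,
with seeded random restarts if a cycle stalls. Attainability is verified up
front by enumerating the vertices of the bounds box (the exact extremes of a
multilinear function over a box); an out-of-range target raises with the
attainable interval. Stopping residual is £1e-4, well inside the £1
acceptance so that re-calibration is a no-op (idempotence). The calibrated
solution is **one consistent completion of an under-determined system**, not
an estimate of clinical practice: for example the solver is free to load the
re-intervention mix onto PCNL to reach the DUL total.

## Sensitivity analysis

Deterministic ±10% analysis perturbs parameters to base×(1±f). Conventions:

* The default varied set is **all probability and cost parameters**;
  durations are excluded. This follows from the published interval
  arithmetic: the printed ICER interval equals the cost-interval extremes
  divided by a *fixed* effect difference of 2.35 days, so stays were not
  varied. A `--params` switch restricts the set.
* Perturbed probabilities are clipped to [0, 1]; during perturbed
  evaluation every chance node's probability vector is clipped and
  renormalised to sum to one, keeping conservation testable. Complement
  probabilities written as `1 - p` track their partner automatically.
* Per-strategy cost ranges are exact: the cost is multilinear, so its box
  extremes lie at vertices, and up to 2^20 vertices are evaluated in a
  single vectorised rollback (the packaged model has 15 varied parameters
  per strategy). Beyond that, an iterated coordinate endpoint search with
  seeded random restarts is used.
* The ICER range is optimised jointly (evaluating the ratio over the box),
  not by independently extremising numerator and denominator. When the
  effect difference does not depend on the varied set, the incremental cost
  is itself multilinear and its extremes decompose exactly: enumerate the
  vertices of the parameters shared between the trees, and condition each
  strategy's independent extremes on them. When the denominator varies, a
  coordinate search on the ratio is used and a sign change inside the box
  is flagged on the returned range.
* All intervals are forced to contain the base value; at ±10% on the
  calibrated model the package obtains EUL [4364, 5461], DUL [6887, 8705]
  and ICER [709, 1747]. The originally printed intervals ([4403, 5398],
  [6982, 8578], [674, 1776]) cannot be reproduced exactly because the
  varied-parameter set and the tree's numeric branch data are unpublished;
  the test suite therefore asserts containment, nesting across fractions,
  and agreement with dense grid search on small models instead.

Currency is GBP throughout; EUR figures are display-only, at a configurable
rate defaulting to 1.1367 €/£ (back-solved from the published £2868/€3260
pair). Report rounding: costs and ICERs to the nearest pound (half-up),
probabilities and p-values to three decimals (half-up); internal computation
is unrounded.

## Cohort statistics

Categorical rows use the pooled two-proportion z-test without continuity
correction — the test that reproduces the published stone-location p-values
(0.033 distal, 0.049 mid, 0.547 vs printed 0.550 proximal) from the printed
counts, where Fisher or continuity-corrected tests do not. Continuous rows
use the two-sample t-test from summary statistics, pooled variance by
default (closest to the published age p-value: pooled gives 0.0100 vs
printed 0.011), Welch by flag. Known irreconcilables, flagged rather than
forced: the males row prints p = 0.048 but no standard two-sample proportion
test yields that from 73/100 vs 11/20 (pooled z gives 0.109); the continuous
p-values (0.011, 0.175, 0.097) sit between pooled and Welch results computed
from the rounded summaries, so exact reproduction is not asserted (the
suite asserts the secondary-outcome column to 0.005 absolute).

## Synthetic cohorts

The generator emulates the *marginal* structure of the two arms (defaults:
100 EUL / 20 DUL patients): Normal ages, Gamma stone sizes (floored at
0.1 mm) and Gamma lengths of stay and detection-to-treatment intervals
moment-matched to the published mean/SD pairs, categorical stone locations,
Bernoulli sex, and independent Bernoulli secondary outcomes at the published
rates. Gamma was chosen because the durations are nonnegative and
right-skewed with SD exceeding the mean in places (EUL interval 2.13 ± 5.7
days), which a shape<1 Gamma represents; a lognormal alternative is
available by switch. Moment matching is rejected when the implied shape
falls below 0.01. What the generator does **not** emulate — and hence what
passing tests cannot show about real data: joint dependence between
outcomes (only marginal rates are published), sex-specific or age-specific
costs, stone-location effects on outcomes, and any relation between
"complete clearance" and the single-procedure stone-free rate, which are
kept as distinct booleans. Sex is generated but unused downstream.

`estimate_parameters` recovers per-arm empirical rates and moments shaped as
model parameters; `end_to_end_check` injects them into the trees and
compares the plug-in rollback against the exact-rate rollback. At 10,000
patients per arm the plug-in expected costs agree with the exact ones to
well under 5% and every estimated rate falls within three binomial standard
errors of its generator truth.

## Numerical choices and problem sizes

* Rollback vs path-enumeration oracle agreement: 1e-9 relative, checked on
  100 random trees of depth ≤ 5 and branching ≤ 4.
* Chance-node conservation: 1e-9 at base values; 1e-6 during evaluation of
  user-supplied numeric probabilities.
* Vertex enumeration vs dense grid (11 points/axis) on 2–3-parameter toy
  models: 1e-6 relative.
* Calibration: residual < £1 (internal stop £1e-4), ≤ 100 cycles, ≤ 20
  seeded restarts.
* Synthetic checks run at n ∈ {100, 1000, 10,000} per arm for recovery-rate
  scaling and 100,000 for distribution moment matching; the full suite and
  the acceptance script each complete in well under a minute of CPU.

## Limitations

The tree topology is a reconstruction constrained by the published event
classes and totals, not a transcription; quantities reported off the free
parameters (e.g. the calibrated modality mix) carry no clinical meaning.
The effect measure is restricted to inpatient days; no probabilistic
sensitivity analysis (distributional sampling, CEACs) is provided because
the source analysis performed only the deterministic ±10% variation; and
whether the two pre-operative waiting days discussed for EUL are costed
inside or alongside the 3.76-day mean stay is not resolvable from the
published figures — the mean stay is used as printed.
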