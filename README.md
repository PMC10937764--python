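# stonecea

Decision-tree cost-effectiveness analysis of **emergency ureteroscopic laser
fragmentation (EUL)** versus **emergency JJ-stenting followed by delayed
ureteroscopy (DUL)** for acute obstructing ureteric stones, from the
perspective of the UK NHS.

The package is aimed at health-economics and urology researchers who want a
tested, reusable implementation of a single-episode decision-analytic
comparison: tree-based expected-cost rollback over NHS reference costs,
calibration of unpublished branch probabilities to published cost totals, an
ICER expressed per inpatient-day averted, deterministic ±10% sensitivity
analysis, the between-arm cohort statistics, and a synthetic patient-cohort
generator so the entire pipeline runs with no external data.

## The model

Each strategy is a finite tree of chance and terminal nodes. Branch
probabilities and payoffs are arithmetic expressions over named parameters
(probabilities *p*, unit costs *c* in GBP, the £262 bed-day cost, mean
inpatient durations in days). The expected cost is the recursive expectation
(rollback):

```
EC(terminal) = cost(node)
EC(chance)   = cost(node) + Σ_b p_b · EC(child_b)
```

Rollback is verified against a brute-force path-enumeration oracle
(Σ over root-to-terminal paths of path probability × path cost, agreement to
1e-9 relative). Effects are the observed per-arm mean inpatient stays (3.76
days EUL, 6.11 days DUL), supplied as scalar overrides. The comparison is

```
ΔC = C_DUL − C_EUL,   ΔE = E_DUL − E_EUL,   ICER = ΔC / ΔE   (£ per day averted)
```

with EUL *dominating* when it is strictly cheaper with no worse effect.

Because the source analysis prints its per-strategy totals (£4915 EUL, £7783
DUL) but not its numeric branch probabilities, the packaged model leaves
those quantities **free** within honest bounds and resolves them by
calibration: the expected cost is multilinear in the parameters, so each
free coordinate is solved by bracketed root finding, cycled to a residual
below £1. Deterministic sensitivity perturbs parameters to base×(1±f); by
multilinearity the extremes of each strategy's cost over the ±f box lie at
box vertices, which are enumerated exactly (vectorised) for up to 20 varied
parameters per strategy, with an iterated coordinate endpoint search as
fallback. The ICER interval is optimised jointly over vertices, not by
independent numerator/denominator extremes.

Cohort statistics reproduce the published between-arm tests: pooled
two-proportion z-tests (no continuity correction) for categorical rows and
pooled/Welch t-tests from summary statistics for continuous rows.

## Worked example

The packaged fixtures (model YAML plus the two NHS reference-cost tables)
reproduce the base case out of the box:

```bash
$ stonecea run --out-dir demo --rate 1.1367
Strategy    Cost (£)       [low, high]    Days  ICER (£/day)
EUL             4915      [4364, 5461]    3.76  1220 [709, 1747]
DUL             7783      [6887, 8705]    6.11
Incremental cost (DUL - EUL): £2868 (€3260)
Dominance: reference_dominates
artifacts written to demo
```

Reading: after calibration the EUL strategy costs £4915 per patient and the
DUL strategy £7783, so immediate definitive treatment averts £2868 per
patient; dividing by the 2.35 inpatient-days averted gives an ICER of £1220
per day, and EUL dominates (cheaper *and* fewer inpatient days). The
bracketed intervals are the joint ±10% deterministic sensitivity ranges over
all probability and cost parameters. Machine-readable artifacts
(`evaluation.csv`, `cea.csv`, `sensitivity.csv`, `tornado.csv`,
`pipeline.log`) are written to `demo/`.

The same from Python:

```python
import stonecea as sc

model, tables = sc.load_reference_model()
params = sc.calibrate_free_parameters(model.trees, model.parameters,
                                      model.calibration_targets)
cea = sc.cea_from_trees(model.trees, params, "EUL", "DUL")
print(round(cea.delta_cost), round(cea.icer))   # 2868 1220
```

Other subcommands: `validate`, `calibrate`, `evaluate`, `icer`,
`sens --fraction 0.10 --params all|probabilities|costs`, `simulate` (writes a
synthetic two-arm cohort at the study's published rates), and `stats`:

```bash
$ stonecea stats | grep ureteric
Share of proximal ureteric stones 33/100  8/20    0.33    0.40 two-proportion z (pooled)  -0.602557 None    0.547
     Share of mid-ureteric stones 16/100  7/20    0.16    0.35 two-proportion z (pooled)  -1.970650 None    0.049
  Share of distal ureteric stones 51/100  5/20    0.51    0.25 two-proportion z (pooled)   2.127624 None    0.033
```

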