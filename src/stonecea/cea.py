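"""Incremental cost-effectiveness and deterministic sensitivity analysis.

The comparison is between a *reference* strategy (here emergency
ureteroscopic laser fragmentation, EUL) and a *comparator* (emergency
stenting with delayed ureteroscopy, DUL).  Effects are mean inpatient days,
so lower is better:

    delta_cost   = cost_comparator  - cost_reference
    delta_effect = effect_comparator - effect_reference   (days averted)
    ICER         = delta_cost / delta_effect              (GBP per day averted)

The reference dominates when it is strictly cheaper with no worse effect;
the ICER is still reported in that case, matching the presentation of the
analysis being reproduced.

Deterministic sensitivity perturbs each parameter to base*(1 +/- fraction)
(probabilities clipped to [0, 1]; chance-node probability vectors are
renormalised during evaluation).  Because the expected cost is multilinear
in the parameters, its extremes over the +/-fraction box lie at the box
vertices; for up to ~20 varied parameters per strategy the vertices are
enumerated exactly in one vectorised rollback.  The ICER range is computed
jointly: when the effect difference does not depend on the varied set (the
default — durations are not varied) the incremental cost is itself
multilinear and its extremes decompose over the parameters shared between
the two trees; otherwise an iterated coordinate endpoint search with random
restarts is used.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .parameters import COST_ROLES, Parameter, ParameterSet
from .tree import StrategyTree, referenced_parameters, rollback

__all__ = [
    "CEAResult",
    "SensitivityRange",
    "TornadoEntry",
    "compute_icer",
    "convert_currency",
    "one_way_range",
    "tornado",
    "joint_range",
    "select_varied",
    "round_gbp",
    "round_probability",
    "DEFAULT_EUR_PER_GBP",
]

#: display conversion rate implied by the printed GBP/EUR pairs (2868 -> 3260)
DEFAULT_EUR_PER_GBP = 1.1367

#: largest per-strategy varied set handled by exact vertex enumeration
MAX_EXACT_VERTICES = 20
#: largest shared-parameter set enumerated in the joint ICER decomposition
MAX_SHARED_VERTICES = 8


def round_gbp(x: float) -> int:
    """Report rounding for costs and ICERs: nearest pound, half up."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def round_probability(p: float, places: int = 3) -> float:
    q = Decimal("1." + "0" * places)
    return float(Decimal(repr(float(p))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CEAResult:
    reference_strategy: str
    comparator_strategy: str
    cost_reference: float
    cost_comparator: float
    effect_reference: float
    effect_comparator: float
    delta_cost: float
    delta_effect: float
    icer: Optional[float]  # absent when delta_effect == 0
    dominance: str  # "none" | "reference_dominates" | "comparator_dominates"


def compute_icer(
    cost_ref: float,
    cost_cmp: float,
    effect_ref: float,
    effect_cmp: float,
    reference: str = "reference",
    comparator: str = "comparator",
) -> CEAResult:
    """Incremental cost per inpatient-day averted by the reference strategy.

    Effects are inpatient days (lower is better).  Negative costs or
    effects are rejected.
    """
    for label, v in (("cost_ref", cost_ref), ("cost_cmp", cost_cmp),
                     ("effect_ref", effect_ref), ("effect_cmp", effect_cmp)):
        if v < 0:
            raise ValueError(f"{label} is negative ({v})")
    delta_cost = cost_cmp - cost_ref
    delta_effect = effect_cmp - effect_ref
    icer = delta_cost / delta_effect if delta_effect != 0.0 else None
    if cost_ref < cost_cmp and effect_ref <= effect_cmp:
        dominance = "reference_dominates"
    elif cost_cmp < cost_ref and effect_cmp <= effect_ref:
        dominance = "comparator_dominates"
    else:
        dominance = "none"
    return CEAResult(
        reference_strategy=reference,
        comparator_strategy=comparator,
        cost_reference=cost_ref,
        cost_comparator=cost_cmp,
        effect_reference=effect_ref,
        effect_comparator=effect_cmp,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=dominance,
    )


def cea_from_trees(trees: Mapping[str, StrategyTree], params: ParameterSet,
                   reference: str, comparator: str) -> CEAResult:
    """Roll back both strategies and compare them."""
    ref = rollback(trees[reference], params)
    cmp_ = rollback(trees[comparator], params)
    return compute_icer(ref.expected_cost, cmp_.expected_cost,
                        ref.expected_effect, cmp_.expected_effect,
                        reference=reference, comparator=comparator)


def convert_currency(amount_gbp: float, rate_eur_per_gbp: float) -> float:
    """Pure display conversion GBP -> EUR (all computation stays in GBP)."""
    if rate_eur_per_gbp <= 0:
        raise ValueError(f"conversion rate must be positive, got {rate_eur_per_gbp}")
    return amount_gbp * rate_eur_per_gbp


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class SensitivityRange:
    quantity: str  # "expected_cost" | "icer" | "delta_cost"
    strategy: str  # strategy name, or "reference vs comparator" pair text
    base: float
    low: float
    high: float
    fraction: float
    denominator_sign_change: bool = False


@dataclass
class TornadoEntry:
    parameter_name: str
    low_result: float
    high_result: float

    @property
    def swing(self) -> float:
        return abs(self.high_result - self.low_result)


def select_varied(params: ParameterSet, which="all") -> List[str]:
    """Resolve a varied-parameter selector to a list of names.

    ``"all"`` means every probability and cost parameter (durations are
    excluded, matching an analysis that varies "cost and probability
    data"); ``"probabilities"`` / ``"costs"`` restrict by role; a sequence
    of names is taken literally (unknown names raise).
    """
    if which == "all":
        return params.subset(("probability",) + COST_ROLES)
    if which == "probabilities":
        return params.subset(("probability",))
    if which == "costs":
        return params.subset(COST_ROLES)
    names = list(which)
    for n in names:
        params[n]  # raises UnknownParameterError
    return names


def perturbation_endpoints(param: Parameter, fraction: float) -> Tuple[float, float]:
    """base*(1-f) and base*(1+f), probabilities clipped to [0, 1]."""
    lo = param.value * (1.0 - fraction)
    hi = param.value * (1.0 + fraction)
    if param.role == "probability":
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return lo, hi


def _strategy_cost(tree: StrategyTree, params: ParameterSet, overrides: Mapping):
    return rollback(tree, params, overrides=overrides, normalize=True).expected_cost


def _quantity_evaluator(quantity, trees, params, reference, comparator):
    """Return f(overrides) -> value for a named sensitivity quantity."""
    if isinstance(quantity, tuple) and quantity[0] == "expected_cost":
        tree = trees[quantity[1]]
        return lambda ov: _strategy_cost(tree, params, ov)
    if quantity == "delta_cost":
        rt, ct = trees[reference], trees[comparator]
        return lambda ov: _strategy_cost(ct, params, ov) - _strategy_cost(rt, params, ov)
    if quantity == "icer":
        rt, ct = trees[reference], trees[comparator]

        def f(ov):
            r = rollback(rt, params, overrides=ov, normalize=True)
            c = rollback(ct, params, overrides=ov, normalize=True)
            return (c.expected_cost - r.expected_cost) / (c.expected_effect - r.expected_effect)

        return f
    raise ValueError(f"unknown sensitivity quantity {quantity!r}")


def one_way_range(
    trees: Mapping[str, StrategyTree],
    params: ParameterSet,
    parameter_name: str,
    fraction: float,
    quantity="delta_cost",
    reference: Optional[str] = None,
    comparator: Optional[str] = None,
) -> TornadoEntry:
    """Evaluate a quantity at base*(1-f) and base*(1+f) of one parameter.

    By multilinearity the extremes of the quantity over the interval lie at
    these endpoints.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    names = list(trees)
    reference = reference or names[0]
    comparator = comparator or names[1 if len(names) > 1 else 0]
    param = params[parameter_name]
    lo, hi = perturbation_endpoints(param, fraction)
    f = _quantity_evaluator(quantity, trees, params, reference, comparator)
    return TornadoEntry(parameter_name, float(f({parameter_name: lo})), float(f({parameter_name: hi})))


def tornado(
    trees: Mapping[str, StrategyTree],
    params: ParameterSet,
    fraction: float,
    quantity="delta_cost",
    vary="all",
    reference: Optional[str] = None,
    comparator: Optional[str] = None,
) -> List[TornadoEntry]:
    """One-way ranges for every varied parameter, sorted by descending swing."""
    entries = [
        one_way_range(trees, params, name, fraction, quantity, reference, comparator)
        for name in select_varied(params, vary)
    ]
    entries.sort(key=lambda e: (-e.swing, e.parameter_name))
    return entries


def _vertex_overrides(params: ParameterSet, names: Sequence[str], fraction: float,
                      fixed: Optional[Mapping] = None) -> Dict[str, np.ndarray]:
    idx = np.arange(2 ** len(names))
    overrides: Dict[str, np.ndarray] = dict(fixed or {})
    for bit, name in enumerate(names):
        lo, hi = perturbation_endpoints(params[name], fraction)
        overrides[name] = np.where((idx >> bit) & 1, hi, lo).astype(float)
    return overrides


def _cost_extremes_exact(tree, params, names, fraction, fixed=None) -> Tuple[float, float]:
    if not names:
        c = float(_strategy_cost(tree, params, dict(fixed or {})))
        return c, c
    costs = np.asarray(_strategy_cost(tree, params, _vertex_overrides(params, names, fraction, fixed)))
    return float(costs.min()), float(costs.max())


def _coordinate_search(objective, params, names, fraction, maximize, rng,
                       restarts=8, max_sweeps=60):
    """Iterated endpoint descent/ascent over box vertices with restarts."""
    sign = -1.0 if maximize else 1.0
    endpoints = {n: perturbation_endpoints(params[n], fraction) for n in names}
    starts = [dict.fromkeys(names, 0), dict.fromkeys(names, 1)]
    for _ in range(restarts):
        starts.append({n: int(rng.integers(0, 2)) for n in names})
    best = None
    for start in starts:
        assign = dict(start)
        value = sign * objective({n: endpoints[n][assign[n]] for n in names})
        for _sweep in range(max_sweeps):
            improved = False
            for n in names:
                flipped = dict(assign)
                flipped[n] = 1 - flipped[n]
                v = sign * objective({m: endpoints[m][flipped[m]] for m in names})
                if v < value - 1e-12:
                    assign, value = flipped, v
                    improved = True
            if not improved:
                break
        if best is None or value < best:
            best = value
    return sign * best


def joint_range(
    trees: Mapping[str, StrategyTree],
    params: ParameterSet,
    fraction: float,
    vary="all",
    reference: Optional[str] = None,
    comparator: Optional[str] = None,
    seed: int = 0,
) -> Dict[str, SensitivityRange]:
    """Joint min/max of each strategy's expected cost and of the ICER over
    the +/-fraction box of the varied parameters.

    Returns a mapping with one :class:`SensitivityRange` per strategy
    (keyed by strategy name) plus an ``"icer"`` entry when the effect
    difference is nonzero.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    names = list(trees)
    reference = reference or names[0]
    comparator = comparator or (names[1] if len(names) > 1 else names[0])
    varied = select_varied(params, vary)
    rng = np.random.default_rng(seed)
    out: Dict[str, SensitivityRange] = {}

    per_tree_varied: Dict[str, List[str]] = {}
    for sname, tree in trees.items():
        referenced = referenced_parameters(tree)
        tnames = [n for n in varied if n in referenced]
        per_tree_varied[sname] = tnames
        base_cost = float(_strategy_cost(tree, params, {}))
        if len(tnames) <= MAX_EXACT_VERTICES:
            lo, hi = _cost_extremes_exact(tree, params, tnames, fraction)
        else:
            obj = lambda ov, t=tree: float(_strategy_cost(t, params, ov))
            lo = _coordinate_search(obj, params, tnames, fraction, False, rng)
            hi = _coordinate_search(obj, params, tnames, fraction, True, rng)
        out[sname] = SensitivityRange(
            "expected_cost", sname, base_cost,
            min(lo, base_cost), max(hi, base_cost), fraction,
        )

    # --- ICER range ---
    ref_tree, cmp_tree = trees[reference], trees[comparator]
    base_res = cea_from_trees(trees, params, reference, comparator)
    if base_res.delta_effect == 0.0 or base_res.icer is None:
        return out

    effect_names = set()
    for t in (ref_tree, cmp_tree):
        if t.effect_mode == "scalar_override":
            effect_names |= set(t.scalar_effect.names)
        else:
            effect_names |= referenced_parameters(t)  # conservative
    denominator_varies = bool(effect_names & set(varied)) or any(
        t.effect_mode != "scalar_override" for t in (ref_tree, cmp_tree)
    )

    ref_names = per_tree_varied[reference]
    cmp_names = per_tree_varied[comparator]
    shared = [n for n in varied if n in set(ref_names) & set(cmp_names)]
    only_ref = [n for n in ref_names if n not in shared]
    only_cmp = [n for n in cmp_names if n not in shared]

    warn = False
    if (not denominator_varies and len(shared) <= MAX_SHARED_VERTICES
            and max(len(only_ref), len(only_cmp)) <= MAX_EXACT_VERTICES):
        # incremental cost is multilinear: condition on shared-parameter
        # vertices, optimise each strategy independently given the vertex
        de = base_res.delta_effect
        dmin, dmax = np.inf, -np.inf
        for sidx in range(2 ** max(len(shared), 0) if shared else 1):
            fixed = {}
            for bit, n in enumerate(shared):
                lo, hi = perturbation_endpoints(params[n], fraction)
                fixed[n] = hi if (sidx >> bit) & 1 else lo
            r_lo, r_hi = _cost_extremes_exact(ref_tree, params, only_ref, fraction, fixed)
            c_lo, c_hi = _cost_extremes_exact(cmp_tree, params, only_cmp, fraction, fixed)
            dmin = min(dmin, c_lo - r_hi)
            dmax = max(dmax, c_hi - r_lo)
        cands = sorted((dmin / de, dmax / de))
        icer_lo, icer_hi = cands[0], cands[1]
    else:
        icer_obj = _quantity_evaluator("icer", trees, params, reference, comparator)
        base_sign = np.sign(base_res.delta_effect)

        def denom(ov):
            r = rollback(ref_tree, params, overrides=ov, normalize=True)
            c = rollback(cmp_tree, params, overrides=ov, normalize=True)
            return c.expected_effect - r.expected_effect

        seen_flip = [False]

        def guarded(ov):
            d = denom(ov)
            if np.sign(d) != base_sign or d == 0.0:
                seen_flip[0] = True
                return np.nan
            return icer_obj(ov)

        union = list(dict.fromkeys(ref_names + cmp_names))

        def safe(ov, sign_):
            v = guarded(ov)
            return sign_ * np.inf if np.isnan(v) else v

        icer_lo = _coordinate_search(lambda ov: safe(ov, +1.0), params, union, fraction, False, rng)
        icer_hi = _coordinate_search(lambda ov: safe(ov, -1.0), params, union, fraction, True, rng)
        warn = seen_flip[0]

    out["icer"] = SensitivityRange(
        "icer", f"{reference} vs {comparator}", float(base_res.icer),
        min(icer_lo, base_res.icer), max(icer_hi, base_res.icer), fraction,
        denominator_sign_change=warn,
    )
    return out
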