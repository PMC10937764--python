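"""Calibration of free branch probabilities / costs to published totals.

The source analysis prints per-strategy expected-cost totals but not the
numeric branch probabilities of its tree, so the fixture model carries a
handful of *free* parameters (flagged on the :class:`~stonecea.parameters.
Parameter`) with honest bounds.  Calibration resolves them so that the
rollback of each strategy reproduces its published total to within £1.

Because the expected cost is multilinear in the parameters, its restriction
to any single parameter (others held fixed) is affine and monotone, so each
coordinate can be solved by bracketed root finding.  The solver cycles
through the free parameters of a strategy: when the running target is
bracketed along a coordinate it is solved exactly (Brent's method); when it
is not, the parameter moves to the endpoint nearest the target.  If a full
cycle makes no progress the free values are restarted from a random
interior point (seeded, deterministic).  Attainability is checked up front
by enumerating the vertices of the bounds box — the multilinear extremes —
and an out-of-range target raises with the attainable interval.
"""
from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional

import numpy as np
from scipy.optimize import brentq

from .parameters import ParameterSet
from .tree import StrategyTree, referenced_parameters, rollback

__all__ = ["CalibrationError", "attainable_cost_range", "calibrate_free_parameters"]

#: residual (GBP) below which a strategy is considered calibrated
DEFAULT_TOL_GBP = 1.0
#: internal stopping residual, well inside the tolerance so that re-running
#: calibration is a no-op (idempotence)
_STOP_GBP = 1e-4


class CalibrationError(ValueError):
    pass


def _expected_cost(tree: StrategyTree, params: ParameterSet, values: Mapping) -> float:
    return rollback(tree, params, overrides=values).expected_cost


def attainable_cost_range(
    tree: StrategyTree,
    params: ParameterSet,
    free_names: Iterable[str],
    fixed: Optional[Mapping[str, float]] = None,
):
    """Exact [min, max] of the expected cost over the free-parameter box.

    The expected cost is multilinear, so its extremes over a box lie at
    vertices; the 2**k vertices are evaluated in one vectorised rollback.
    """
    free_names = list(free_names)
    k = len(free_names)
    if k == 0:
        base = _expected_cost(tree, params, dict(fixed or {}))
        return base, base
    if k > 20:
        raise CalibrationError(f"too many free parameters for vertex enumeration ({k})")
    idx = np.arange(2**k)
    overrides: Dict[str, np.ndarray] = dict(fixed or {})
    for bit, name in enumerate(free_names):
        lo, hi = params[name].effective_bounds()
        if not np.isfinite(hi):
            raise CalibrationError(f"free parameter {name!r} has an unbounded interval")
        overrides[name] = np.where((idx >> bit) & 1, hi, lo).astype(float)
    costs = np.asarray(_expected_cost(tree, params, overrides))
    return float(costs.min()), float(costs.max())


def calibrate_free_parameters(
    trees,
    params: ParameterSet,
    targets: Mapping[str, float],
    *,
    tol: float = DEFAULT_TOL_GBP,
    max_cycles: int = 100,
    max_restarts: int = 20,
    seed: int = 0,
) -> ParameterSet:
    """Resolve free parameters so each strategy's rollback hits its target.

    Parameters
    ----------
    trees : mapping or sequence of StrategyTree
        The strategies being calibrated; free parameters are matched to a
        strategy by appearing in its tree.
    targets : mapping
        Strategy name -> target expected cost (GBP).

    Returns
    -------
    ParameterSet
        A copy with calibrated free values; fixed parameters unchanged.
    """
    if not isinstance(trees, Mapping):
        trees = {t.strategy_name: t for t in trees}
    rng = np.random.default_rng(seed)
    current = params

    for strategy, target in targets.items():
        if strategy not in trees:
            raise CalibrationError(f"no tree for calibration target {strategy!r}")
        tree = trees[strategy]
        referenced = referenced_parameters(tree)
        free = [n for n in current.names() if current[n].free and n in referenced]
        target = float(target)
        if not free:
            base = _expected_cost(tree, current, {})
            if abs(base - target) > tol:
                raise CalibrationError(
                    f"strategy {strategy!r}: no free parameters and expected cost "
                    f"{base:.2f} misses target {target:.2f}"
                )
            continue
        lo_cost, hi_cost = attainable_cost_range(tree, current, free)
        if not (lo_cost - tol <= target <= hi_cost + tol):
            raise CalibrationError(
                f"strategy {strategy!r}: target {target:.2f} outside attainable "
                f"expected-cost range [{lo_cost:.2f}, {hi_cost:.2f}]"
            )
        values = {n: current[n].value for n in free}
        restarts = 0
        for _cycle in range(max_cycles):
            moved = False
            done = False
            for name in free:
                blo, bhi = current[name].effective_bounds()

                def f(v, _name=name):
                    trial = dict(values)
                    trial[_name] = v
                    return _expected_cost(tree, current, trial)

                f_lo, f_hi = f(blo), f(bhi)
                if (f_lo - target) * (f_hi - target) <= 0.0 and f_lo != f_hi:
                    root = brentq(lambda v: f(v) - target, blo, bhi, xtol=1e-12)
                    if abs(root - values[name]) > 0.0:
                        values[name] = float(root)
                        moved = True
                    done = True
                    break
                # not bracketed along this coordinate: move to the better endpoint
                best_end, best_val = min(((blo, f_lo), (bhi, f_hi)), key=lambda t: abs(t[1] - target))
                cur_val = f(values[name])
                if abs(best_val - target) < abs(cur_val - target) - 1e-12:
                    values[name] = float(best_end)
                    moved = True
            residual = abs(_expected_cost(tree, current, values) - target)
            if done and residual < _STOP_GBP:
                break
            if not moved:
                if residual <= tol:
                    break
                restarts += 1
                if restarts > max_restarts:
                    raise CalibrationError(
                        f"strategy {strategy!r}: calibration stalled with residual "
                        f"£{residual:.2f} after {restarts - 1} restarts"
                    )
                for name in free:
                    blo, bhi = current[name].effective_bounds()
                    values[name] = float(rng.uniform(blo, bhi))
        current = current.with_values(values)

    # final verification across all strategies (guards shared free parameters)
    for strategy, target in targets.items():
        got = _expected_cost(trees[strategy], current, {})
        if abs(got - float(target)) > tol:
            raise CalibrationError(
                f"strategy {strategy!r}: post-calibration expected cost {got:.2f} "
                f"misses target {float(target):.2f} by more than £{tol:.2f}"
            )
    return current
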