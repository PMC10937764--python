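"""Decision-tree data model, validation, rollback and path enumeration.

A strategy is a finite tree of chance and terminal nodes.  Chance-node
branches carry probability expressions that must sum to one; nodes carry
cost (GBP) and effect (days) payoffs as expressions over named parameters.
The expected cost of a strategy is the recursive expectation ("rollback"):
terminal nodes contribute their payoff, chance nodes contribute their
payoff plus the probability-weighted value of their children.  Decision
nodes only ever appear at the root of a comparison; strategies are
evaluated separately and compared downstream.

Effects (inpatient days) can either accumulate along the tree or be
supplied as a per-strategy scalar override — the latter matches analyses
where the effect measure is the observed cohort mean length of stay rather
than a modelled quantity.

`enumerate_paths` expands every root-to-terminal path with its joint
probability and summed payoffs; it is the brute-force oracle against which
rollback is verified (the two must agree to 1e-9 relative).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence

import numpy as np

from .expressions import ZERO, Expr, ExpressionError, as_expr
from .parameters import ParameterSet

__all__ = [
    "Branch",
    "TreeNode",
    "StrategyTree",
    "Path",
    "PathEnumeration",
    "EvaluationResult",
    "EvaluationError",
    "validate_tree",
    "rollback",
    "enumerate_paths",
    "referenced_parameters",
]

#: tolerance on chance-node probability conservation
PROB_SUM_TOL = 1e-9


class EvaluationError(ValueError):
    """Raised when a tree cannot be evaluated (bad probability, unknown name)."""


@dataclass
class Branch:
    probability: Optional[Expr]  # None only for decision-node branches
    child: "TreeNode"


@dataclass
class TreeNode:
    kind: str  # "decision" | "chance" | "terminal"
    label: str
    payload_cost: Expr = ZERO
    payload_effect: Expr = ZERO
    branches: List[Branch] = field(default_factory=list)

    def __post_init__(self):
        self.payload_cost = as_expr(self.payload_cost)
        self.payload_effect = as_expr(self.payload_effect)


@dataclass
class StrategyTree:
    """A named strategy with its event tree and effect convention."""

    strategy_name: str
    root: TreeNode
    effect_mode: str = "tree_accumulated"  # or "scalar_override"
    scalar_effect: Optional[Expr] = None  # days, used iff scalar_override

    def __post_init__(self):
        if self.effect_mode not in ("tree_accumulated", "scalar_override"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if self.effect_mode == "scalar_override":
            if self.scalar_effect is None:
                raise ValueError("scalar_override requires scalar_effect")
            self.scalar_effect = as_expr(self.scalar_effect)


@dataclass
class Path:
    probability: float
    cost: float
    effect: float
    node_labels: List[str]


PathEnumeration = List[Path]


@dataclass
class EvaluationResult:
    strategy_name: str
    expected_cost: float
    expected_effect: float


def referenced_parameters(tree: StrategyTree) -> set:
    """All parameter names referenced by the tree's expressions."""
    names: set = set()

    def walk(node: TreeNode) -> None:
        names.update(node.payload_cost.names)
        names.update(node.payload_effect.names)
        for br in node.branches:
            if br.probability is not None:
                names.update(br.probability.names)
            walk(br.child)

    walk(tree.root)
    if tree.scalar_effect is not None:
        names.update(tree.scalar_effect.names)
    return names


def validate_tree(tree: StrategyTree, params: ParameterSet) -> List[str]:
    """Check structural and probabilistic invariants at base values.

    Returns a list of human-readable diagnostics; an empty list means the
    tree is valid.  Unresolvable parameter names are fatal diagnostics.
    """
    diags: List[str] = []
    env = params.values()
    seen_ids: set = set()

    def check_expr(expr: Optional[Expr], node: TreeNode, what: str):
        if expr is None:
            return None
        try:
            return float(expr(env))
        except ExpressionError as exc:
            diags.append(f"node {node.label!r}: fatal, {what}: {exc}")
            return None

    def walk(node: TreeNode, is_root: bool, depth: int) -> None:
        if depth > 10_000:
            diags.append(f"node {node.label!r}: tree depth exceeds 10000 (cycle?)")
            return
        if id(node) in seen_ids:
            diags.append(f"node {node.label!r}: reachable twice — graph is not a tree")
            return
        seen_ids.add(id(node))
        if node.kind not in ("decision", "chance", "terminal"):
            diags.append(f"node {node.label!r}: unknown kind {node.kind!r}")
            return
        if node.kind == "decision" and not is_root:
            diags.append(f"node {node.label!r}: decision nodes may appear only at the root")
        if node.kind == "terminal":
            if node.branches:
                diags.append(f"node {node.label!r}: terminal nodes must have no branches")
            check_expr(node.payload_cost, node, "payload cost")
            check_expr(node.payload_effect, node, "payload effect")
            return
        if not node.branches:
            diags.append(f"node {node.label!r}: {node.kind} node has no branches")
        check_expr(node.payload_cost, node, "payload cost")
        check_expr(node.payload_effect, node, "payload effect")
        if node.kind == "chance":
            total = 0.0
            ok = True
            for br in node.branches:
                if br.probability is None:
                    diags.append(
                        f"node {node.label!r}: chance branch to {br.child.label!r} lacks a probability"
                    )
                    ok = False
                    continue
                val = check_expr(br.probability, node, f"branch probability {br.probability.text!r}")
                if val is None:
                    ok = False
                    continue
                if not (-PROB_SUM_TOL <= val <= 1.0 + PROB_SUM_TOL):
                    diags.append(
                        f"node {node.label!r}: branch probability {br.probability.text!r} "
                        f"evaluates to {val:.6g}, outside [0, 1]"
                    )
                    ok = False
                total += val
            if ok and abs(total - 1.0) > PROB_SUM_TOL:
                diags.append(
                    f"node {node.label!r}: branch probabilities sum to {total:.6g}, not 1"
                )
        else:  # decision
            for br in node.branches:
                if br.probability is not None:
                    diags.append(
                        f"node {node.label!r}: decision branches must not carry probabilities"
                    )
        for br in node.branches:
            walk(br.child, False, depth + 1)

    walk(tree.root, True, 0)
    return diags


def _branch_probabilities(node: TreeNode, env: Mapping, normalize: bool):
    probs = []
    for br in node.branches:
        if br.probability is None:
            raise EvaluationError(
                f"node {node.label!r}: chance branch without probability"
            )
        try:
            probs.append(br.probability(env))
        except ExpressionError as exc:
            raise EvaluationError(str(exc)) from exc
    if normalize:
        probs = [np.clip(p, 0.0, 1.0) for p in probs]
        total = sum(probs)
        if np.any(np.asarray(total) <= 0.0):
            raise EvaluationError(
                f"node {node.label!r}: branch probabilities sum to zero after clipping"
            )
        probs = [p / total for p in probs]
    else:
        for br, p in zip(node.branches, probs):
            arr = np.asarray(p)
            if np.any(arr < -PROB_SUM_TOL) or np.any(arr > 1.0 + PROB_SUM_TOL):
                raise EvaluationError(
                    f"node {node.label!r}: probability {br.probability.text!r} outside "
                    f"[0, 1] (value {float(np.min(arr)) if np.any(arr < 0) else float(np.max(arr)):.6g})"
                )
        total = np.asarray(sum(probs))
        if np.any(np.abs(total - 1.0) > 1e-6):
            raise EvaluationError(
                f"node {node.label!r}: branch probabilities sum to "
                f"{float(np.max(total)):.6g}, not 1"
            )
    return probs


def rollback(
    tree: StrategyTree,
    params: ParameterSet,
    overrides: Optional[Mapping] = None,
    *,
    normalize: bool = False,
) -> EvaluationResult:
    """Expected cost and effect of a strategy by recursive expectation.

    Parameters
    ----------
    overrides : mapping, optional
        Values replacing base parameter values; entries may be scalars or
        NumPy arrays of a common shape (vectorised scenario evaluation).
    normalize : bool
        When true, branch probabilities are clipped to [0, 1] and each
        chance node's probability vector renormalised to sum to one —
        the convention used when parameters are perturbed in sensitivity
        analysis.  When false, conservation is enforced strictly.
    """
    env = params.values()
    if overrides:
        env.update(overrides)

    def value(node: TreeNode):
        if node.kind == "decision":
            raise EvaluationError(
                f"node {node.label!r}: decision nodes are not evaluated; "
                "roll back each strategy separately"
            )
        try:
            cost = node.payload_cost(env)
            effect = node.payload_effect(env)
        except ExpressionError as exc:
            raise EvaluationError(str(exc)) from exc
        if node.kind == "terminal":
            return cost, effect
        probs = _branch_probabilities(node, env, normalize)
        for p, br in zip(probs, node.branches):
            c, e = value(br.child)
            cost = cost + p * c
            effect = effect + p * e
        return cost, effect

    cost, effect = value(tree.root)
    if tree.effect_mode == "scalar_override":
        try:
            effect = tree.scalar_effect(env)
        except ExpressionError as exc:
            raise EvaluationError(str(exc)) from exc
    return EvaluationResult(tree.strategy_name, cost, effect)


def enumerate_paths(tree: StrategyTree, params: ParameterSet,
                    overrides: Optional[Mapping] = None) -> PathEnumeration:
    """Every root-to-terminal path with joint probability and summed payoffs.

    The probability-weighted sum of path costs equals the rollback expected
    cost (to 1e-9 relative); this is the independent oracle for rollback.
    """
    env = params.values()
    if overrides:
        env.update(overrides)
    paths: PathEnumeration = []

    def walk(node: TreeNode, prob: float, cost: float, effect: float, labels: List[str]):
        if node.kind == "decision":
            raise EvaluationError(
                f"node {node.label!r}: decision nodes are not enumerated"
            )
        try:
            cost = cost + float(node.payload_cost(env))
            effect = effect + float(node.payload_effect(env))
        except ExpressionError as exc:
            raise EvaluationError(str(exc)) from exc
        labels = labels + [node.label]
        if node.kind == "terminal":
            paths.append(Path(prob, cost, effect, labels))
            return
        probs = _branch_probabilities(node, env, normalize=False)
        for p, br in zip(probs, node.branches):
            walk(br.child, prob * float(p), cost, effect, labels)

    walk(tree.root, 1.0, 0.0, 0.0, [])
    return paths


def paths_expected_cost(paths: PathEnumeration) -> float:
    return float(sum(p.probability * p.cost for p in paths))


def paths_expected_effect(paths: PathEnumeration) -> float:
    return float(sum(p.probability * p.effect for p in paths))
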