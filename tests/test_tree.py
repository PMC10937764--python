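import numpy as np
import pytest

from stonecea.cea import perturbation_endpoints, select_varied
from stonecea.expressions import as_expr
from stonecea.parameters import Parameter, ParameterSet
from stonecea.tree import (
    Branch,
    EvaluationError,
    StrategyTree,
    TreeNode,
    enumerate_paths,
    paths_expected_cost,
    paths_expected_effect,
    referenced_parameters,
    rollback,
    validate_tree,
)

EMPTY = ParameterSet()


def chance(label, *branches, cost=0.0):
    return TreeNode("chance", label, payload_cost=cost,
                    branches=[Branch(None if p is None else as_expr(p), c)
                              for p, c in branches])


def terminal(label, cost=0.0, effect=0.0):
    return TreeNode("terminal", label, payload_cost=cost, payload_effect=effect)


class TestValidation:
    def test_single_terminal_is_valid(self):
        tree = StrategyTree("S", terminal("only"))
        assert validate_tree(tree, EMPTY) == []

    def test_probability_conservation_violation_reported(self):
        tree = StrategyTree("S", chance("root", (0.7, terminal("a")), (0.2, terminal("b"))))
        diags = validate_tree(tree, EMPTY)
        assert len(diags) == 1
        assert "sum to 0.9" in diags[0] and "root" in diags[0]

    def test_terminal_with_branches_flagged(self):
        bad = TreeNode("terminal", "t", branches=[Branch(None, terminal("x"))])
        assert any("no branches" in d for d in validate_tree(StrategyTree("S", bad), EMPTY))

    def test_decision_below_root_flagged(self):
        inner = TreeNode("decision", "inner", branches=[Branch(None, terminal("x"))])
        tree = StrategyTree("S", chance("root", (1.0, inner)))
        assert any("only at the root" in d for d in validate_tree(tree, EMPTY))

    def test_unknown_parameter_is_fatal(self):
        tree = StrategyTree("S", chance("root", ("p_missing", terminal("a")),
                                        ("1 - p_missing", terminal("b"))))
        diags = validate_tree(tree, EMPTY)
        assert any("fatal" in d and "p_missing" in d for d in diags)

    def test_shared_subtree_is_not_a_tree(self):
        leaf = terminal("shared")
        tree = StrategyTree("S", chance("root", (0.5, leaf), (0.5, leaf)))
        assert any("not a tree" in d for d in validate_tree(tree, EMPTY))

    def test_reference_model_trees_are_valid(self, reference_model):
        for tree in reference_model.trees.values():
            assert validate_tree(tree, reference_model.parameters) == []


class TestRollback:
    def test_terminal_identity(self):
        res = rollback(StrategyTree("S", terminal("t", cost=100.0)), EMPTY)
        assert res.expected_cost == 100.0

    def test_dul_deterministic_backbone(self, reference_model):
        # emergency stenting + elective ureteroscopy + stent removal + mean stay
        backbone = StrategyTree(
            "DUL-backbone",
            terminal("episode", cost="c_stent_insertion + c_dul_ureteroscopy + "
                                      "c_stent_removal + los_mean_dul * daily_bed_cost"),
        )
        res = rollback(backbone, reference_model.parameters)
        assert res.expected_cost == pytest.approx(6477.58, abs=0.005)

    def test_probability_out_of_range_names_parameter(self):
        params = ParameterSet([Parameter("p", "probability", 0.5)])
        tree = StrategyTree("S", chance("root", ("p + 1", terminal("a")),
                                        ("-p", terminal("b"))))
        with pytest.raises(EvaluationError, match="p \\+ 1"):
            rollback(tree, params)

    def test_normalize_renormalises_clipped_probabilities(self):
        tree = StrategyTree("S", chance("root", (0.6, terminal("a", cost=100.0)),
                                        (0.6, terminal("b", cost=300.0))))
        res = rollback(tree, EMPTY, normalize=True)
        assert res.expected_cost == pytest.approx(200.0)
        with pytest.raises(EvaluationError):
            rollback(tree, EMPTY)

    def test_scalar_effect_override(self):
        tree = StrategyTree("S", terminal("t", cost=10.0, effect=99.0),
                            effect_mode="scalar_override", scalar_effect=6.11)
        res = rollback(tree, EMPTY)
        assert res.expected_effect == 6.11

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_path_enumeration_oracle(self, random_tree_factory, seed):
        tree = random_tree_factory(seed)
        res = rollback(tree, EMPTY)
        paths = enumerate_paths(tree, EMPTY)
        assert res.expected_cost == pytest.approx(paths_expected_cost(paths), rel=1e-9)
        assert res.expected_effect == pytest.approx(paths_expected_effect(paths), rel=1e-9)


class TestPathEnumeration:
    def test_single_terminal_single_path(self):
        paths = enumerate_paths(StrategyTree("S", terminal("t", cost=5.0)), EMPTY)
        assert len(paths) == 1
        assert paths[0].probability == 1.0
        assert paths[0].node_labels == ["t"]

    def test_balanced_binary_depth_two(self):
        level1 = [chance(f"mid{i}", (0.5, terminal(f"l{i}0")), (0.5, terminal(f"l{i}1")))
                  for i in range(2)]
        tree = StrategyTree("S", chance("root", (0.5, level1[0]), (0.5, level1[1])))
        paths = enumerate_paths(tree, EMPTY)
        assert len(paths) == 4
        assert all(p.probability == pytest.approx(0.25) for p in paths)

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_path_probabilities_conserve_mass(self, random_tree_factory, seed):
        paths = enumerate_paths(random_tree_factory(seed), EMPTY)
        assert sum(p.probability for p in paths) == pytest.approx(1.0, abs=1e-9)


class TestMultilinearStructure:
    def test_three_point_collinearity_in_every_parameter(self, reference_model,
                                                         calibrated_params):
        """Expected cost is affine along each parameter axis."""
        for tree in reference_model.trees.values():
            referenced = referenced_parameters(tree)
            for name in select_varied(calibrated_params, "all"):
                if name not in referenced:
                    continue
                lo, hi = perturbation_endpoints(calibrated_params[name], 0.1)
                mid = (lo + hi) / 2.0
                f = lambda v: rollback(tree, calibrated_params, {name: v},
                                       normalize=True).expected_cost
                assert f(mid) == pytest.approx((f(lo) + f(hi)) / 2.0, rel=1e-9, abs=1e-9)

    def test_expected_cost_monotone_in_unit_costs(self, reference_model, calibrated_params):
        for tree in reference_model.trees.values():
            base = rollback(tree, calibrated_params).expected_cost
            for name in calibrated_params.subset(("unit_cost", "daily_cost")):
                bumped = rollback(tree, calibrated_params,
                                  {name: calibrated_params[name].value * 1.1}).expected_cost
                assert bumped >= base - 1e-9
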