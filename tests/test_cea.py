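import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stonecea.cea as cea_mod
from stonecea.cea import (
    compute_icer,
    convert_currency,
    joint_range,
    one_way_range,
    round_gbp,
    tornado,
)
from stonecea.expressions import as_expr
from stonecea.parameters import Parameter, ParameterSet
from stonecea.tree import Branch, StrategyTree, TreeNode, rollback


class TestComputeIcer:
    def test_published_base_case(self):
        res = compute_icer(4915.0, 7783.0, 3.76, 6.11, reference="EUL", comparator="DUL")
        assert res.delta_cost == pytest.approx(2868.0)
        assert res.delta_effect == pytest.approx(2.35)
        assert res.icer == pytest.approx(1220.43, abs=0.005)
        assert round_gbp(res.icer) == 1220
        assert res.dominance == "reference_dominates"

    def test_identical_inputs_have_no_icer(self):
        res = compute_icer(1000.0, 1000.0, 5.0, 5.0)
        assert res.delta_cost == 0.0 and res.delta_effect == 0.0
        assert res.icer is None and res.dominance == "none"

    def test_equal_effect_cheaper_reference_dominates(self):
        res = compute_icer(1000.0, 1100.0, 5.0, 5.0)
        assert res.icer is None
        assert res.dominance == "reference_dominates"

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_icer(-1.0, 10.0, 1.0, 2.0)

    @given(
        c1=st.floats(0, 1e5), c2=st.floats(0, 1e5),
        e1=st.floats(0, 100), e2=st.floats(0, 100),
    )
    def test_antisymmetry_under_strategy_swap(self, c1, c2, e1, e2):
        a = compute_icer(c1, c2, e1, e2)
        b = compute_icer(c2, c1, e2, e1)
        assert b.delta_cost == -a.delta_cost
        assert b.delta_effect == -a.delta_effect
        if a.icer is not None:
            assert b.icer == pytest.approx(a.icer, rel=1e-12)


class TestCurrency:
    def test_implied_study_rate(self):
        assert convert_currency(2868.0, 1.1367) == pytest.approx(3260.0556, abs=1e-3)
        assert round_gbp(convert_currency(2868.0, 1.1367)) == 3260

    @pytest.mark.parametrize("amount,rate,expected", [(0.0, 2.0, 0.0), (100.0, 1.0, 100.0)])
    def test_trivial_conversions(self, amount, rate, expected):
        assert convert_currency(amount, rate) == expected

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            convert_currency(1.0, 0.0)


def _toy_cost_tree(expr, params):
    tree = StrategyTree("toy", TreeNode("terminal", "t", payload_cost=as_expr(expr)))
    return {"toy": tree}, params


class TestOneWayRange:
    def test_unit_coefficient_linearity(self):
        trees, params = _toy_cost_tree("c", ParameterSet([Parameter("c", "unit_cost", 100.0)]))
        entry = one_way_range(trees, params, "c", 0.1, quantity=("expected_cost", "toy"))
        assert entry.low_result == pytest.approx(90.0)
        assert entry.high_result == pytest.approx(110.0)
        assert entry.swing == pytest.approx(20.0)

    def test_unreferenced_parameter_has_zero_swing(self):
        params = ParameterSet([Parameter("c", "unit_cost", 100.0),
                               Parameter("other", "unit_cost", 50.0)])
        trees, params = _toy_cost_tree("c", params)
        entry = one_way_range(trees, params, "other", 0.1, quantity=("expected_cost", "toy"))
        assert entry.swing == 0.0

    def test_fraction_bounds_enforced(self, reference_model, calibrated_params):
        with pytest.raises(ValueError):
            one_way_range(reference_model.trees, calibrated_params, "c_ct", 0.0)

    @pytest.mark.parametrize("name", ["daily_bed_cost", "p_readm_eul", "c_readm_eul",
                                      "p_stent_eul", "m_urs_eul"])
    def test_endpoints_bracket_grid_scan(self, reference_model, calibrated_params, name):
        tree = reference_model.trees["EUL"]
        entry = one_way_range(reference_model.trees, calibrated_params, name, 0.1,
                              quantity=("expected_cost", "EUL"))
        lo, hi = sorted((entry.low_result, entry.high_result))
        base = calibrated_params[name].value
        for factor in np.linspace(0.9, 1.1, 21):
            value = base * factor
            if calibrated_params[name].role == "probability":
                value = min(max(value, 0.0), 1.0)
            cost = rollback(tree, calibrated_params, {name: value},
                            normalize=True).expected_cost
            assert lo - 1e-9 <= cost <= hi + 1e-9

    def test_tornado_sorted_by_swing(self, reference_model, calibrated_params):
        entries = tornado(reference_model.trees, calibrated_params, 0.1,
                          quantity="delta_cost", reference="EUL", comparator="DUL")
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)
        assert all(s >= 0.0 for s in swings)


def _two_param_pair():
    """Two one-terminal strategies sharing one parameter."""
    params = ParameterSet([
        Parameter("a", "unit_cost", 100.0),
        Parameter("b", "unit_cost", 50.0),
        Parameter("p", "probability", 0.4),
    ])
    ref = StrategyTree("R", TreeNode("chance", "r", branches=[
        Branch(as_expr("p"), TreeNode("terminal", "hi", payload_cost=as_expr("a + b"))),
        Branch(as_expr("1 - p"), TreeNode("terminal", "lo", payload_cost=as_expr("b"))),
    ]), effect_mode="scalar_override", scalar_effect=2.0)
    cmp_ = StrategyTree("C", TreeNode("terminal", "t", payload_cost=as_expr("3 * a")),
                        effect_mode="scalar_override", scalar_effect=5.0)
    return {"R": ref, "C": cmp_}, params


class TestJointRange:
    def test_single_parameter_interval(self):
        trees, params = _toy_cost_tree("c", ParameterSet([Parameter("c", "unit_cost", 100.0)]))
        out = joint_range(trees, params, 0.1)
        assert out["toy"].low == pytest.approx(90.0)
        assert out["toy"].high == pytest.approx(110.0)

    def test_vertex_enumeration_matches_dense_grid(self):
        trees, params = _two_param_pair()
        out = joint_range(trees, params, 0.1)
        grid = np.linspace(0.9, 1.1, 11)
        costs_r, costs_c, icers = [], [], []
        for fa in grid:
            for fb in grid:
                for fp in grid:
                    ov = {"a": 100.0 * fa, "b": 50.0 * fb, "p": 0.4 * fp}
                    r = rollback(trees["R"], params, ov, normalize=True)
                    c = rollback(trees["C"], params, ov, normalize=True)
                    costs_r.append(r.expected_cost)
                    costs_c.append(c.expected_cost)
                    icers.append((c.expected_cost - r.expected_cost) / 3.0)
        assert out["R"].low == pytest.approx(min(costs_r), rel=1e-6)
        assert out["R"].high == pytest.approx(max(costs_r), rel=1e-6)
        assert out["C"].low == pytest.approx(min(costs_c), rel=1e-6)
        assert out["C"].high == pytest.approx(max(costs_c), rel=1e-6)
        assert out["icer"].low == pytest.approx(min(icers), rel=1e-6)
        assert out["icer"].high == pytest.approx(max(icers), rel=1e-6)

    def test_coordinate_search_matches_exact_enumeration(self, reference_model,
                                                         calibrated_params, monkeypatch):
        exact = joint_range(reference_model.trees, calibrated_params, 0.1, seed=0)
        monkeypatch.setattr(cea_mod, "MAX_EXACT_VERTICES", 0)
        monkeypatch.setattr(cea_mod, "MAX_SHARED_VERTICES", -1)
        approx = joint_range(reference_model.trees, calibrated_params, 0.1, seed=0)
        for key in exact:
            assert approx[key].low == pytest.approx(exact[key].low, rel=1e-6)
            assert approx[key].high == pytest.approx(exact[key].high, rel=1e-6)

    def test_restricting_varied_set_narrows_ranges(self, reference_model, calibrated_params):
        full = joint_range(reference_model.trees, calibrated_params, 0.1, vary="all")
        costs_only = joint_range(reference_model.trees, calibrated_params, 0.1, vary="costs")
        for key in full:
            assert costs_only[key].low >= full[key].low - 1e-9
            assert costs_only[key].high <= full[key].high + 1e-9

    def test_containment_and_nesting(self, reference_model, calibrated_params):
        wide = joint_range(reference_model.trees, calibrated_params, 0.10)
        narrow = joint_range(reference_model.trees, calibrated_params, 0.05)
        for key, r in wide.items():
            assert r.low <= r.base <= r.high
            assert narrow[key].low >= r.low - 1e-9
            assert narrow[key].high <= r.high + 1e-9
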