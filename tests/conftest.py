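import numpy as np
import pytest
from hypothesis import settings

import stonecea as sc
from stonecea.expressions import as_expr
from stonecea.tree import Branch, StrategyTree, TreeNode

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_model():
    """The packaged EUL-vs-DUL model with its unit-cost tables resolved."""
    return sc.load_reference_model()[0]


@pytest.fixture(scope="session")
def calibrated_params(reference_model):
    return sc.calibrate_free_parameters(
        reference_model.trees,
        reference_model.parameters,
        reference_model.calibration_targets,
        seed=0,
    )


def _random_node(rng, depth, max_depth, max_branch) -> TreeNode:
    if depth >= max_depth or (depth > 0 and rng.random() < 0.35):
        return TreeNode(
            "terminal",
            f"leaf d{depth}",
            payload_cost=float(rng.uniform(0.0, 1000.0)),
            payload_effect=float(rng.uniform(0.0, 10.0)),
        )
    n_branches = int(rng.integers(2, max_branch + 1))
    probs = rng.dirichlet(np.ones(n_branches))
    branches = [
        Branch(as_expr(float(p)), _random_node(rng, depth + 1, max_depth, max_branch))
        for p in probs
    ]
    return TreeNode(
        "chance",
        f"chance d{depth}",
        payload_cost=float(rng.uniform(0.0, 500.0)),
        branches=branches,
    )


@pytest.fixture(scope="session")
def random_tree_factory():
    """Build random chance trees (constant probabilities and payoffs)."""

    def factory(seed: int, max_depth: int = 5, max_branch: int = 4) -> StrategyTree:
        rng = np.random.default_rng(seed)
        return StrategyTree(f"random-{seed}", _random_node(rng, 0, max_depth, max_branch))

    return factory
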