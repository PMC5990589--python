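"""Shared solved models (session-scoped: policy iteration is deterministic)."""

from __future__ import annotations

import pytest

from optbounds.boundaries import extract_boundary
from optbounds.mdp import DriftMixture, RewardConfig, TaskModel
from optbounds.solver import solve_optimal


def solve_with_boundary(model):
    solution = solve_optimal(model)
    return model, solution, extract_boundary(solution.policy, model)


@pytest.fixture(scope="session")
def single_medium():
    """Single difficulty u in {0.30, 0.70}, D = 150: the canonical flat bound."""
    return solve_with_boundary(
        TaskModel(DriftMixture.single(0.20), RewardConfig(D_C=150.0, D_I=150.0))
    )


@pytest.fixture(scope="session")
def mixed_zero_drift():
    """Mixture of drifts {0.20, 0} with P(easy) = 1/2, D = 150: collapsing."""
    return solve_with_boundary(
        TaskModel(
            DriftMixture.two_difficulty(0.20, 0.0),
            RewardConfig(D_C=150.0, D_I=150.0),
        )
    )


@pytest.fixture(scope="session")
def increasing_mixture():
    """Mixture u in {0.05, 0.40, 0.60, 0.95}, D = 150, long horizon: increasing."""
    return solve_with_boundary(
        TaskModel(
            DriftMixture.two_difficulty(0.45, 0.10),
            RewardConfig(D_C=150.0, D_I=150.0),
            t_max=100,
        )
    )


@pytest.fixture(scope="session")
def biased_prior():
    """Single difficulty with P(U in U+) = 0.70, D = 150: shifted bounds."""
    return solve_with_boundary(
        TaskModel(
            DriftMixture.single(0.20, p_plus=0.70), RewardConfig(D_C=150.0, D_I=150.0)
        )
    )
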