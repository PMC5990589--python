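"""Lattice bookkeeping, drift posteriors, and transition probabilities."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optbounds.mdp import (
    DriftMixture,
    EvidenceState,
    RewardConfig,
    TaskModel,
    drift_posterior,
    enumerate_states,
    go_transition,
    n_states,
    posterior_maps,
    state_index,
    wait_transition,
)


# ---------------------------------------------------------------------------
# lattice


class TestLattice:
    def test_minimal_horizon(self):
        assert {(s.t, s.x) for s in enumerate_states(1)} == {(0, 0), (1, -1), (1, 1)}

    @pytest.mark.parametrize("t_max,count", [(2, 6), (70, 2556)])
    def test_state_count_matches_closed_form(self, t_max, count):
        states = enumerate_states(t_max)
        assert len(states) == count == n_states(t_max)

    def test_canonical_order_matches_index(self):
        for i, s in enumerate(enumerate_states(9)):
            assert state_index(s.t, s.x) == i

    def test_rejects_non_positive_horizon(self):
        with pytest.raises(ValueError):
            enumerate_states(0)

    @pytest.mark.parametrize("t,x", [(1, 0), (2, 3), (-1, 0), (3, -2)])
    def test_rejects_off_lattice_states(self, t, x):
        with pytest.raises(ValueError):
            EvidenceState(t, x)


# ---------------------------------------------------------------------------
# posteriors


def brute_force_posterior(t, x, mixture):
    """Oracle: enumerate every +-1 sample path and apply Bayes directly."""
    joint = np.zeros(len(mixture.support))
    for k, (u, w) in enumerate(zip(mixture.support, mixture.prior)):
        for path in itertools.product((1, -1), repeat=t):
            if sum(path) != x:
                continue
            p = w
            for step in path:
                p *= u if step == 1 else 1.0 - u
            joint[k] += p
    return joint / joint.sum()


class TestDriftPosterior:
    def test_origin_returns_prior(self):
        mix = DriftMixture(support=(0.3, 0.5, 0.7), prior=(0.25, 0.5, 0.25))
        np.testing.assert_allclose(
            drift_posterior(EvidenceState(0, 0), mix), mix.prior_array
        )

    def test_one_up_sample_two_point_mixture(self):
        mix = DriftMixture.single(0.20)
        post = drift_posterior(EvidenceState(1, 1), mix)
        np.testing.assert_allclose(post, [0.3, 0.7])

    def test_balanced_evidence_three_point_mixture(self):
        # P(0.5 | t=4, x=0) = 0.5*0.0625 / (0.25*0.0441 + 0.5*0.0625 + 0.25*0.0441)
        mix = DriftMixture(support=(0.3, 0.5, 0.7), prior=(0.25, 0.5, 0.25))
        post = drift_posterior(EvidenceState(4, 0), mix)
        np.testing.assert_allclose(post[1], 0.03125 / 0.0533, rtol=1e-10)

    @pytest.mark.parametrize(
        "mixture",
        [
            DriftMixture.single(0.20),
            DriftMixture.two_difficulty(0.20, 0.0),
            DriftMixture(support=(0.1, 0.45, 0.8), prior=(0.2, 0.5, 0.3)),
            DriftMixture.single(0.20, p_plus=0.7),
        ],
        ids=["single", "zero-drift-mix", "asymmetric", "biased"],
    )
    def test_agrees_with_path_enumeration_oracle(self, mixture):
        for t in range(9):
            for x in range(-t, t + 1, 2):
                expected = brute_force_posterior(t, x, mixture)
                got = drift_posterior(EvidenceState(t, x), mixture)
                np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_reflection_symmetry(self):
        # symmetric mixture, equal world priors: P(u | t, x) = P(1-u | t, -x)
        # (to machine precision; the mirrored supports differ in the last ulp)
        mix = DriftMixture.two_difficulty(0.20, 0.05)
        for t, x in [(3, 1), (8, 4), (15, -7), (40, 10)]:
            fwd = drift_posterior(EvidenceState(t, x), mix)
            bwd = drift_posterior(EvidenceState(t, -x), mix)
            # support is sorted, so u <-> 1-u is an index reversal
            np.testing.assert_allclose(fwd, bwd[::-1], rtol=1e-13, atol=1e-15)

    def test_stable_at_large_t(self):
        mix = DriftMixture.two_difficulty(0.20, 0.0)
        post = drift_posterior(EvidenceState(400, 10), mix)
        assert np.all(np.isfinite(post))
        assert abs(post.sum() - 1.0) < 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(
        us=st.lists(
            st.floats(0.01, 0.99), min_size=1, max_size=6, unique=True
        ),
        ws=st.lists(st.floats(0.05, 1.0), min_size=6, max_size=6),
        t=st.integers(0, 30),
        frac=st.floats(0.0, 1.0),
    )
    def test_posterior_normalized_for_arbitrary_mixtures(self, us, ws, t, frac):
        w = np.array(ws[: len(us)])
        mix = DriftMixture(tuple(sorted(us)), tuple(w / w.sum()))
        n_up = int(round(frac * t))
        post = drift_posterior(EvidenceState(t, 2 * n_up - t), mix)
        assert abs(post.sum() - 1.0) < 1e-12
        assert np.all(post >= 0)


# ---------------------------------------------------------------------------
# transitions


class TestTransitions:
    def test_zero_drift_source_predicts_even_odds(self):
        mix = DriftMixture.single(0.0)
        assert wait_transition(EvidenceState(6, 2), mix).p_up == pytest.approx(0.5)

    def test_symmetric_origin_predicts_even_odds(self):
        mix = DriftMixture.single(0.20)
        tr = wait_transition(EvidenceState(0, 0), mix)
        assert tr.p_up == pytest.approx(0.5)
        assert tr.p_up + tr.p_down == pytest.approx(1.0)

    def test_one_up_sample_posterior_predictive(self):
        mix = DriftMixture.single(0.20)
        tr = wait_transition(EvidenceState(1, 1), mix)
        assert tr.p_up == pytest.approx(0.7 * 0.7 + 0.3 * 0.3)

    def test_go_at_origin_is_a_coin_flip(self):
        mix = DriftMixture.single(0.20)
        tr = go_transition(EvidenceState(0, 0), mix)
        assert tr.p_correct == pytest.approx(0.5)
        assert tr.chosen_alternative == "buy"  # deterministic tie-break

    def test_go_after_one_up_sample(self):
        mix = DriftMixture.single(0.20)
        tr = go_transition(EvidenceState(1, 1), mix)
        assert tr.chosen_alternative == "buy"
        assert tr.p_correct == pytest.approx(0.7)

    def test_half_splitting_rule_at_balanced_evidence(self):
        # u = 1/2 belongs half to each world state, so p_correct stays 1/2
        mix = DriftMixture.two_difficulty(0.20, 0.0)
        tr = go_transition(EvidenceState(2, 0), mix)
        assert tr.p_correct == pytest.approx(0.5)

    def test_negative_evidence_selects_sell(self):
        mix = DriftMixture.single(0.20)
        assert go_transition(EvidenceState(1, -1), mix).chosen_alternative == "sell"


# ---------------------------------------------------------------------------
# posterior maps


class TestPosteriorMaps:
    def test_origin_equals_priors(self):
        model = TaskModel(
            DriftMixture.two_difficulty(0.20, 0.0, p_easy=0.3), RewardConfig(), t_max=10
        )
        maps = posterior_maps(model)
        row = maps[(maps.t == 0) & (maps.x == 0)].iloc[0]
        assert row.p_easy == pytest.approx(0.3)
        assert row.p_plus == pytest.approx(0.5)

    def test_equal_prior_reflection(self):
        model = TaskModel(DriftMixture.two_difficulty(0.20, 0.0), RewardConfig(), t_max=20)
        maps = posterior_maps(model).set_index(["t", "x"])
        for t, x in [(4, 2), (10, 6), (19, -3)]:
            assert maps.loc[(t, x), "p_plus"] + maps.loc[(t, -x), "p_plus"] == pytest.approx(1.0)

    def test_confidence_decays_with_time_at_fixed_evidence(self):
        # mixed difficulty: the longer the trial, the likelier it is difficult,
        # so the same evidence level supports the rising state less
        model = TaskModel(DriftMixture.two_difficulty(0.20, 0.0), RewardConfig(), t_max=40)
        maps = posterior_maps(model).set_index(["t", "x"])
        vals = [maps.loc[(t, 4), "p_plus"] for t in range(4, 40, 2)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_single_difficulty_maps_depend_only_on_evidence(self):
        model = TaskModel(DriftMixture.single(0.20), RewardConfig(), t_max=30)
        maps = posterior_maps(model)
        assert np.allclose(maps.p_easy, 1.0)
        for x in (2, -4):
            vals = maps[maps.x == x].p_plus.to_numpy()
            assert np.allclose(vals, vals[0])

    def test_difficulty_map_independent_of_world_prior(self):
        kw = dict(rewards=RewardConfig(), t_max=25)
        base = posterior_maps(
            TaskModel(DriftMixture.two_difficulty(0.20, 0.0, p_plus=0.5), **kw)
        )
        for p_plus in (0.52, 0.70):
            other = posterior_maps(
                TaskModel(DriftMixture.two_difficulty(0.20, 0.0, p_plus=p_plus), **kw)
            )
            np.testing.assert_allclose(other.p_easy, base.p_easy, atol=1e-12)


# ---------------------------------------------------------------------------
# mixture and reward construction


class TestConstruction:
    def test_from_drifts_realizes_requested_world_prior(self):
        mix = DriftMixture.two_difficulty(0.20, 0.0, p_plus=0.70)
        assert mix.p_plus == pytest.approx(0.70)
        assert mix.p_easy == pytest.approx(0.5)

    def test_unrealizable_world_prior_is_rejected(self):
        # half the mass sits on u = 1/2, capping P(U in U+) at 0.75
        with pytest.raises(ValueError):
            DriftMixture.two_difficulty(0.20, 0.0, p_plus=0.90)

    def test_duplicate_drifts_are_merged(self):
        mix = DriftMixture.from_drifts([0.2, 0.2, 0.0])
        assert mix.support == (0.3, 0.5, 0.7)
        assert sum(mix.prior) == pytest.approx(1.0)

    def test_prior_must_normalize(self):
        with pytest.raises(ValueError):
            DriftMixture(support=(0.3, 0.7), prior=(0.5, 0.6))

    def test_inconsistent_delays_are_rejected(self):
        with pytest.raises(ValueError):
            RewardConfig(D_C=100.0, D_I=120.0, D_p=75.0)

    def test_error_penalty_derives_error_delay(self):
        rw = RewardConfig(D_C=75.0, D_p=75.0)
        assert rw.D_I == 150.0

    def test_pass_action_requires_pass_delay(self):
        with pytest.raises(ValueError):
            TaskModel(
                DriftMixture.single(0.2),
                RewardConfig(),
                actions=("wait", "go", "pass"),
            )
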