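"""Seeded Monte-Carlo simulation of the bounded random walk under a policy.

This is the independent check on the dynamic-programming solution: run the
renewal process trial by trial (draw an up-probability from the mixture
prior, follow the policy through the walk, collect rewards and delays) and
estimate the empirical reward rate, which must converge to the solver's rho
at roughly 1/sqrt(n_trials).

Each trial uses its own deterministic substream spawned from the master seed,
so trial i is reproducible in isolation and results are bit-identical for a
given (seed, n_trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mdp import TaskModel
from .solver import GO, PASS, WAIT, Policy

__all__ = ["SimulationResult", "simulate_policy"]


@dataclass(frozen=True)
class SimulationResult:
    """Aggregate outcome of a simulated block of trials."""

    n_trials: int
    seed: int
    reward_rate: float
    reward_rate_se: float
    total_reward: float
    total_time: float
    accuracy: float
    accuracy_by_drift: dict[float, float]
    decision_time_counts: np.ndarray
    pass_fraction: float

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationResult):
            return NotImplemented
        return (
            self.n_trials == other.n_trials
            and self.seed == other.seed
            and self.reward_rate == other.reward_rate
            and self.reward_rate_se == other.reward_rate_se
            and self.total_reward == other.total_reward
            and self.total_time == other.total_time
            and self.accuracy == other.accuracy
            and self.accuracy_by_drift == other.accuracy_by_drift
            and np.array_equal(self.decision_time_counts, other.decision_time_counts)
            and self.pass_fraction == other.pass_fraction
        )


def simulate_policy(
    model: TaskModel,
    policy: Policy,
    n_trials: int,
    seed: int,
    n_bootstrap: int = 200,
) -> SimulationResult:
    """Simulate ``n_trials`` renewal cycles under a fixed policy.

    Per trial: draw u from the mixture prior, run the +-1 walk following the
    policy (waiting at the horizon is the forced loss), accrue the reward and
    the one-step-per-action plus outcome-delay time.  The reward-rate
    standard error is a per-trial bootstrap of the ratio estimator.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if policy.t_max != model.t_max:
        raise ValueError("policy horizon does not match the model")
    rw = model.rewards
    mix = model.mixture
    support = mix.support_array
    prior = mix.prior_array
    T = model.t_max

    # policy and buy-side lookup as dense [t][(t+x)/2] grids for the loop
    act_grid = [policy.actions[t * (t + 1) // 2 : (t + 1) * (t + 2) // 2] for t in range(T + 1)]
    from .mdp import transition_tables

    tab = transition_tables(model)
    buy_grid = [tab.buy[t * (t + 1) // 2 : (t + 1) * (t + 2) // 2] for t in range(T + 1)]

    master = np.random.SeedSequence(seed)
    rewards = np.empty(n_trials)
    times = np.empty(n_trials)
    dt_counts = np.zeros(T + 1, dtype=np.int64)
    n_pass = 0
    correct_by_u: dict[float, list[int]] = {float(u): [0, 0] for u in support}

    for i in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        u_idx = rng.choice(len(support), p=prior)
        u = float(support[u_idx])
        t, x = 0, 0
        while True:
            a = act_grid[t][(t + x) // 2]
            if a == WAIT and t == T:  # forced loss at the horizon
                a, forced = GO, True
            else:
                forced = False
            if a == WAIT:
                x += 1 if rng.random() < u else -1
                t += 1
                continue
            dt_counts[t] += 1
            if a == PASS:
                n_pass += 1
                rewards[i] = rw.pass_reward
                times[i] = t + 1 + rw.pass_delay
            else:
                if forced:
                    correct = False
                else:
                    buy = bool(buy_grid[t][(t + x) // 2])
                    if abs(u - 0.5) <= 1e-12:
                        correct = bool(rng.random() < 0.5)
                    else:
                        correct = buy == (u > 0.5)
                tally = correct_by_u[u]
                tally[0] += int(correct)
                tally[1] += 1
                rewards[i] = rw.R_C if correct else rw.R_I
                times[i] = t + 1 + (rw.D_C if correct else rw.D_I)
            break

    total_reward = float(rewards.sum())
    total_time = float(times.sum())
    rate = total_reward / total_time

    boot_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(n_trials, 1))
    )
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = boot_rng.integers(0, n_trials, size=n_trials)
        boot[b] = rewards[idx].sum() / times[idx].sum()
    se = float(boot.std(ddof=1)) if n_bootstrap > 1 else float("nan")

    n_decided = sum(n for _, n in correct_by_u.values())
    n_correct = sum(c for c, _ in correct_by_u.values())
    drift_tally: dict[float, list[int]] = {}
    for u, (c, n) in correct_by_u.items():
        d = round(abs(u - 0.5), 12)
        tally = drift_tally.setdefault(d, [0, 0])
        tally[0] += c
        tally[1] += n
    acc_by_drift = {d: c / n for d, (c, n) in drift_tally.items() if n}

    return SimulationResult(
        n_trials=n_trials,
        seed=seed,
        reward_rate=rate,
        reward_rate_se=se,
        total_reward=total_reward,
        total_time=total_time,
        accuracy=(n_correct / n_decided) if n_decided else float("nan"),
        accuracy_by_drift=acc_by_drift,
        decision_time_counts=dt_counts,
        pass_fraction=n_pass / n_trials,
    )
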