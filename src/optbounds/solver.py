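"""Average-reward policy iteration on the evidence lattice.

Policy evaluation solves the relative-value equations of average-reward
dynamic programming exactly: for a fixed policy pi the unknowns are the
relative values v_(t,x), the outcome values v_C, v_I (and the pass outcome),
and the gain rho (average reward per unit time).  Every transition -- wait,
go, or pass -- takes one time step; the outcome states then add their
inter-trial delay, so

    v_C = R_C + v_(0,0) - D_C * rho,      v_I = R_I + v_(0,0) - D_I * rho,

and waiting at the horizon t_max is a forced transition to the incorrect
outcome.  The system has a one-dimensional gauge freedom (adding a constant
to all values), closed by the identification v_(0,0) = 0.  Evaluation builds
one sparse linear system over all lattice states plus rho and solves it
directly, which is exact and fast at the few thousand states involved.

Policy improvement is greedy: wait is selected only where its one-step
look-ahead value strictly exceeds the best of go/pass (ties go to go, then
pass), and iterating evaluation/improvement from the all-go policy converges
to the reward-rate-optimal policy in a finite number of steps, with rho
non-decreasing along the way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .mdp import TaskModel, TransitionTables, n_states, state_index, transition_tables

__all__ = [
    "WAIT",
    "GO",
    "PASS",
    "ACTION_NAMES",
    "Policy",
    "ValueSolution",
    "OptimalSolution",
    "SolverError",
    "ConvergenceError",
    "all_go_policy",
    "mirror_policy",
    "evaluate_policy",
    "improve_policy",
    "solve_optimal",
]

WAIT, GO, PASS = 0, 1, 2
ACTION_NAMES = ("wait", "go", "pass")

#: relative tolerance used to collapse numerically tied action values
ACTION_TIE_RTOL = 1e-10


class SolverError(RuntimeError):
    """Malformed model: the policy-evaluation system is singular."""


class ConvergenceError(RuntimeError):
    """Policy iteration failed to reach a fixed point within the cap."""


@dataclass(frozen=True)
class Policy:
    """Action per lattice state, in canonical state order."""

    t_max: int
    actions: np.ndarray  # int8 codes, WAIT/GO/PASS

    def __post_init__(self) -> None:
        if len(self.actions) != n_states(self.t_max):
            raise ValueError("policy must cover every lattice state up to t_max")

    def action_code(self, t: int, x: int) -> int:
        return int(self.actions[state_index(t, x)])

    def action(self, t: int, x: int) -> str:
        return ACTION_NAMES[self.action_code(t, x)]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Policy)
            and self.t_max == other.t_max
            and np.array_equal(self.actions, other.actions)
        )

    def __hash__(self) -> int:  # pragma: no cover - not used as dict key
        return hash((self.t_max, self.actions.tobytes()))


@dataclass(frozen=True)
class ValueSolution:
    """Solution (rho, v) of the relative-value equations for one policy."""

    rho: float
    v: np.ndarray
    v_correct: float
    v_incorrect: float
    v_pass: float | None = None

    def value(self, t: int, x: int) -> float:
        return float(self.v[state_index(t, x)])


@dataclass(frozen=True)
class OptimalSolution:
    """Fixed point of policy iteration; unpacks as (policy, values)."""

    policy: Policy
    values: ValueSolution
    iterations: int
    rho_history: tuple[float, ...]

    def __iter__(self) -> Iterator:
        return iter((self.policy, self.values))


def mirror_policy(policy: Policy) -> Policy:
    """The policy reflected through x -> -x (row-reversed at each t)."""
    actions = policy.actions.copy()
    for t in range(policy.t_max + 1):
        sl = slice(t * (t + 1) // 2, (t + 1) * (t + 2) // 2)
        actions[sl] = actions[sl][::-1]
    return Policy(policy.t_max, actions)


def all_go_policy(model: TaskModel) -> Policy:
    """The initialization used by policy iteration: go in every state."""
    return Policy(model.t_max, np.full(n_states(model.t_max), GO, dtype=np.int8))


def evaluate_policy(
    model: TaskModel, policy: Policy, tables: TransitionTables | None = None
) -> ValueSolution:
    """Solve the linear relative-value system for a fixed policy.

    Unknowns are the state values (canonical order) followed by rho; the
    state equations plus the identification row v_(0,0) = 0 close the
    square system.
    """
    if policy.t_max != model.t_max:
        raise ValueError("policy horizon does not match the model")
    tab = tables if tables is not None else transition_tables(model)
    rw = model.rewards
    N = n_states(model.t_max)
    acts = policy.actions
    if np.any(acts == PASS) and not model.allow_pass:
        raise ValueError("policy uses pass but the model does not allow it")

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(N + 1)
    idx = np.arange(N)
    rho_col = N

    def add(r, c, v) -> None:
        rows.append(np.atleast_1d(r).astype(np.int64))
        cols.append(np.atleast_1d(c).astype(np.int64))
        vals.append(np.atleast_1d(v).astype(float))

    # diagonal for every state equation
    add(idx, idx, np.ones(N))

    interior = tab.t < model.t_max
    wait_i = (acts == WAIT) & interior
    if np.any(wait_i):
        i = idx[wait_i]
        up = ((tab.t[wait_i] + 1) * (tab.t[wait_i] + 2)) // 2 + (
            tab.t[wait_i] + 1 + tab.x[wait_i] + 1
        ) // 2
        dn = up - 1
        add(i, up, -tab.p_up[wait_i])
        add(i, dn, -(1.0 - tab.p_up[wait_i]))
        add(i, np.full(i.shape, rho_col), np.ones(i.size))

    # waiting at the horizon is a forced loss: one step, then the I outcome
    wait_T = (acts == WAIT) & ~interior
    if np.any(wait_T):
        i = idx[wait_T]
        add(i, np.full(i.shape, rho_col), np.full(i.size, 1.0 + rw.D_I))
        rhs[i] = rw.R_I

    go_m = acts == GO
    if np.any(go_m):
        i = idx[go_m]
        pc = tab.p_correct[go_m]
        add(i, np.full(i.shape, rho_col), 1.0 + pc * rw.D_C + (1.0 - pc) * rw.D_I)
        rhs[i] = pc * rw.R_C + (1.0 - pc) * rw.R_I

    pass_m = acts == PASS
    if np.any(pass_m):
        i = idx[pass_m]
        add(i, np.full(i.shape, rho_col), np.full(i.size, 1.0 + rw.pass_delay))

    # identification v_(0,0) = 0
    add(np.array([N]), np.array([0]), np.array([1.0]))

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N + 1, N + 1),
    )
    with np.errstate(all="ignore"):
        sol = spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(sol)):
        raise SolverError("singular policy-evaluation system (malformed model)")
    resid = np.abs(A @ sol - rhs).max()
    if resid > 1e-7 * max(1.0, np.abs(rhs).max()):
        raise SolverError(f"policy-evaluation solve inaccurate (residual {resid:g})")

    rho = float(sol[rho_col])
    v = sol[:N]
    return ValueSolution(
        rho=rho,
        v=v,
        v_correct=rw.R_C - rw.D_C * rho,
        v_incorrect=rw.R_I - rw.D_I * rho,
        v_pass=(-rw.pass_delay * rho) if model.allow_pass else None,
    )


def _action_values(
    model: TaskModel, values: ValueSolution, tab: TransitionTables
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """One-step look-ahead value of wait / go / pass in every state."""
    rw = model.rewards
    rho, v = values.rho, values.v
    v_C = rw.R_C - rw.D_C * rho
    v_I = rw.R_I - rw.D_I * rho

    q_wait = np.empty(len(v))
    interior = tab.t < model.t_max
    up = ((tab.t + 1) * (tab.t + 2)) // 2 + (tab.t + 1 + tab.x + 1) // 2
    q_wait[interior] = (
        tab.p_up[interior] * v[up[interior]]
        + (1.0 - tab.p_up[interior]) * v[up[interior] - 1]
        - rho
    )
    q_wait[~interior] = v_I - rho

    q_go = tab.p_correct * v_C + (1.0 - tab.p_correct) * v_I - rho
    q_pass = None
    if model.allow_pass:
        q_pass = np.full(len(v), -rw.pass_delay * rho - rho)
    return q_wait, q_go, q_pass


def improve_policy(
    model: TaskModel,
    values: ValueSolution,
    tables: TransitionTables | None = None,
) -> Policy:
    """Greedy improvement: wait only where it strictly beats go and pass.

    Exact (and numerically near-exact) ties are resolved in favor of go,
    then pass, so the iteration is deterministic.
    """
    tab = tables if tables is not None else transition_tables(model)
    q_wait, q_go, q_pass = _action_values(model, values, tab)
    scale = max(
        1.0, float(np.max(np.abs(q_go))), float(np.max(np.abs(q_wait)))
    )
    tol = ACTION_TIE_RTOL * scale

    if q_pass is None:
        best_commit = q_go
        commit = np.full(len(q_go), GO, dtype=np.int8)
    else:
        take_pass = q_pass > q_go + tol  # go preferred on ties
        best_commit = np.where(take_pass, q_pass, q_go)
        commit = np.where(take_pass, PASS, GO).astype(np.int8)

    actions = np.where(q_wait > best_commit + tol, WAIT, commit).astype(np.int8)
    return Policy(model.t_max, actions)


def solve_optimal(model: TaskModel, max_iter: int = 500) -> OptimalSolution:
    """Policy iteration from the all-go policy to the optimal fixed point."""
    tab = transition_tables(model)
    policy = all_go_policy(model)
    rho_history: list[float] = []
    for it in range(1, max_iter + 1):
        values = evaluate_policy(model, policy, tab)
        rho_history.append(values.rho)
        new_policy = improve_policy(model, values, tab)
        if new_policy == policy:
            return OptimalSolution(policy, values, it, tuple(rho_history))
        policy = new_policy
    raise ConvergenceError(
        f"policy iteration did not converge within {max_iter} iterations "
        "(numerical cycling)"
    )
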