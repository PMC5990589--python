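"""State space, Bayesian drift inference, and state-transition probabilities.

The model: a decision-maker watches a stream of binary evidence samples.  Each
sample goes *up* with an unknown up-probability ``u`` and *down* otherwise.
``u > 1/2`` means the world is in the "rising" state (the correct answer is
*buy*), ``u < 1/2`` means "falling" (*sell*), and the drift ``|u - 1/2|``
measures how informative each sample is -- ``u = 1/2`` samples carry no signal
at all.  On every trial ``u`` is drawn from a known finite mixture, so the
decision-maker is uncertain both about the state of the world and about the
difficulty of the current trial.

The decision-maker's state within a trial is the pair ``(t, x)``: the number
of samples observed and the cumulative evidence (number of ups minus downs).
These states live on the random-walk lattice ``|x| <= t``, ``t + x`` even.
Because every path from the origin to ``(t, x)`` contains the same number of
up and down steps, the path count cancels from the posterior over ``u``, which
is simply

    P(u | t, x)  ~  u**((t+x)/2) * (1-u)**((t-x)/2) * P(u)

normalized over the mixture support.  All transition probabilities (the
predictive up-probability under *wait*, the probability of being correct under
*go*) follow from this posterior by marginalization.  When ``u = 1/2`` is in
the support, it belongs half to the rising and half to the falling state of
the world, and its posterior mass is split accordingly when scoring a *go*.

Likelihoods are accumulated in log space so that states with ``t`` in the
hundreds remain well conditioned.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "EvidenceState",
    "DriftMixture",
    "RewardConfig",
    "TaskModel",
    "TransitionProbs",
    "TransitionTables",
    "enumerate_states",
    "n_states",
    "state_index",
    "lattice_arrays",
    "drift_posterior",
    "wait_transition",
    "go_transition",
    "transition_tables",
    "posterior_maps",
    "posterior_maps_long",
]

#: tolerance for recognizing the zero-drift element u == 1/2
HALF_ATOL = 1e-12


@dataclass(frozen=True)
class EvidenceState:
    """A node ``(t, x)`` of the evidence random-walk lattice.

    ``t`` is the number of samples observed, ``x = n_up - n_down`` the
    cumulative evidence.  Valid states satisfy ``|x| <= t`` and ``t + x``
    even (lattice parity).
    """

    t: int
    x: int

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"time step must be non-negative, got t={self.t}")
        if abs(self.x) > self.t:
            raise ValueError(f"evidence |x| <= t violated: (t={self.t}, x={self.x})")
        if (self.t + self.x) % 2 != 0:
            raise ValueError(f"off-lattice state (t + x must be even): (t={self.t}, x={self.x})")

    @property
    def n_up(self) -> int:
        return (self.t + self.x) // 2

    @property
    def n_down(self) -> int:
        return (self.t - self.x) // 2


def _is_half(u: float) -> bool:
    return abs(u - 0.5) <= HALF_ATOL


@dataclass(frozen=True)
class DriftMixture:
    """Finite mixture of up-probabilities with prior weights.

    ``support`` lists the possible up-probabilities ``u`` in [0, 1] and
    ``prior`` their weights (summing to one).  ``easy`` flags which support
    elements belong to the easy difficulty class; by default the elements at
    the largest drift are easy.  The element ``u = 1/2`` (if present) belongs
    half to each state of the world.

    Prefer the constructors :meth:`from_drifts`, :meth:`two_difficulty`, and
    :meth:`single` over positional construction.
    """

    support: tuple[float, ...]
    prior: tuple[float, ...]
    easy: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if len(self.support) == 0:
            raise ValueError("mixture support must be non-empty")
        if len(self.support) != len(self.prior):
            raise ValueError("support and prior must have equal length")
        if any(u < 0.0 or u > 1.0 for u in self.support):
            raise ValueError("every up-probability must lie in [0, 1]")
        if any(w < 0.0 for w in self.prior):
            raise ValueError("prior weights must be non-negative")
        total = float(sum(self.prior))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prior weights must sum to 1 (got {total})")
        if len(self.easy) == 0:
            drifts = [abs(u - 0.5) for u in self.support]
            dmax = max(drifts)
            object.__setattr__(
                self, "easy", tuple(abs(d - dmax) <= HALF_ATOL for d in drifts)
            )
        elif len(self.easy) != len(self.support):
            raise ValueError("easy flags must match support length")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_drifts(
        cls,
        drifts: Sequence[float],
        weights: Sequence[float] | None = None,
        p_plus: float = 0.5,
        easy_drifts: Sequence[float] | None = None,
    ) -> "DriftMixture":
        """Build a mixture from drift magnitudes ``eps`` (``u = 1/2 +- eps``).

        ``weights`` is the probability of each drift level (uniform by
        default).  ``p_plus`` is the prior probability that the world is in
        the rising state, P(U in U+), counting half the weight of any
        zero-drift component; the rising/falling split within each non-zero
        drift level is chosen (identically across levels) to realize it.
        """
        drifts = [float(d) for d in drifts]
        if any(d < 0.0 or d > 0.5 for d in drifts):
            raise ValueError("drifts must lie in [0, 0.5]")
        if weights is None:
            weights = [1.0] * len(drifts)
        w = np.asarray(weights, dtype=float)
        if len(w) != len(drifts) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, one per drift")
        w = w / w.sum()

        w0 = float(sum(wi for d, wi in zip(drifts, w) if d <= HALF_ATOL))
        if 1.0 - w0 <= HALF_ATOL:
            if abs(p_plus - 0.5) > 1e-12:
                raise ValueError("p_plus must be 1/2 when only zero-drift components exist")
            q = 0.5
        else:
            q = (p_plus - 0.5 * w0) / (1.0 - w0)
        if q < -1e-12 or q > 1.0 + 1e-12:
            raise ValueError(f"p_plus={p_plus} not realizable with this zero-drift weight")
        q = min(max(q, 0.0), 1.0)

        if easy_drifts is None:
            easy_set = {max(drifts)} if len(set(drifts)) > 1 else set(drifts)
        else:
            easy_set = {float(d) for d in easy_drifts}

        acc: dict[float, list] = {}
        for d, wi in zip(drifts, w):
            is_easy = any(abs(d - e) <= HALF_ATOL for e in easy_set)
            if d <= HALF_ATOL:
                pieces = [(0.5, wi)]
            else:
                pieces = [(0.5 + d, wi * q), (0.5 - d, wi * (1.0 - q))]
            for u, wu in pieces:
                if u in acc:
                    acc[u][0] += wu
                    acc[u][1] = acc[u][1] or is_easy
                else:
                    acc[u] = [wu, is_easy]
        us = sorted(acc)
        prior = np.array([acc[u][0] for u in us], dtype=float)
        prior = prior / prior.sum()
        return cls(tuple(us), tuple(prior), tuple(acc[u][1] for u in us))

    @classmethod
    def two_difficulty(
        cls,
        easy_drift: float,
        difficult_drift: float,
        p_easy: float = 0.5,
        p_plus: float = 0.5,
    ) -> "DriftMixture":
        """The canonical two-level task: easy drift ``eps_e`` and difficult
        drift ``eps_d`` (possibly zero) mixed with P(easy) = ``p_easy``."""
        if not 0.0 <= p_easy <= 1.0:
            raise ValueError("p_easy must lie in [0, 1]")
        return cls.from_drifts(
            [easy_drift, difficult_drift],
            [p_easy, 1.0 - p_easy],
            p_plus=p_plus,
            easy_drifts=[easy_drift],
        )

    @classmethod
    def single(cls, drift: float, p_plus: float = 0.5) -> "DriftMixture":
        """A single-difficulty task with drift ``eps``."""
        return cls.from_drifts([drift], p_plus=p_plus)

    # -- derived views -----------------------------------------------------

    @property
    def support_array(self) -> np.ndarray:
        return np.asarray(self.support, dtype=float)

    @property
    def prior_array(self) -> np.ndarray:
        return np.asarray(self.prior, dtype=float)

    @property
    def easy_array(self) -> np.ndarray:
        return np.asarray(self.easy, dtype=bool)

    @property
    def plus_mass(self) -> np.ndarray:
        """Per-u membership weight in the rising class U+ (1/2 counts half)."""
        u = self.support_array
        m = np.where(u > 0.5, 1.0, 0.0)
        m[np.abs(u - 0.5) <= HALF_ATOL] = 0.5
        return m

    @property
    def drifts(self) -> np.ndarray:
        return np.abs(self.support_array - 0.5)

    @property
    def p_plus(self) -> float:
        """Prior probability of the rising world state, P(U in U+)."""
        return float(self.prior_array @ self.plus_mass)

    @property
    def p_easy(self) -> float:
        return float(self.prior_array[self.easy_array].sum())

    @property
    def has_zero_drift(self) -> bool:
        return bool(np.any(np.abs(self.support_array - 0.5) <= HALF_ATOL))

    @property
    def is_single_difficulty(self) -> bool:
        d = np.round(self.drifts, 12)
        return len(set(d.tolist())) == 1

    @property
    def is_symmetric(self) -> bool:
        """True when the prior is invariant under u <-> 1 - u."""
        pairs = {(round(u, 12), round(w, 12)) for u, w in zip(self.support, self.prior)}
        mirror = {(round(1.0 - u, 12), round(w, 12)) for u, w in zip(self.support, self.prior)}
        return pairs == mirror

    def symmetrized(self) -> "DriftMixture":
        """Same drift-class weights, but rising/falling split equally.

        This is the class-symmetric mixture used for difficulty inference in
        :func:`posterior_maps`, making the easy/difficult posterior
        independent of the world-state prior.
        """
        acc: dict[float, list] = {}
        for u, w, e in zip(self.support, self.prior, self.easy):
            d = round(abs(u - 0.5), 12)
            if d in acc:
                acc[d][0] += w
                acc[d][1] = acc[d][1] or e
            else:
                acc[d] = [w, e]
        support: list[float] = []
        prior: list[float] = []
        easy: list[bool] = []
        for d in sorted(acc):
            w, e = acc[d]
            if d <= HALF_ATOL:
                support.append(0.5)
                prior.append(w)
                easy.append(e)
            else:
                support.extend([0.5 - d, 0.5 + d])
                prior.extend([w / 2.0, w / 2.0])
                easy.extend([e, e])
        order = np.argsort(support)
        return DriftMixture(
            tuple(np.asarray(support)[order]),
            tuple(np.asarray(prior)[order]),
            tuple(np.asarray(easy)[order]),
        )


@dataclass(frozen=True)
class RewardConfig:
    """Rewards and delays (delays in sample-time units).

    ``R_C``/``R_I`` are the rewards for correct/incorrect choices; ``D_C`` /
    ``D_I`` the inter-trial delays that follow them.  ``D_p`` is the optional
    extra error penalty time, in which case ``D_I = D_C + D_p``.  The *pass*
    (opt-out) action carries no reward and its own, typically shorter, delay.
    """

    R_C: float = 1.0
    R_I: float = 0.0
    D_C: float = 150.0
    D_I: float | None = None
    D_p: float | None = None
    pass_delay: float | None = None

    def __post_init__(self) -> None:
        if self.D_C < 0:
            raise ValueError("D_C must be non-negative")
        if self.D_I is None:
            object.__setattr__(self, "D_I", self.D_C + (self.D_p or 0.0))
        if self.D_I < 0:
            raise ValueError("D_I must be non-negative")
        if self.D_p is not None and abs(self.D_I - (self.D_C + self.D_p)) > 1e-9:
            raise ValueError("inconsistent delays: D_I must equal D_C + D_p")
        if self.pass_delay is not None and self.pass_delay < 0:
            raise ValueError("pass_delay must be non-negative")

    @property
    def pass_reward(self) -> float:
        return 0.0


@dataclass(frozen=True)
class TaskModel:
    """Bundle of mixture, rewards, horizon, and available actions."""

    mixture: DriftMixture
    rewards: RewardConfig = field(default_factory=RewardConfig)
    t_max: int = 70
    actions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.t_max < 1:
            raise ValueError("t_max must be at least 1")
        if len(self.actions) == 0:
            acts = ("wait", "go")
            if self.rewards.pass_delay is not None:
                acts = acts + ("pass",)
            object.__setattr__(self, "actions", acts)
        unknown = set(self.actions) - {"wait", "go", "pass"}
        if unknown:
            raise ValueError(f"unknown actions: {sorted(unknown)}")
        if "pass" in self.actions and self.rewards.pass_delay is None:
            raise ValueError("pass action requires rewards.pass_delay")

    @property
    def allow_pass(self) -> bool:
        return "pass" in self.actions


@dataclass(frozen=True)
class TransitionProbs:
    """One-step transition probabilities from a state.

    ``p_up``/``p_down`` apply under *wait* (the posterior-predictive sample
    probabilities); ``p_correct`` is the probability of landing in the
    correct outcome under *go*, and ``chosen_alternative`` ('buy' or 'sell')
    is the alternative the optimal decision-maker selects there.
    """

    p_up: float
    p_down: float
    p_correct: float
    chosen_alternative: str


# ---------------------------------------------------------------------------
# lattice bookkeeping


def n_states(t_max: int) -> int:
    """Number of lattice states with t <= t_max: (t_max+1)(t_max+2)/2."""
    return (t_max + 1) * (t_max + 2) // 2


def state_index(t: int, x: int) -> int:
    """Position of (t, x) in the canonical state order (by t, then x)."""
    return t * (t + 1) // 2 + (t + x) // 2


def enumerate_states(t_max: int) -> list[EvidenceState]:
    """All lattice states up to the horizon, in canonical (linear-system) order."""
    if t_max < 1:
        raise ValueError("t_max must be at least 1")
    return [
        EvidenceState(t, x) for t in range(t_max + 1) for x in range(-t, t + 1, 2)
    ]


def lattice_arrays(t_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectors of t and x for every lattice state, in canonical order."""
    ts = np.concatenate([np.full(t + 1, t, dtype=np.int64) for t in range(t_max + 1)])
    xs = np.concatenate([np.arange(-t, t + 1, 2, dtype=np.int64) for t in range(t_max + 1)])
    return ts, xs


# ---------------------------------------------------------------------------
# posteriors and transition probabilities


def _log_posterior_weights(
    t: np.ndarray, x: np.ndarray, mixture: DriftMixture
) -> np.ndarray:
    """Posterior P(U = u | X_t = x) for each state row; shape (N, K).

    Computed in log space; states where every support member has zero
    likelihood (unreachable under the mixture) fall back to the prior.
    """
    u = mixture.support_array
    w = mixture.prior_array
    k_up = ((t + x) // 2).astype(float)[:, None]
    k_dn = ((t - x) // 2).astype(float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_u = np.log(u)[None, :]
        log_1mu = np.log1p(-u)[None, :]
        term_up = np.where(k_up == 0, 0.0, k_up * log_u)
        term_dn = np.where(k_dn == 0, 0.0, k_dn * log_1mu)
        log_prior = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)[None, :]
    lp = term_up + term_dn + log_prior
    norm = logsumexp(lp, axis=1)
    degenerate = ~np.isfinite(norm)
    post = np.exp(lp - np.where(degenerate, 0.0, norm)[:, None])
    if np.any(degenerate):
        post[degenerate] = w
    return post


def drift_posterior(state: EvidenceState, mixture: DriftMixture) -> np.ndarray:
    """P(U = u | X_t = x), one probability per support element.

    At the origin this is the prior itself; e.g. at (1, 1) with support
    {0.3, 0.7} and equal priors it equals (0.3, 0.7).
    """
    t = np.array([state.t])
    x = np.array([state.x])
    return _log_posterior_weights(t, x, mixture)[0]


def _probs_from_posterior(
    post: np.ndarray, mixture: DriftMixture
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p_up, p_plus, p_correct) for posterior rows."""
    p_up = post @ mixture.support_array
    p_plus = post @ mixture.plus_mass
    p_correct = np.maximum(p_plus, 1.0 - p_plus)
    return p_up, p_plus, p_correct


def _transition(state: EvidenceState, mixture: DriftMixture) -> TransitionProbs:
    post = drift_posterior(state, mixture)[None, :]
    p_up, p_plus, p_correct = _probs_from_posterior(post, mixture)
    # deterministic tie-break: buy when the posterior odds are exactly even
    chosen = "buy" if p_plus[0] >= 0.5 - 1e-12 else "sell"
    return TransitionProbs(
        p_up=float(p_up[0]),
        p_down=float(1.0 - p_up[0]),
        p_correct=float(p_correct[0]),
        chosen_alternative=chosen,
    )


def wait_transition(state: EvidenceState, mixture: DriftMixture) -> TransitionProbs:
    """Transition probabilities under *wait*: the next sample goes up with
    the posterior-predictive probability sum_u u P(u | t, x)."""
    return _transition(state, mixture)


def go_transition(state: EvidenceState, mixture: DriftMixture) -> TransitionProbs:
    """Transition probabilities under *go*: the decision-maker chooses the
    more probable world state; P(correct) = max{P(U+ | t,x), P(U- | t,x)},
    splitting any mass on u = 1/2 half-and-half between the two classes."""
    return _transition(state, mixture)


@dataclass(frozen=True)
class TransitionTables:
    """Per-state transition quantities for the whole lattice (canonical order)."""

    t_max: int
    t: np.ndarray
    x: np.ndarray
    p_up: np.ndarray
    p_plus: np.ndarray
    p_correct: np.ndarray
    buy: np.ndarray  # chosen alternative is buy (ties -> buy)
    p_easy: np.ndarray

    def index(self, t: int, x: int) -> int:
        return state_index(t, x)


def transition_tables(model: TaskModel) -> TransitionTables:
    """Precompute posteriors and transition probabilities on the full lattice."""
    t, x = lattice_arrays(model.t_max)
    post = _log_posterior_weights(t, x, model.mixture)
    p_up, p_plus, p_correct = _probs_from_posterior(post, model.mixture)
    buy = p_plus >= 0.5 - 1e-12
    sym = model.mixture.symmetrized()
    post_sym = _log_posterior_weights(t, x, sym)
    p_easy = post_sym @ sym.easy_array.astype(float)
    return TransitionTables(
        t_max=model.t_max,
        t=t,
        x=x,
        p_up=p_up,
        p_plus=p_plus,
        p_correct=p_correct,
        buy=buy,
        p_easy=p_easy,
    )


def posterior_maps(model: TaskModel) -> pd.DataFrame:
    """Full-lattice posterior grids as a tidy frame.

    Columns: ``t``, ``x``, ``p_easy`` (posterior that the trial is easy,
    computed under class-symmetric world weights so it does not depend on the
    world-state prior) and ``p_plus`` (posterior that the world is rising).
    """
    tab = transition_tables(model)
    return pd.DataFrame(
        {"t": tab.t, "x": tab.x, "p_easy": tab.p_easy, "p_plus": tab.p_plus}
    )


def posterior_maps_long(model: TaskModel) -> pd.DataFrame:
    """Long-format (t, x, quantity, value) version of :func:`posterior_maps`."""
    wide = posterior_maps(model)
    return wide.melt(id_vars=["t", "x"], var_name="quantity", value_name="value")
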