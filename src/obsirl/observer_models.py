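"""Candidate observer models for learning from another agent's choices.

Four strategies compete to explain an observer who watches an agent play
three slot machines but never sees any outcomes:

``inverse_rl``
    Approximate inverse reinforcement learning.  The observer tracks a 3x3
    matrix of posterior-mean outcome probabilities (one row per machine, one
    column per outcome in agent preference rank).  When the agent picks one
    of two offered machines, the chosen machine's row is multiplied
    elementwise by updating constants ``eps = (eps1, eps2, eps3)`` and
    renormalized; the unchosen machine's row is multiplied by the *reversed*
    vector ``(eps3, eps2, eps1)``; the unoffered machine is untouched.  With
    ``eps`` decreasing, observed choices shift belief mass toward the agent's
    preferred outcomes for chosen machines and away for unchosen ones.  On
    self-choice trials machine values are expectations of the observer's own
    preference values under the learned rows, and choice is pairwise softmax.

``imitation``
    Imitation RL.  Action values (initialized at 0.5) follow a prediction
    error toward 1 for the machine the agent chose.  On self trials values
    are passed through an inversion parameter ``theta``:
    ``V_self = (1 - theta) * V_obs + theta * (1 - V_obs)``, letting a pure
    imitator (theta = 0) flip its policy when the agent is judged dissimilar
    (theta = 1).

``cf_imitation``
    Imitation RL with counterfactual updating of the unchosen-but-offered
    machine toward 0 with its own learning rate.

``rank_learner``
    A preference-ranking learner: a Bayesian belief over the 6 strict
    orderings of the machines, updated from each observed choice through the
    shared pairwise softmax with sharpness ``kappa`` and read out on self
    trials with a condition-dependent orientation flip.

The inverse RL model also emits the trial-wise signals used as parametric
regressors downstream: the agent-referential expected values of the offered
machines (agent preference values times the inferred outcome probabilities)
and the KL divergence between posterior and prior outcome beliefs of the
chosen machine at the moment the choice is revealed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .agent_sim import softmax_pair_prob
from .task_core import (
    DEFAULT_PREF_VALUES,
    Condition,
    PreferenceProfile,
    SessionLog,
    SlotMachineSet,
    TrialRecord,
    condition_permutation,
    observer_values_agent_space,
)

__all__ = [
    "InverseRLParams",
    "ImitationParams",
    "RankLearnerParams",
    "init_beliefs",
    "irl_update",
    "irl_expected_values",
    "irl_kl_signal",
    "imitation_update",
    "imitation_invert",
    "rank_belief_update",
    "rank_belief_policy",
    "SessionContext",
    "make_context",
    "make_observer",
    "observer_simulate",
    "MODEL_IDS",
    "ORDERINGS",
]

_SIMPLEX_ATOL = 1e-10

MODEL_IDS = ("inverse_rl", "imitation", "cf_imitation", "rank_learner")

#: The 6 strict orderings of the 3 machine indices, best first.
ORDERINGS: tuple[tuple[int, int, int], ...] = tuple(itertools.permutations(range(3)))

#: Ordering score of machine m under ordering pi: 4 - rank (rank counted from 1).
_ORDER_SCORES = np.array(
    [[3 - pi.index(m) for m in range(3)] for pi in ORDERINGS], dtype=float
)


class ObserverParamError(ValueError):
    """Raised for observer-model parameters outside their stated bounds."""


@dataclass(frozen=True)
class InverseRLParams:
    """Parameters of the approximate inverse RL observer.

    eps: multiplicative updating constants, each in the open interval (0, 1).
    beta: self-choice exploitation intensity, fit box [2, 22].
    decay: optional forgetting window (only the last ``decay`` observations
        shape beliefs); integer in [1, 100], disabled by default.
    """

    eps: tuple[float, float, float]
    beta: float
    decay: int | None = None

    def __post_init__(self) -> None:
        if len(self.eps) != 3 or not all(0.0 < e < 1.0 for e in self.eps):
            raise ObserverParamError("each eps must lie strictly in (0, 1)")
        if not 2.0 <= self.beta <= 22.0:
            raise ObserverParamError("beta must lie in [2, 22]")
        if self.decay is not None and not (1 <= int(self.decay) <= 100):
            raise ObserverParamError("decay window must lie in [1, 100]")


@dataclass(frozen=True)
class ImitationParams:
    """Parameters of the imitation RL observer (and its counterfactual variant)."""

    eta: float
    theta: float
    beta: float
    eta_unchosen: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ObserverParamError("eta must lie in [0, 1]")
        if not 0.0 <= self.theta <= 1.0:
            raise ObserverParamError("theta must lie in [0, 1]")
        if not 2.0 <= self.beta <= 22.0:
            raise ObserverParamError("beta must lie in [2, 22]")
        if self.eta_unchosen is not None and not 0.0 <= self.eta_unchosen <= 1.0:
            raise ObserverParamError("eta_unchosen must lie in [0, 1]")


@dataclass(frozen=True)
class RankLearnerParams:
    """Parameters of the preference-ranking learner."""

    kappa: float
    beta: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ObserverParamError("kappa must be positive")
        if not 2.0 <= self.beta <= 22.0:
            raise ObserverParamError("beta must lie in [2, 22]")


# ---------------------------------------------------------------------------
# inverse RL primitives


def init_beliefs() -> np.ndarray:
    """Uniform prior outcome beliefs: each machine row at (1/3, 1/3, 1/3)."""
    return np.full((3, 3), 1.0 / 3.0)


def _check_row(row: np.ndarray) -> None:
    if abs(float(row.sum()) - 1.0) > _SIMPLEX_ATOL or np.any(row < 0):
        raise ObserverParamError("belief row must lie on the probability simplex")


def irl_update(
    beliefs: np.ndarray,
    chosen: int,
    unchosen: int,
    params: InverseRLParams,
) -> np.ndarray:
    """One observed choice updates the posterior-mean outcome beliefs.

    Chosen row: elementwise multiply by ``eps`` then renormalize; unchosen
    row: multiply by reversed ``eps`` then renormalize (renormalization keeps
    the rows valid probability vectors); the unoffered machine's row is not
    updated.
    """
    if chosen == unchosen:
        raise ObserverParamError("chosen and unchosen machines must differ")
    eps = np.asarray(params.eps, dtype=float)
    new = np.array(beliefs, dtype=float, copy=True)
    new[chosen] = new[chosen] * eps
    new[chosen] /= new[chosen].sum()
    new[unchosen] = new[unchosen] * eps[::-1]
    new[unchosen] /= new[unchosen].sum()
    return new


def irl_expected_values(beliefs: np.ndarray, values: Sequence[float]) -> np.ndarray:
    """Expected machine values under a preference-value vector:
    ``V(m) = sum_i beliefs[m, i] * values[i]``."""
    vals = np.asarray(values, dtype=float)
    if vals.shape != (3,):
        raise ObserverParamError("values must have length 3")
    return np.asarray(beliefs, dtype=float) @ vals


def irl_kl_signal(prior_row: np.ndarray, posterior_row: np.ndarray) -> float:
    """Belief-update signal: KL(posterior || prior) in nats for one machine row."""
    p = np.asarray(posterior_row, dtype=float)
    q = np.asarray(prior_row, dtype=float)
    _check_row(p)
    _check_row(q)
    if np.any((q == 0) & (p > 0)):
        raise ObserverParamError("KL undefined: posterior mass on a zero-prior outcome")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


# ---------------------------------------------------------------------------
# imitation primitives


def imitation_update(
    values: np.ndarray,
    chosen: int,
    params: ImitationParams,
    counterfactual: bool = False,
    unchosen: int | None = None,
) -> np.ndarray:
    """Prediction-error update toward 1 for the chosen machine; with the
    counterfactual flag, the unchosen-but-offered machine decays toward 0."""
    new = np.array(values, dtype=float, copy=True)
    new[chosen] = new[chosen] + params.eta * (1.0 - new[chosen])
    if counterfactual:
        if params.eta_unchosen is None:
            raise ObserverParamError("counterfactual update requires eta_unchosen")
        if unchosen is None:
            raise ObserverParamError("counterfactual update requires the unchosen machine")
        new[unchosen] = new[unchosen] + params.eta_unchosen * (0.0 - new[unchosen])
    return new


def imitation_invert(v_obs: float, theta: float) -> float:
    """Self-trial value inversion: ``(1 - theta) * v + theta * (1 - v)``."""
    if not 0.0 <= v_obs <= 1.0:
        raise ObserverParamError("v_obs must lie in [0, 1]")
    if not 0.0 <= theta <= 1.0:
        raise ObserverParamError("theta must lie in [0, 1]")
    return (1.0 - theta) * v_obs + theta * (1.0 - v_obs)


# ---------------------------------------------------------------------------
# preference-ranking learner primitives


def rank_belief_update(
    belief: np.ndarray, chosen: int, unchosen: int, kappa: float
) -> np.ndarray:
    """Bayesian update of the belief over machine orderings from one observed
    choice, with the pairwise softmax at sharpness ``kappa`` as likelihood."""
    like = np.array(
        [
            softmax_pair_prob(_ORDER_SCORES[k, chosen], _ORDER_SCORES[k, unchosen], kappa)
            for k in range(len(ORDERINGS))
        ]
    )
    post = np.asarray(belief, dtype=float) * like
    return post / post.sum()


def rank_belief_policy(
    belief: np.ndarray, pair: tuple[int, int], beta: float, flip: int = 1
) -> float:
    """Probability of choosing the first pair member: softmax over
    belief-expected ordering scores, orientation set by ``flip``."""
    scores = flip * (np.asarray(belief, dtype=float) @ _ORDER_SCORES)
    return softmax_pair_prob(scores[pair[0]], scores[pair[1]], beta)


# ---------------------------------------------------------------------------
# observer state machines (replay / generation)


@dataclass(frozen=True)
class SessionContext:
    """Everything condition-dependent an observer model needs.

    ``agent_values`` (va) and ``observer_values`` (vs) are both expressed in
    agent-rank outcome space; vs is the observer's own preference values
    re-indexed through the food-identity correspondence of the condition.
    """

    condition: Condition
    agent_values: np.ndarray
    observer_values: np.ndarray
    machines: SlotMachineSet = field(default_factory=SlotMachineSet)


def make_context(
    condition: Condition,
    machines: SlotMachineSet | None = None,
    agent_values: Sequence[float] = DEFAULT_PREF_VALUES,
    observer_values: Sequence[float] = DEFAULT_PREF_VALUES,
) -> SessionContext:
    perm = condition_permutation(condition)
    return SessionContext(
        condition=condition,
        agent_values=np.asarray(agent_values, dtype=float),
        observer_values=observer_values_agent_space(observer_values, perm),
        machines=machines if machines is not None else SlotMachineSet(),
    )


class _Observer:
    """Interface shared by the four observer state machines."""

    def observe(self, chosen: int, unchosen: int) -> float:
        """Consume one observed agent choice; return the KL update signal
        (NaN for models without outcome beliefs)."""
        raise NotImplementedError

    def agent_space_values(self) -> np.ndarray:
        """Agent-referential machine values (the regressor at choice display)."""
        raise NotImplementedError

    def self_values(self) -> np.ndarray:
        """Machine values entering the observer's own softmax choice."""
        raise NotImplementedError

    def self_choice_prob(self, pair: tuple[int, int]) -> float:
        v = self.self_values()
        return softmax_pair_prob(v[pair[0]], v[pair[1]], self.beta)  # type: ignore[attr-defined]


class InverseRLObserver(_Observer):
    def __init__(self, params: InverseRLParams, ctx: SessionContext) -> None:
        self.params = params
        self.beta = params.beta
        self.ctx = ctx
        self.beliefs = init_beliefs()
        self._history: list[tuple[int, int]] = []

    def _recompute_window(self) -> np.ndarray:
        beliefs = init_beliefs()
        for c, u in self._history[-int(self.params.decay) :]:  # type: ignore[arg-type]
            beliefs = irl_update(beliefs, c, u, self.params)
        return beliefs

    def observe(self, chosen: int, unchosen: int) -> float:
        prior_row = self.beliefs[chosen].copy()
        self._history.append((chosen, unchosen))
        if self.params.decay is None:
            self.beliefs = irl_update(self.beliefs, chosen, unchosen, self.params)
        else:
            self.beliefs = self._recompute_window()
        return irl_kl_signal(prior_row, self.beliefs[chosen])

    def agent_space_values(self) -> np.ndarray:
        return irl_expected_values(self.beliefs, self.ctx.agent_values)

    def self_values(self) -> np.ndarray:
        return irl_expected_values(self.beliefs, self.ctx.observer_values)


class ImitationObserver(_Observer):
    def __init__(
        self, params: ImitationParams, ctx: SessionContext, counterfactual: bool = False
    ) -> None:
        if counterfactual and params.eta_unchosen is None:
            raise ObserverParamError("cf_imitation requires eta_unchosen")
        self.params = params
        self.beta = params.beta
        self.counterfactual = counterfactual
        self.values = np.full(3, 0.5)

    def observe(self, chosen: int, unchosen: int) -> float:
        self.values = imitation_update(
            self.values, chosen, self.params, self.counterfactual, unchosen
        )
        return float("nan")

    def agent_space_values(self) -> np.ndarray:
        return self.values.copy()

    def self_values(self) -> np.ndarray:
        return np.array([imitation_invert(v, self.params.theta) for v in self.values])


class RankLearnerObserver(_Observer):
    def __init__(self, params: RankLearnerParams, ctx: SessionContext) -> None:
        self.params = params
        self.beta = params.beta
        self.flip = 1 if ctx.condition == "similar" else -1
        self.belief = np.full(len(ORDERINGS), 1.0 / len(ORDERINGS))

    def observe(self, chosen: int, unchosen: int) -> float:
        self.belief = rank_belief_update(self.belief, chosen, unchosen, self.params.kappa)
        return float("nan")

    def agent_space_values(self) -> np.ndarray:
        return self.belief @ _ORDER_SCORES

    def self_values(self) -> np.ndarray:
        return self.flip * (self.belief @ _ORDER_SCORES)


def make_observer(model_id: str, params, ctx: SessionContext) -> _Observer:
    """Instantiate the observer state machine for a model id."""
    if model_id == "inverse_rl":
        return InverseRLObserver(params, ctx)
    if model_id == "imitation":
        return ImitationObserver(params, ctx, counterfactual=False)
    if model_id == "cf_imitation":
        return ImitationObserver(params, ctx, counterfactual=True)
    if model_id == "rank_learner":
        return RankLearnerObserver(params, ctx)
    raise ObserverParamError(f"unknown model id {model_id!r}")


def observer_simulate(
    model_id: str,
    params,
    agent_log: SessionLog,
    ctx: SessionContext,
    rng: np.random.Generator,
) -> tuple[SessionLog, pd.DataFrame]:
    """Generate observer behavior for a session whose agent trials are filled.

    Replays the agent trials in order to drive the model's internal state,
    samples the observer's own choices from the model policy on self trials,
    and collects per-trial signals: agent-referential values of the offered
    machines and the KL update on agent trials; self-space values of chosen
    and unchosen machines on self trials.
    """
    machines = ctx.machines
    observer = make_observer(model_id, params, ctx)
    records: list[TrialRecord] = []
    rows: list[dict] = []
    for rec in agent_log.records:
        i, j = machines.index(rec.pair[0]), machines.index(rec.pair[1])
        if rec.kind == "agent":
            if rec.chosen is None:
                raise ObserverParamError("agent trial without a recorded choice")
            c = machines.index(rec.chosen)
            u = j if c == i else i
            va = observer.agent_space_values()
            kl = observer.observe(c, u)
            records.append(rec)
            rows.append(
                {
                    "trial": rec.index,
                    "kind": "agent",
                    "condition": ctx.condition,
                    "value_agent_chosen": va[c],
                    "value_agent_unchosen": va[u],
                    "kl_update": kl,
                    "value_self_chosen": np.nan,
                    "value_self_unchosen": np.nan,
                }
            )
        else:
            p_first = observer.self_choice_prob((i, j))
            pick_first = rng.random() < p_first
            chosen_id = rec.pair[0] if pick_first else rec.pair[1]
            c, u = (i, j) if pick_first else (j, i)
            vs = observer.self_values()
            records.append(
                TrialRecord(
                    index=rec.index,
                    kind="self",
                    pair=rec.pair,
                    chooser="self",
                    chosen=chosen_id,
                    outcome_rank=None,
                )
            )
            rows.append(
                {
                    "trial": rec.index,
                    "kind": "self",
                    "condition": ctx.condition,
                    "value_agent_chosen": np.nan,
                    "value_agent_unchosen": np.nan,
                    "kl_update": np.nan,
                    "value_self_chosen": vs[c],
                    "value_self_unchosen": vs[u],
                }
            )
    log = SessionLog(condition=ctx.condition, schedule=agent_log.schedule, records=records)
    return log, pd.DataFrame(rows)
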