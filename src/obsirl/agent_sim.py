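"""Simulated agent: a softmax prediction-error learner on scalar-coded outcomes.

The observed agent is artificial.  It starts with a flat value of 1/3 on each
machine, makes pairwise softmax choices, receives the (hidden-to-the-observer)
food outcome, and updates the chosen machine's value with a weighted
prediction error on the scalar outcome code (1..3, increasing in the agent's
own preference).  The 1/3 initialization sits below the 1..3 outcome range;
that mismatch is part of the generating procedure and is kept as is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task_core import (
    SessionLog,
    SlotMachineSet,
    TrialRecord,
    TrialSchedule,
    sample_outcome,
)

__all__ = [
    "AgentParams",
    "AgentState",
    "softmax_pair_prob",
    "outcome_code",
    "agent_choose",
    "agent_update",
    "simulate_agent_session",
]


def softmax_pair_prob(v_chosen: float, v_unchosen: float, beta: float) -> float:
    """Pairwise softmax (logistic) choice probability.

    ``P = 1 / (1 + exp(-beta * (v_chosen - v_unchosen)))`` — the common choice
    rule for the agent and every observer model.
    """
    if beta <= 0:
        raise ValueError("beta (exploitation intensity) must be positive")
    # logistic of the value difference; clip the exponent for overflow safety
    x = np.clip(beta * (float(v_chosen) - float(v_unchosen)), -700, 700)
    return float(1.0 / (1.0 + np.exp(-x)))


def outcome_code(outcome_rank: int) -> float:
    """Scalar code of an outcome: 1..3 increasing in agent preference.

    Ranks count from 1 = most preferred, so code = 4 - rank.
    """
    if outcome_rank not in (1, 2, 3):
        raise ValueError("outcome_rank must be 1, 2 or 3")
    return float(4 - outcome_rank)


@dataclass(frozen=True)
class AgentParams:
    """Fixed learning rate and exploitation intensity of the simulated agent.

    Defaults give the agent a clear best > mid > worst asymptotic choice
    ordering on the default payout matrix.
    """

    alpha: float = 0.3
    beta: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class AgentState:
    """Machine values of the agent, initialized flat at 1/3 per machine."""

    params: AgentParams = field(default_factory=AgentParams)
    values: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))

    def copy(self) -> "AgentState":
        return AgentState(params=self.params, values=self.values.copy())


def agent_choose(
    state: AgentState,
    pair: tuple[str, str],
    machines: SlotMachineSet,
    rng: np.random.Generator,
) -> str:
    """Sample the agent's softmax choice between the two offered machines."""
    i, j = machines.index(pair[0]), machines.index(pair[1])
    p_first = softmax_pair_prob(state.values[i], state.values[j], state.params.beta)
    return pair[0] if rng.random() < p_first else pair[1]


def agent_update(state: AgentState, chosen: str, outcome_rank: int, machines: SlotMachineSet) -> AgentState:
    """Prediction-error update of the chosen machine's value:
    ``V <- V + alpha * (code - V)``; other machines untouched."""
    code = outcome_code(outcome_rank)
    new = state.copy()
    k = machines.index(chosen)
    new.values[k] = new.values[k] + state.params.alpha * (code - new.values[k])
    return new


def simulate_agent_session(
    machines: SlotMachineSet,
    schedule: TrialSchedule,
    params: AgentParams,
    rng: np.random.Generator,
    condition: str = "similar",
) -> SessionLog:
    """Play the agent through a schedule: on every agent trial it chooses,
    draws a hidden outcome and learns; self trials are left for the observer.

    The agent's behavior does not depend on the condition label — the same
    generating process is used with similar and dissimilar observers.
    """
    state = AgentState(params=params)
    records: list[TrialRecord] = []
    for trial in schedule.trials:
        if trial.kind == "agent":
            chosen = agent_choose(state, trial.pair, machines, rng)
            rank = sample_outcome(chosen, machines, rng)
            state = agent_update(state, chosen, rank, machines)
            records.append(
                TrialRecord(
                    index=trial.index,
                    kind="agent",
                    pair=trial.pair,
                    chooser="agent",
                    chosen=chosen,
                    outcome_rank=rank,
                )
            )
        else:
            records.append(
                TrialRecord(
                    index=trial.index,
                    kind="self",
                    pair=trial.pair,
                    chooser="self",
                    chosen=None,
                    outcome_rank=None,
                )
            )
    return SessionLog(condition=condition, schedule=schedule, records=records)  # type: ignore[arg-type]
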