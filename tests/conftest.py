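import numpy as np
import pytest

from obsirl.agent_sim import AgentParams, simulate_agent_session
from obsirl.task_core import (
    SessionConfig,
    SessionLog,
    SlotMachineSet,
    Trial,
    TrialRecord,
    TrialSchedule,
    build_schedule,
)


@pytest.fixture
def machines() -> SlotMachineSet:
    return SlotMachineSet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def agent_log(machines, rng) -> SessionLog:
    """A full default session (100 agent + 50 self trials) with agent trials
    simulated and self trials still open."""
    schedule = build_schedule(SessionConfig(), rng, machines.machine_ids)
    return simulate_agent_session(machines, schedule, AgentParams(), rng)


def make_log(records, condition="similar") -> SessionLog:
    trials = tuple(Trial(index=r.index, kind=r.kind, pair=r.pair) for r in records)
    return SessionLog(condition=condition, schedule=TrialSchedule(trials), records=records)


@pytest.fixture
def hand_log() -> SessionLog:
    """Six hand-written trials: A beats B twice, B beats C once on agent
    trials; self picks A, A, C."""
    recs = [
        TrialRecord(1, "agent", ("A", "B"), "agent", "A", 1),
        TrialRecord(2, "self", ("A", "C"), "self", "A", None),
        TrialRecord(3, "agent", ("A", "B"), "agent", "A", 2),
        TrialRecord(4, "self", ("A", "B"), "self", "A", None),
        TrialRecord(5, "agent", ("B", "C"), "agent", "B", 3),
        TrialRecord(6, "self", ("B", "C"), "self", "C", None),
    ]
    return make_log(recs)
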