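"""Observational slot-machine task: machines, preferences, schedules, session logs.

The task has three slot machines, each of which pays out one of three food
items on every pull.  Payout probabilities are fixed within a session and
hidden from everyone.  Outcomes are indexed internally by the *agent's*
preference rank (index 0 = the agent's most preferred item); the observed
agent's scalar outcome code used by its learning rule is ``4 - rank`` with
ranks counted from 1, i.e. increasing in preference from 1 to 3.

A session interleaves ``agent`` trials (the observer watches the agent choose
between two offered machines; the outcome is delivered to the agent but is
never shown to the observer) with ``self`` trials (the observer chooses; again
no outcome is shown).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MACHINE_IDS",
    "DEFAULT_TRUE_PROBS",
    "DEFAULT_PREF_VALUES",
    "PreferenceProfile",
    "SlotMachineSet",
    "Trial",
    "TrialSchedule",
    "TrialRecord",
    "SessionLog",
    "SessionConfig",
    "build_schedule",
    "sample_outcome",
    "choice_ratio",
    "alignment_permutation",
    "condition_permutation",
    "observer_values_agent_space",
]

Condition = Literal["similar", "dissimilar"]
Kind = Literal["agent", "self"]

DEFAULT_MACHINE_IDS: tuple[str, str, str] = ("A", "B", "C")

#: Default hidden payout matrix, rows = machines, columns = outcomes ordered
#: by agent preference rank (best, mid, worst).  Gives a clear best/mid/worst
#: machine ordering in both the agent's and a reversed observer's value space.
DEFAULT_TRUE_PROBS = np.array(
    [
        [0.6, 0.3, 0.1],
        [0.3, 0.4, 0.3],
        [0.1, 0.3, 0.6],
    ]
)

DEFAULT_PREF_VALUES: tuple[float, float, float] = (3.0, 2.0, 1.0)

_SIMPLEX_ATOL = 1e-12


class TaskValidationError(ValueError):
    """Raised when task structures violate their invariants."""


@dataclass(frozen=True)
class PreferenceProfile:
    """An actor's preference ranking over the three food outcomes.

    Parameters
    ----------
    actor_id:
        Free-form label ("agent", "observer", ...).
    ranking:
        The three outcome identities from most to least preferred.
    values:
        Numeric preference values by rank (rank 1 first); must be strictly
        decreasing.  Default ``(3, 2, 1)``.
    """

    actor_id: str
    ranking: tuple[str, str, str]
    values: tuple[float, float, float] = DEFAULT_PREF_VALUES

    def __post_init__(self) -> None:
        if len(self.ranking) != 3 or len(set(self.ranking)) != 3:
            raise TaskValidationError("ranking must be a strict permutation of 3 outcomes")
        if len(self.values) != 3:
            raise TaskValidationError("values must have length 3")
        if not (self.values[0] > self.values[1] > self.values[2]):
            raise TaskValidationError("preference values must be strictly decreasing in rank")

    def value_of(self, outcome: str) -> float:
        return self.values[self.ranking.index(outcome)]

    @property
    def values_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def alignment_permutation(agent: PreferenceProfile, observer: PreferenceProfile) -> np.ndarray:
    """Permutation ``p`` with ``p[i]`` = observer's rank index of the outcome
    the agent ranks at index ``i``.  Identity for identical rankings, reversal
    for exactly opposite ones."""
    return np.array([observer.ranking.index(o) for o in agent.ranking])


def condition_permutation(condition: Condition) -> np.ndarray:
    """Outcome-identity correspondence implied by the experimental condition:
    a similar agent shares the observer's ranking, a dissimilar one reverses it."""
    if condition == "similar":
        return np.arange(3)
    if condition == "dissimilar":
        return np.array([2, 1, 0])
    raise TaskValidationError(f"unknown condition: {condition!r}")


def observer_values_agent_space(
    observer_values: Sequence[float], permutation: np.ndarray
) -> np.ndarray:
    """Re-index the observer's own preference values into agent-rank space."""
    vals = np.asarray(observer_values, dtype=float)
    return vals[np.asarray(permutation)]


@dataclass(frozen=True)
class SlotMachineSet:
    """The three machines and their hidden outcome distributions.

    ``true_probs`` is the 3x3 payout matrix (rows = machines, columns =
    outcomes by agent preference rank); every row must lie on the simplex.
    """

    machine_ids: tuple[str, str, str] = DEFAULT_MACHINE_IDS
    true_probs: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_PROBS.copy())

    def __post_init__(self) -> None:
        if len(self.machine_ids) != 3 or len(set(self.machine_ids)) != 3:
            raise TaskValidationError("exactly 3 distinct machine ids required")
        probs = np.asarray(self.true_probs, dtype=float)
        object.__setattr__(self, "true_probs", probs)
        if probs.shape != (3, 3):
            raise TaskValidationError("true_probs must be 3x3")
        if np.any(probs < 0) or np.any(probs > 1):
            raise TaskValidationError("probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=_SIMPLEX_ATOL, rtol=0):
            raise TaskValidationError("each machine's outcome row must sum to 1")

    def index(self, machine: str) -> int:
        try:
            return self.machine_ids.index(machine)
        except ValueError:
            raise TaskValidationError(f"unknown machine {machine!r}") from None

    def row(self, machine: str) -> np.ndarray:
        return self.true_probs[self.index(machine)]

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(itertools.combinations(self.machine_ids, 2))


@dataclass(frozen=True)
class Trial:
    index: int  # 1-based position in the session
    kind: Kind
    pair: tuple[str, str]


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[Trial, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def count(self, kind: Kind) -> int:
        return sum(1 for t in self.trials if t.kind == kind)


@dataclass(frozen=True)
class SessionConfig:
    """Structural parameters of one session (defaults follow the task design:
    150 trials = 100 agent observations + 50 self choices)."""

    n_agent: int = 100
    n_self: int = 50

    def __post_init__(self) -> None:
        if self.n_agent < 1 or self.n_self < 1:
            raise TaskValidationError("n_agent and n_self must both be >= 1")


@dataclass
class TrialRecord:
    index: int
    kind: Kind
    pair: tuple[str, str]
    chooser: Literal["agent", "self"]
    chosen: str | None
    outcome_rank: int | None  # 1..3 in agent preference rank; None on self trials


@dataclass
class SessionLog:
    """Per-trial record of one observer x agent session.

    Outcomes are present only on agent trials and are never visible to the
    observer; they exist in the log because the agent simulator needed them.
    """

    condition: Condition
    schedule: TrialSchedule
    records: list[TrialRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.chosen is not None and rec.chosen not in rec.pair:
                raise TaskValidationError(
                    f"trial {rec.index}: chosen machine {rec.chosen!r} not in pair {rec.pair}"
                )
            if rec.kind == "agent" and rec.chosen is not None and rec.outcome_rank is None:
                raise TaskValidationError(f"trial {rec.index}: agent trial missing outcome")
            if rec.kind == "self" and rec.outcome_rank is not None:
                raise TaskValidationError(f"trial {rec.index}: self trial must not carry outcome")

    def trials_of(self, kind: Kind) -> list[TrialRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [r.index for r in self.records],
                "kind": [r.kind for r in self.records],
                "condition": self.condition,
                "machine_a": [r.pair[0] for r in self.records],
                "machine_b": [r.pair[1] for r in self.records],
                "chooser": [r.chooser for r in self.records],
                "chosen": [r.chosen for r in self.records],
                "outcome_rank": [r.outcome_rank for r in self.records],
            }
        )

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if metadata is not None:
            path.with_suffix(".json").write_text(json.dumps(metadata, indent=2))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SessionLog":
        records = []
        trials = []
        condition = str(frame["condition"].iloc[0])
        for row in frame.itertuples(index=False):
            pair = (str(row.machine_a), str(row.machine_b))
            outcome = None if pd.isna(row.outcome_rank) else int(row.outcome_rank)
            chosen = None if (row.chosen is None or pd.isna(row.chosen)) else str(row.chosen)
            records.append(
                TrialRecord(
                    index=int(row.trial),
                    kind=str(row.kind),  # type: ignore[arg-type]
                    pair=pair,
                    chooser=str(row.chooser),  # type: ignore[arg-type]
                    chosen=chosen,
                    outcome_rank=outcome,
                )
            )
            trials.append(Trial(index=int(row.trial), kind=str(row.kind), pair=pair))  # type: ignore[arg-type]
        return cls(condition=condition, schedule=TrialSchedule(tuple(trials)), records=records)  # type: ignore[arg-type]

    @classmethod
    def from_csv(cls, path: str | Path) -> "SessionLog":
        return cls.from_frame(pd.read_csv(path))


def _balanced_pair_counts(n: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Each pair floor(n/3) or ceil(n/3) times; the remainder pairs are drawn
    without replacement."""
    counts = np.full(n_pairs, n // n_pairs)
    extra = rng.choice(n_pairs, size=n % n_pairs, replace=False)
    counts[extra] += 1
    return counts


def build_schedule(
    config: SessionConfig,
    rng: np.random.Generator,
    machine_ids: Sequence[str] = DEFAULT_MACHINE_IDS,
) -> TrialSchedule:
    """Build a session schedule: pair presentations balanced within each trial
    kind, then a single seeded shuffle of the overall trial order."""
    pairs = list(itertools.combinations(machine_ids, 2))
    entries: list[tuple[Kind, tuple[str, str]]] = []
    for kind, n in (("agent", config.n_agent), ("self", config.n_self)):
        counts = _balanced_pair_counts(n, len(pairs), rng)
        for pair, cnt in zip(pairs, counts):
            entries.extend([(kind, pair)] * int(cnt))
    order = rng.permutation(len(entries))
    trials = tuple(
        Trial(index=i + 1, kind=entries[j][0], pair=entries[j][1])
        for i, j in enumerate(order)
    )
    return TrialSchedule(trials)


def sample_outcome(
    machine: str, machines: SlotMachineSet, rng: np.random.Generator
) -> int:
    """Draw one outcome rank (1..3, agent preference rank) from the machine's
    hidden payout distribution."""
    row = machines.row(machine)
    return int(rng.choice(3, p=row)) + 1


def choice_ratio(log: SessionLog, chooser: Kind) -> np.ndarray:
    """Choice frequency of each machine given its number of presentations, for
    trials of the requested chooser kind.  NaN marks a machine never offered."""
    trials = [r for r in log.trials_of(chooser) if r.chosen is not None]
    if not trials:
        raise TaskValidationError(f"log contains no completed {chooser!r} trials")
    machine_ids = sorted({m for r in log.records for m in r.pair})
    offered = np.zeros(len(machine_ids))
    chosen = np.zeros(len(machine_ids))
    idx = {m: i for i, m in enumerate(machine_ids)}
    for rec in trials:
        for m in rec.pair:
            offered[idx[m]] += 1
        chosen[idx[rec.chosen]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(offered > 0, chosen / np.maximum(offered, 1), np.nan)
    ratios[offered == 0] = np.nan
    return ratios
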