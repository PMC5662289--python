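"""Descriptive behavioral statistics of the observational learning task.

Choice ratios are compared in *referential spaces*: a machine ordering is
"agent-referential" when machines are sorted by their expected value under
the agent's preferences and the true payout matrix, and "self-referential"
when sorted under the observer's own preferences.  The SI (social information
integration) index scores how well an observer's own-choice distribution,
expressed in its own space, matches the agent's distribution in agent space:
1 means perfect transfer of the inferred structure into own preferences, 0
(in the dissimilar condition) means pure mimicry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .task_core import (
    PreferenceProfile,
    SessionLog,
    SlotMachineSet,
    choice_ratio,
)

__all__ = [
    "referential_order",
    "referential_reorder",
    "spearman_agent_observer",
    "fisher_compare",
    "plateau_ratios",
    "si_index",
]


def referential_order(
    machines: SlotMachineSet, values_agent_space: np.ndarray
) -> np.ndarray:
    """Machine indices sorted best-first by true expected value under a
    preference-value vector (agent-rank outcome space).  Ties break by
    machine label."""
    ev = machines.true_probs @ np.asarray(values_agent_space, dtype=float)
    # stable sort on (-EV, label) gives a deterministic tie-break
    order = sorted(range(3), key=lambda m: (-ev[m], machines.machine_ids[m]))
    return np.array(order)


def referential_reorder(
    ratios: np.ndarray, values_agent_space: np.ndarray, machines: SlotMachineSet
) -> np.ndarray:
    """Reorder a per-machine vector into referential space (best first)."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (3,):
        raise ValueError("ratios must have length 3")
    return ratios[referential_order(machines, values_agent_space)]


def spearman_agent_observer(
    sessions: list[SessionLog],
    machines: SlotMachineSet,
    agent_values: np.ndarray,
    observer_values_by_session: list[np.ndarray],
) -> float:
    """Spearman rank correlation between observer self-choice ratios in
    self-referential space and agent choice ratios in agent space, pooled
    over subject x machine pairs."""
    if len(sessions) < 2:
        raise ValueError("need at least 2 subjects")
    obs_pool: list[float] = []
    ag_pool: list[float] = []
    for log, vs in zip(sessions, observer_values_by_session):
        ag = referential_reorder(choice_ratio(log, "agent"), agent_values, machines)
        ob = referential_reorder(choice_ratio(log, "self"), vs, machines)
        ag_pool.extend(ag)
        obs_pool.extend(ob)
    obs_arr, ag_arr = np.asarray(obs_pool), np.asarray(ag_pool)
    if np.nanstd(obs_arr) == 0 or np.nanstd(ag_arr) == 0:
        return float("nan")
    rs = stats.spearmanr(obs_arr, ag_arr, nan_policy="omit").statistic
    return float(rs)


def fisher_compare(rs_a: float, rs_b: float, n_a: int, n_b: int) -> tuple[float, float]:
    """Fisher z comparison of two independent correlations.

    Returns ``(z, p)`` with a one-tailed p for the alternative rs_a > rs_b.
    """
    if abs(rs_a) >= 1 or abs(rs_b) >= 1:
        raise ValueError("|rs| must be < 1 for the Fisher transform")
    if n_a < 4 or n_b < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (np.arctanh(rs_a) - np.arctanh(rs_b)) / np.sqrt(
        1.0 / (n_a - 3) + 1.0 / (n_b - 3)
    )
    return float(z), float(stats.norm.sf(z))


def plateau_ratios(
    log: SessionLog, cutoff: int = 76, chooser: str = "self"
) -> np.ndarray:
    """Choice ratios restricted to trials at or after ``cutoff`` (the late
    window in which the agent's learning has plateaued; default: the second
    half of a 150-trial session)."""
    late = [r for r in log.records if r.index >= cutoff]
    if not any(r.kind == chooser or r.chooser == chooser for r in late):
        raise ValueError("empty late window for the requested chooser")
    sub = SessionLog(condition=log.condition, schedule=log.schedule, records=late)
    return choice_ratio(sub, chooser)  # type: ignore[arg-type]


def si_index(
    agent_log: SessionLog,
    observer_log: SessionLog,
    machines: SlotMachineSet,
    agent_values: np.ndarray,
    observer_values: np.ndarray,
) -> float:
    """Social information integration index in [0, 1].

    Both actors' choice-ratio vectors are normalized to distributions, each
    expressed in its own referential space, and compared with the base-2
    Jensen-Shannon divergence; SI = 1 - JSD.  Identical ordered distributions
    give 1; disjoint support gives 0.
    """
    ag = referential_reorder(choice_ratio(agent_log, "agent"), agent_values, machines)
    ob = referential_reorder(choice_ratio(observer_log, "self"), observer_values, machines)
    for v in (ag, ob):
        if np.nansum(v) <= 0:
            raise ValueError("cannot normalize an all-zero choice-ratio vector")
    ag = np.nan_to_num(ag) / np.nansum(ag)
    ob = np.nan_to_num(ob) / np.nansum(ob)
    jsd = float(jensenshannon(ag, ob, base=2) ** 2)
    return float(1.0 - min(max(jsd, 0.0), 1.0))
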