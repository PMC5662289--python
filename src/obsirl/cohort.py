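"""Synthetic cohorts with the structure of the observational learning study.

Each subject contributes two 150-trial sessions (one with a similar and one
with a dissimilar agent; 100 agent observations + 50 self choices per
session).  Agent behavior is simulated with the softmax prediction-error
learner; observer behavior is generated under a known model with ground-truth
parameters sampled from configurable distributions, stored alongside every
session so that parameter- and model-recovery analyses can be run against
them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agent_sim import AgentParams, simulate_agent_session
from .fitting import MODEL_SPECS
from .metrics import referential_reorder
from .observer_models import (
    ImitationParams,
    InverseRLParams,
    RankLearnerParams,
    SessionContext,
    make_context,
    observer_simulate,
)
from .task_core import (
    Condition,
    SessionConfig,
    SessionLog,
    SlotMachineSet,
    build_schedule,
    choice_ratio,
)

__all__ = [
    "CohortSpec",
    "Subject",
    "Cohort",
    "sample_params",
    "generate_cohort",
    "cohort_summary",
    "write_cohort",
    "read_cohort",
]

CONDITIONS: tuple[Condition, Condition] = ("similar", "dissimilar")


def sample_params(model_id: str, rng: np.random.Generator, monotone_eps: bool = False):
    """Draw ground-truth generating parameters inside the fitting boxes.

    eps components are uniform on (0.05, 0.95) (optionally sorted decreasing
    so that observed choices are informative about the agent's preference
    order), eta/theta uniform on (0, 1), beta uniform on (2, 22), kappa
    log-uniform on (0.1, 5).
    """
    beta = float(rng.uniform(2.0, 22.0))
    if model_id == "inverse_rl":
        eps = rng.uniform(0.05, 0.95, size=3)
        if monotone_eps:
            eps = np.sort(eps)[::-1]
        return InverseRLParams(eps=tuple(float(e) for e in eps), beta=beta)
    if model_id == "imitation":
        return ImitationParams(
            eta=float(rng.uniform(0.0, 1.0)), theta=float(rng.uniform(0.0, 1.0)), beta=beta
        )
    if model_id == "cf_imitation":
        return ImitationParams(
            eta=float(rng.uniform(0.0, 1.0)),
            theta=float(rng.uniform(0.0, 1.0)),
            beta=beta,
            eta_unchosen=float(rng.uniform(0.0, 1.0)),
        )
    if model_id == "rank_learner":
        return RankLearnerParams(
            kappa=float(np.exp(rng.uniform(np.log(0.1), np.log(5.0)))), beta=beta
        )
    raise ValueError(f"unknown model id {model_id!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Study-structured cohort configuration (defaults: 43 subjects, two
    conditions each, inverse-RL generating model for every subject)."""

    n_subjects: int = 43
    session: SessionConfig = field(default_factory=SessionConfig)
    machines: SlotMachineSet = field(default_factory=SlotMachineSet)
    agent_params: AgentParams = field(default_factory=AgentParams)
    generating_models: tuple[str, ...] = ("inverse_rl",)
    monotone_eps: bool = False
    master_seed: int = 0

    def model_for(self, subject: int) -> str:
        return self.generating_models[subject % len(self.generating_models)]


@dataclass
class Subject:
    subject_id: str
    model_id: str
    true_params: object
    sessions: dict[Condition, SessionLog]
    signals: dict[Condition, pd.DataFrame]
    contexts: dict[Condition, SessionContext]


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject]

    def sessions(self, condition: Condition) -> list[SessionLog]:
        return [s.sessions[condition] for s in self.subjects]


def _subject_rng(master_seed: int, subject: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, subject]))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full cohort: for every subject and condition, an agent
    session is generated first and the subject's observer model (with the
    subject's ground-truth parameters) then fills in the self choices."""
    subjects: list[Subject] = []
    for s in range(spec.n_subjects):
        rng = _subject_rng(spec.master_seed, s)
        model_id = spec.model_for(s)
        params = sample_params(model_id, rng, monotone_eps=spec.monotone_eps)
        sessions: dict[Condition, SessionLog] = {}
        signals: dict[Condition, pd.DataFrame] = {}
        contexts: dict[Condition, SessionContext] = {}
        for condition in CONDITIONS:
            schedule = build_schedule(spec.session, rng, spec.machines.machine_ids)
            agent_log = simulate_agent_session(
                spec.machines, schedule, spec.agent_params, rng, condition=condition
            )
            ctx = make_context(condition, machines=spec.machines)
            log, sig = observer_simulate(model_id, params, agent_log, ctx, rng)
            sessions[condition] = log
            signals[condition] = sig
            contexts[condition] = ctx
        subjects.append(
            Subject(
                subject_id=f"sub-{s:03d}",
                model_id=model_id,
                true_params=params,
                sessions=sessions,
                signals=signals,
                contexts=contexts,
            )
        )
    return Cohort(spec=spec, subjects=subjects)


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Mean and SEM choice ratios per machine position (best/mid/worst in the
    relevant referential space) per condition, for agent and observer."""
    if not cohort.subjects:
        raise ValueError("empty cohort")
    machines = cohort.spec.machines
    rows = []
    positions = ("best", "mid", "worst")
    for condition in CONDITIONS:
        ag_mat, ob_mat = [], []
        for sub in cohort.subjects:
            log = sub.sessions[condition]
            ctx = sub.contexts[condition]
            ag_mat.append(
                referential_reorder(choice_ratio(log, "agent"), ctx.agent_values, machines)
            )
            ob_mat.append(
                referential_reorder(choice_ratio(log, "self"), ctx.observer_values, machines)
            )
        for chooser, mat in (("agent", np.array(ag_mat)), ("self", np.array(ob_mat))):
            mean = np.nanmean(mat, axis=0)
            sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(mat.shape[0])
            for pos, m, s in zip(positions, mean, sem):
                rows.append(
                    {
                        "condition": condition,
                        "chooser": chooser,
                        "position": pos,
                        "mean_ratio": float(m),
                        "sem_ratio": float(s),
                    }
                )
    return pd.DataFrame(rows)


def _params_to_dict(params) -> dict:
    if isinstance(params, InverseRLParams):
        return {"model": "inverse_rl", "eps": list(params.eps), "beta": params.beta,
                "decay": params.decay}
    if isinstance(params, ImitationParams):
        return {"model": "imitation", "eta": params.eta, "theta": params.theta,
                "beta": params.beta, "eta_unchosen": params.eta_unchosen}
    if isinstance(params, RankLearnerParams):
        return {"model": "rank_learner", "kappa": params.kappa, "beta": params.beta}
    raise TypeError(f"unknown params type {type(params)!r}")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the cohort to disk: per-subject session CSVs, signal CSVs and a
    ground-truth JSON, plus a cohort manifest YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_subjects": cohort.spec.n_subjects,
        "master_seed": cohort.spec.master_seed,
        "generating_models": list(cohort.spec.generating_models),
        "subjects": [],
    }
    for sub in cohort.subjects:
        sub_dir = out / sub.subject_id
        sub_dir.mkdir(exist_ok=True)
        for condition in CONDITIONS:
            sub.sessions[condition].to_csv(sub_dir / f"session_{condition}.csv")
            sub.signals[condition].to_csv(sub_dir / f"signals_{condition}.csv", index=False)
        truth = {"subject_id": sub.subject_id, "model_id": sub.model_id,
                 "params": _params_to_dict(sub.true_params)}
        (sub_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        manifest["subjects"].append(sub.subject_id)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def read_cohort_sessions(in_dir: str | Path) -> dict[str, dict[str, SessionLog]]:
    """Re-read the per-subject session logs of a written cohort."""
    root = Path(in_dir)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    out: dict[str, dict[str, SessionLog]] = {}
    for sub_id in manifest["subjects"]:
        out[sub_id] = {
            condition: SessionLog.from_csv(root / sub_id / f"session_{condition}.csv")
            for condition in CONDITIONS
        }
    return out


read_cohort = read_cohort_sessions
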