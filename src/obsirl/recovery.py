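"""Generate-and-recover studies: parameter recovery and subject simulation
helpers shared by the confusion-matrix analysis, the test suite and the CLI.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .agent_sim import simulate_agent_session
from .cohort import CohortSpec, sample_params
from .fitting import FitResult, fit_mle
from .observer_models import InverseRLParams, SessionContext, make_context, observer_simulate
from .task_core import Condition, SessionLog, build_schedule

__all__ = ["eps_spread", "simulate_subject_factory", "parameter_recovery"]


def eps_spread(eps) -> float:
    """Scale-free summary of the updating constants: log(eps1 / eps3).

    The multiplicative belief update is invariant to a common rescaling of
    eps, so only ratios are identifiable; the log ratio of the extreme
    components captures how strongly observed choices polarize beliefs.
    """
    return float(np.log(eps[0] / eps[2]))


def simulate_one_subject(
    spec: CohortSpec,
    model_id: str,
    params,
    rng: np.random.Generator,
    condition: Condition = "dissimilar",
) -> tuple[SessionLog, SessionContext]:
    """One agent session plus observer behavior under known parameters."""
    schedule = build_schedule(spec.session, rng, spec.machines.machine_ids)
    agent_log = simulate_agent_session(
        spec.machines, schedule, spec.agent_params, rng, condition=condition
    )
    ctx = make_context(condition, machines=spec.machines)
    log, _ = observer_simulate(model_id, params, agent_log, ctx, rng)
    return log, ctx


def simulate_subject_factory(
    spec: CohortSpec, condition: Condition = "dissimilar", monotone_eps: bool = True
):
    """Build the ``simulate_subject(model_id, rng)`` callable used by
    ``confusion_study``: parameters are drawn fresh per subject."""

    def simulate_subject(model_id: str, rng: np.random.Generator):
        params = sample_params(model_id, rng, monotone_eps=monotone_eps)
        return simulate_one_subject(spec, model_id, params, rng, condition=condition)

    return simulate_subject


def _truth_row(model_id: str, params) -> dict[str, float]:
    if model_id == "inverse_rl":
        return {
            "true_eps_spread": eps_spread(params.eps),
            "true_beta": params.beta,
        }
    row = {"true_eta": params.eta, "true_theta": params.theta, "true_beta": params.beta}
    if getattr(params, "eta_unchosen", None) is not None:
        row["true_eta_unchosen"] = params.eta_unchosen
    return row


def _fit_row(model_id: str, fit: FitResult) -> dict[str, float]:
    p = fit.best_params
    if model_id == "inverse_rl":
        return {
            "fit_eps_spread": eps_spread((p["eps1"], p["eps2"], p["eps3"])),
            "fit_beta": p["beta"],
        }
    row = {"fit_eta": p["eta"], "fit_theta": p["theta"], "fit_beta": p["beta"]}
    if "eta_unchosen" in p:
        row["fit_eta_unchosen"] = p["eta_unchosen"]
    return row


def parameter_recovery(
    model_id: str,
    n_subjects: int,
    spec: CohortSpec,
    rng: np.random.Generator,
    condition: Condition = "dissimilar",
    n_starts: int = 3,
) -> pd.DataFrame:
    """Simulate ``n_subjects`` observers with known parameters, refit the same
    model, and tabulate generating vs recovered parameter values."""
    rows = []
    for s in range(n_subjects):
        params = sample_params(model_id, rng, monotone_eps=False)
        log, ctx = simulate_one_subject(spec, model_id, params, rng, condition=condition)
        fit = fit_mle(model_id, log, ctx, rng, n_starts=n_starts)
        rows.append(
            {"subject": s, "nll": fit.nll, **_truth_row(model_id, params), **_fit_row(model_id, fit)}
        )
    return pd.DataFrame(rows)
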