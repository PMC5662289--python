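"""Model fitting and comparison: constrained ML, BIC, random-effects BMS,
and generate-and-recover confusion matrices.

Each candidate model is fit to a subject's *self* choices only: agent trials
drive the model's internal state but contribute no likelihood terms.  Fitting
is multistart constrained minimization of the negative log-likelihood (3
random interior starts by default).  Model evidence is approximated as
-BIC/2, and group-level comparison uses the random-effects variational
Dirichlet scheme with Monte-Carlo exceedance probabilities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma

from .observer_models import (
    ImitationParams,
    InverseRLParams,
    RankLearnerParams,
    SessionContext,
    make_observer,
)
from .task_core import SessionLog

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "FitResult",
    "BMSResult",
    "ConfusionMatrix",
    "nll_self_choices",
    "fit_mle",
    "bic",
    "rfx_bms",
    "confusion_study",
]

#: Per-trial likelihoods are floored here to keep the NLL finite at extreme
#: parameter values; well inside the beta box this floor is never active.
LIKELIHOOD_FLOOR = 1e-12

_EPS_LO, _EPS_HI = 1e-3, 1.0 - 1e-3


@dataclass(frozen=True)
class ModelSpec:
    """Fitting-side description of one model: free parameters, their box
    constraints, and the bridge from a parameter vector to model params."""

    model_id: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    def to_params(self, x: np.ndarray, decay: int | None = None):
        d = dict(zip(self.param_names, (float(v) for v in x)))
        if self.model_id == "inverse_rl":
            return InverseRLParams(
                eps=(d["eps1"], d["eps2"], d["eps3"]), beta=d["beta"], decay=decay
            )
        if self.model_id == "imitation":
            return ImitationParams(eta=d["eta"], theta=d["theta"], beta=d["beta"])
        if self.model_id == "cf_imitation":
            return ImitationParams(
                eta=d["eta"], theta=d["theta"], beta=d["beta"],
                eta_unchosen=d["eta_unchosen"],
            )
        if self.model_id == "rank_learner":
            return RankLearnerParams(kappa=d["kappa"], beta=d["beta"])
        raise ValueError(f"unknown model id {self.model_id!r}")

    def from_params(self, params) -> np.ndarray:
        if self.model_id == "inverse_rl":
            return np.array([*params.eps, params.beta])
        if self.model_id == "imitation":
            return np.array([params.eta, params.theta, params.beta])
        if self.model_id == "cf_imitation":
            return np.array([params.eta, params.eta_unchosen, params.theta, params.beta])
        if self.model_id == "rank_learner":
            return np.array([params.kappa, params.beta])
        raise ValueError(f"unknown model id {self.model_id!r}")


MODEL_SPECS: dict[str, ModelSpec] = {
    "inverse_rl": ModelSpec(
        "inverse_rl",
        ("eps1", "eps2", "eps3", "beta"),
        ((_EPS_LO, _EPS_HI),) * 3 + ((2.0, 22.0),),
    ),
    "imitation": ModelSpec(
        "imitation", ("eta", "theta", "beta"), ((0.0, 1.0), (0.0, 1.0), (2.0, 22.0))
    ),
    "cf_imitation": ModelSpec(
        "cf_imitation",
        ("eta", "eta_unchosen", "theta", "beta"),
        ((0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (2.0, 22.0)),
    ),
    "rank_learner": ModelSpec(
        "rank_learner", ("kappa", "beta"), ((0.01, 10.0), (2.0, 22.0))
    ),
}


@dataclass
class FitResult:
    model_id: str
    best_params: dict[str, float]
    nll: float
    n_choices: int
    k_params: int
    bic: float
    start_nlls: tuple[float, ...]
    decay: int | None = None
    success: bool = True


@dataclass
class BMSResult:
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    n_samples: int
    seed: int | None = None


@dataclass
class ConfusionMatrix:
    """Generator-by-fitted-model grid of group exceedance probabilities."""

    model_ids: tuple[str, ...]
    ep: np.ndarray  # rows: generating model; columns: fitted model
    n_subjects: int
    meta: dict = field(default_factory=dict)


def nll_self_choices(
    model_id: str, params, session: SessionLog, ctx: SessionContext
) -> float:
    """Negative log-likelihood of the recorded self choices under a model.

    Agent trials are replayed in order to drive the model state; each self
    trial with a recorded choice contributes -ln P(choice).
    """
    machines = ctx.machines
    observer = make_observer(model_id, params, ctx)
    nll = 0.0
    n_self = 0
    for rec in session.records:
        i, j = machines.index(rec.pair[0]), machines.index(rec.pair[1])
        if rec.kind == "agent":
            if rec.chosen is None:
                continue
            c = machines.index(rec.chosen)
            u = j if c == i else i
            observer.observe(c, u)
        else:
            if rec.chosen is None:
                raise ValueError(f"self trial {rec.index} has no recorded choice")
            p_first = observer.self_choice_prob((i, j))
            p = p_first if rec.chosen == rec.pair[0] else 1.0 - p_first
            nll -= float(np.log(max(p, LIKELIHOOD_FLOOR)))
            n_self += 1
    if n_self == 0:
        raise ValueError("session contains no self choices to fit")
    return nll


# ---------------------------------------------------------------------------
# fast replay paths used inside the optimizer loop (plain-float reimplementation
# of the observer state machines; equivalence with nll_self_choices is covered
# by tests)

_ORDER_SCORES_LIST = [
    [3 - pi.index(m) for m in range(3)] for pi in itertools.permutations(range(3))
]


def _compile_session(session: SessionLog, ctx: SessionContext) -> list[tuple[int, int, int]]:
    """Per-trial (is_agent, chosen_idx, unchosen_idx) sequence."""
    machines = ctx.machines
    out = []
    for rec in session.records:
        if rec.chosen is None:
            continue
        i, j = machines.index(rec.pair[0]), machines.index(rec.pair[1])
        c = machines.index(rec.chosen)
        u = j if c == i else i
        out.append((1 if rec.kind == "agent" else 0, c, u))
    return out


def _logistic(x: float) -> float:
    if x < -700.0:
        x = -700.0
    return 1.0 / (1.0 + math.exp(-x))


def _fast_nll_inverse_rl(x, trials, vs) -> float:
    e1, e2, e3, beta = x
    b = [[1 / 3, 1 / 3, 1 / 3] for _ in range(3)]
    v0, v1, v2 = vs
    nll = 0.0
    for is_agent, c, u in trials:
        if is_agent:
            row = b[c]
            a0, a1, a2 = row[0] * e1, row[1] * e2, row[2] * e3
            s = a0 + a1 + a2
            b[c] = [a0 / s, a1 / s, a2 / s]
            row = b[u]
            a0, a1, a2 = row[0] * e3, row[1] * e2, row[2] * e1
            s = a0 + a1 + a2
            b[u] = [a0 / s, a1 / s, a2 / s]
        else:
            rc, ru = b[c], b[u]
            dv = (rc[0] - ru[0]) * v0 + (rc[1] - ru[1]) * v1 + (rc[2] - ru[2]) * v2
            p = _logistic(beta * dv)
            nll -= math.log(p if p > LIKELIHOOD_FLOOR else LIKELIHOOD_FLOOR)
    return nll


def _fast_nll_imitation(x, trials, counterfactual: bool) -> float:
    if counterfactual:
        eta, eta_u, theta, beta = x
    else:
        eta, theta, beta = x
        eta_u = 0.0
    v = [0.5, 0.5, 0.5]
    sign = 1.0 - 2.0 * theta  # v_self difference = (1 - 2 theta) * v_obs difference
    nll = 0.0
    for is_agent, c, u in trials:
        if is_agent:
            v[c] += eta * (1.0 - v[c])
            if counterfactual:
                v[u] += eta_u * (0.0 - v[u])
        else:
            p = _logistic(beta * sign * (v[c] - v[u]))
            nll -= math.log(p if p > LIKELIHOOD_FLOOR else LIKELIHOOD_FLOOR)
    return nll


def _fast_nll_rank(x, trials, flip: int) -> float:
    kappa, beta = x
    bel = [1 / 6] * 6
    S = _ORDER_SCORES_LIST
    nll = 0.0
    for is_agent, c, u in trials:
        if is_agent:
            tot = 0.0
            new = [0.0] * 6
            for k in range(6):
                new[k] = bel[k] * _logistic(kappa * (S[k][c] - S[k][u]))
                tot += new[k]
            bel = [w / tot for w in new]
        else:
            sc = su = 0.0
            for k in range(6):
                sc += bel[k] * S[k][c]
                su += bel[k] * S[k][u]
            p = _logistic(beta * flip * (sc - su))
            nll -= math.log(p if p > LIKELIHOOD_FLOOR else LIKELIHOOD_FLOOR)
    return nll


def _fast_objective(spec: ModelSpec, session: SessionLog, ctx: SessionContext):
    trials = _compile_session(session, ctx)
    if spec.model_id == "inverse_rl":
        vs = tuple(float(v) for v in ctx.observer_values)
        return lambda x: _fast_nll_inverse_rl(x, trials, vs)
    if spec.model_id == "imitation":
        return lambda x: _fast_nll_imitation(x, trials, False)
    if spec.model_id == "cf_imitation":
        return lambda x: _fast_nll_imitation(x, trials, True)
    if spec.model_id == "rank_learner":
        flip = 1 if ctx.condition == "similar" else -1
        return lambda x: _fast_nll_rank(x, trials, flip)
    raise ValueError(f"unknown model id {spec.model_id!r}")


def bic(nll: float, k_params: int, n_choices: int) -> float:
    """Bayesian Information Criterion: ``2 * nll + k * ln(n)``; lower is better."""
    if n_choices < 1:
        raise ValueError("n_choices must be >= 1")
    return 2.0 * float(nll) + k_params * float(np.log(n_choices))


def _fit_once(
    spec: ModelSpec,
    session: SessionLog,
    ctx: SessionContext,
    x0: np.ndarray,
    decay: int | None,
) -> tuple[float, np.ndarray, bool]:
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    if decay is None:
        fast = _fast_objective(spec, session, ctx)
        objective = lambda x: fast(np.clip(x, lo, hi))
    else:
        def objective(x: np.ndarray) -> float:
            params = spec.to_params(np.clip(x, lo, hi), decay)
            return nll_self_choices(spec.model_id, params, session, ctx)

    res = minimize(objective, x0, method="L-BFGS-B", bounds=spec.bounds)
    return float(res.fun), np.asarray(res.x), bool(res.success)


def fit_mle(
    model_id: str,
    session: SessionLog,
    ctx: SessionContext,
    rng: np.random.Generator,
    n_starts: int = 3,
    decay_candidates: tuple[int, ...] | None = None,
) -> FitResult:
    """Best-of-``n_starts`` constrained ML fit of one model to one session.

    Starting points are drawn uniformly inside the constraint box.  When
    ``decay_candidates`` is given (inverse RL forgetting variant), the
    continuous fit is repeated at each candidate integer window and the best
    total fit is kept.
    """
    spec = MODEL_SPECS[model_id]
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    decays: tuple[int | None, ...] = (None,) if decay_candidates is None else tuple(decay_candidates)

    best: tuple[float, np.ndarray, int | None] | None = None
    start_nlls: list[float] = []
    any_success = False
    starts = [lo + rng.random(len(lo)) * (hi - lo) for _ in range(n_starts)]
    for d_idx, decay in enumerate(decays):
        for x0 in starts:
            fun, x, ok = _fit_once(spec, session, ctx, x0, decay)
            any_success = any_success or ok
            if d_idx == 0:
                start_nlls.append(fun)
            if best is None or fun < best[0]:
                best = (fun, x, decay)
    assert best is not None
    nll, x, decay = best
    n_self = sum(1 for r in session.records if r.kind == "self" and r.chosen is not None)
    k = spec.k_params + (1 if decay_candidates is not None else 0)
    return FitResult(
        model_id=model_id,
        best_params=dict(zip(spec.param_names, (float(v) for v in x))),
        nll=nll,
        n_choices=n_self,
        k_params=k,
        bic=bic(nll, k, n_self),
        start_nlls=tuple(start_nlls),
        decay=decay,
        success=any_success,
    )


def rfx_bms(
    log_evidences: np.ndarray,
    rng: np.random.Generator,
    n_samples: int = 100_000,
    alpha0: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BMSResult:
    """Random-effects Bayesian model selection over a subjects x models
    log-evidence matrix.

    Variational posterior over population model frequencies is Dirichlet with
    a uniform prior (alpha0 = 1); exceedance probabilities — the probability
    that each model is the most frequent in the population — are estimated by
    Monte-Carlo sampling of that Dirichlet.
    """
    lme = np.asarray(log_evidences, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    n_sub, n_mod = lme.shape
    alpha = np.full(n_mod, alpha0)
    for _ in range(max_iter):
        w = lme + digamma(alpha) - digamma(alpha.sum())
        w = np.exp(w - w.max(axis=1, keepdims=True))
        u = w / w.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    ep = np.bincount(winners, minlength=n_mod) / n_samples
    return BMSResult(
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance_probabilities=ep,
        n_samples=n_samples,
    )


def fit_cohort_bms(
    sessions: list[tuple[SessionLog, SessionContext]],
    model_ids: tuple[str, ...],
    rng: np.random.Generator,
    n_starts: int = 3,
    n_samples: int = 100_000,
) -> tuple[list[dict[str, FitResult]], BMSResult]:
    """Fit every model to every session and run group BMS on -BIC/2 evidences."""
    fits: list[dict[str, FitResult]] = []
    for session, ctx in sessions:
        fits.append(
            {m: fit_mle(m, session, ctx, rng, n_starts=n_starts) for m in model_ids}
        )
    lme = np.array([[-f[m].bic / 2.0 for m in model_ids] for f in fits])
    return fits, rfx_bms(lme, rng, n_samples=n_samples)


def confusion_study(
    model_ids: tuple[str, ...],
    n_subjects: int,
    simulate_subject,
    rng: np.random.Generator,
    n_starts: int = 3,
    n_samples: int = 100_000,
) -> ConfusionMatrix:
    """Generate-and-recover study.

    For each generating model, ``simulate_subject(model_id, rng)`` must return
    a ``(SessionLog, SessionContext)`` pair with sampled ground-truth
    parameters; all candidate models are fit to each simulated subject and the
    group exceedance probabilities form one row of the confusion matrix.
    """
    ep_rows = []
    for gen in model_ids:
        sessions = [simulate_subject(gen, rng) for _ in range(n_subjects)]
        _, bms = fit_cohort_bms(
            sessions, model_ids, rng, n_starts=n_starts, n_samples=n_samples
        )
        ep_rows.append(bms.exceedance_probabilities)
    return ConfusionMatrix(
        model_ids=tuple(model_ids),
        ep=np.vstack(ep_rows),
        n_subjects=n_subjects,
    )
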