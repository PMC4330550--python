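"""Maximum-likelihood model fitting on the switch/stay objective, and AIC.

The objective is the mean per-trial log probability the model assigns to the
observed stay-or-switch behavior: for every trial with a defined predecessor
(the previous non-missed trial of the session), the model's softmax — with
values updated through the predecessor — gives the probability of repeating
versus changing the previous choice.  With two options this equals the
probability of the observed choice, so the switch/stay conditioning and the
full choice likelihood coincide; the first valid trial contributes no term.
Missed trials contribute neither a likelihood term nor a value update.

AIC is kept on the same per-trial scale: ``AIC = -2 logL + 2 M / N`` with
``logL`` the mean per-trial log-likelihood, ``M`` the number of free
parameters and ``N`` the number of (non-missed) trials.

Estimation runs a seeded global search (differential evolution, restarted)
followed by bounded local refinement (L-BFGS-B); likelihood ties are broken by
the smaller temperature, then lexicographically smaller rates, so fits are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .rl_models import (
    TAU_MAX,
    TAU_MIN,
    Model,
    SubjectParameters,
    _replay_core,
    replay_record,
)
from .task_engine import BehavioralRecord

ALPHA_BOUNDS = (0.0, 1.0)
TAU_BOUNDS = (TAU_MIN, TAU_MAX)


def switch_indicators(record: BehavioralRecord) -> np.ndarray:
    """Per-trial stay/switch indicator B_t (1 = switch, 0 = stay, -1 = undefined).

    Undefined on missed trials and on the first valid trial (no predecessor).
    """
    out = np.full(record.n_trials, -1, dtype=np.int64)
    prev = -1
    for t in range(record.n_trials):
        if record.missed[t]:
            continue
        if prev >= 0:
            out[t] = int(record.choice[t] != prev)
        prev = record.choice[t]
    return out


def switch_stay_counts(record: BehavioralRecord) -> tuple[int, int]:
    """(N_switch, N_stay) over trials with a defined predecessor."""
    b = switch_indicators(record)
    return int((b == 1).sum()), int((b == 0).sum())


def log_likelihood(
    record: BehavioralRecord,
    model: Model,
    params: SubjectParameters,
    v_initial: tuple[float, float] = (0.0, 0.0),
    reset_between_runs: bool = False,
) -> float:
    """Mean per-trial log probability of the observed stay/switch sequence."""
    if record.n_valid_trials == 0:
        raise ValueError("record has no valid (non-missed) trials")
    _, _, _, loglik, n_terms = replay_record(
        record, model, params, v_initial, reset_between_runs
    )
    if n_terms == 0:
        raise ValueError("record has no trial with a defined predecessor")
    return loglik / n_terms


def compute_aic(log_l: float, m: int, n: int) -> float:
    """Per-trial AIC: ``-2 logL + 2 M / N`` (``logL`` is the per-trial mean)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return -2.0 * log_l + 2.0 * m / n


@dataclass(frozen=True)
class OptimizerSettings:
    """Search configuration for the seeded global-then-local optimizer."""

    seed: int = 0
    restarts: int = 2  # independent differential-evolution starts
    de_popsize: int = 16
    de_maxiter: int = 120
    de_tol: float = 1e-7
    polish: bool = True


@dataclass
class FitResult:
    """Fitted parameters and fit quality for one subject and model."""

    subject_id: str
    model: Model
    params: SubjectParameters
    log_likelihood: float  # mean per-trial
    aic: float
    n_trials: int
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "model": self.model.value,
            "params": self.params.as_dict(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_trials": self.n_trials,
            "diagnostics": self.diagnostics,
        }


def model_bounds(model: Model) -> list[tuple[float, float]]:
    """Optimizer bounds for the model's free-parameter vector."""
    n_alphas = {Model.RESCORLA_WAGNER: 1, Model.RISK_SENSITIVE: 2, Model.RSAV: 4}[model]
    return [ALPHA_BOUNDS] * n_alphas + [TAU_BOUNDS]


def unpack_parameters(model: Model, x: Sequence[float]) -> SubjectParameters:
    """Free-parameter vector -> full SubjectParameters for the model."""
    x = [float(v) for v in x]
    if model is Model.RESCORLA_WAGNER:
        return SubjectParameters.rescorla_wagner(x[0], x[1])
    if model is Model.RISK_SENSITIVE:
        return SubjectParameters.risk_sensitive(x[0], x[1], x[2])
    return SubjectParameters(*x)


def _record_arrays(record: BehavioralRecord):
    return (
        np.ascontiguousarray(record.choice, dtype=np.int64),
        np.ascontiguousarray(record.outcome, dtype=np.float64),
        np.ascontiguousarray(record.valid, dtype=np.bool_),
        np.ascontiguousarray(record.run, dtype=np.int64),
    )


def _mean_loglik_fn(records, model, v_initial, reset_between_runs):
    """Build a fast objective: packed vector -> mean per-trial logL over records."""
    arrays = [_record_arrays(r) for r in records]
    v0a, v0b = float(v_initial[0]), float(v_initial[1])
    reset = bool(reset_between_runs)
    is_rw = model is Model.RESCORLA_WAGNER
    is_rs = model is Model.RISK_SENSITIVE

    def mean_loglik(x):
        if is_rw:
            a_cp = a_cn = x[0]
            a_up = a_un = 0.0
            tau = x[1]
        elif is_rs:
            a_cp, a_cn = x[0], x[1]
            a_up = a_un = 0.0
            tau = x[2]
        else:
            a_cp, a_cn, a_up, a_un, tau = x
        total = 0.0
        for choices, outcomes, valid, runs in arrays:
            _, _, _, ll, n_terms = _replay_core(
                choices, outcomes, valid, runs,
                a_cp, a_cn, a_up, a_un, tau, v0a, v0b, reset,
            )
            total += ll / n_terms
        return total / len(arrays)

    return mean_loglik


def _prefer(cand: tuple[float, tuple], best: "tuple[float, tuple] | None") -> bool:
    """Deterministic candidate ordering: higher logL, ties by smaller tau then
    lexicographic rates (tau is the last packed coordinate)."""
    if best is None:
        return True
    ll_c, x_c = cand
    ll_b, x_b = best
    if ll_c != ll_b:
        return ll_c > ll_b
    if x_c[-1] != x_b[-1]:
        return x_c[-1] < x_b[-1]
    return x_c[:-1] < x_b[:-1]


def _maximize(mean_loglik, bounds, settings: OptimizerSettings):
    """Seeded multi-start DE + L-BFGS-B polish; returns (x, logL, diagnostics)."""
    neg = lambda x: -mean_loglik(x)
    seeds = np.random.SeedSequence(settings.seed).generate_state(max(settings.restarts, 1))
    best = None
    converged = False
    nfev = 0
    for s in seeds:
        res = optimize.differential_evolution(
            neg,
            bounds=bounds,
            seed=int(s % (2**31 - 1)),
            popsize=settings.de_popsize,
            maxiter=settings.de_maxiter,
            tol=settings.de_tol,
            polish=False,
        )
        nfev += res.nfev
        converged = converged or bool(res.success)
        cand = (float(-res.fun), tuple(float(v) for v in res.x))
        if _prefer(cand, best):
            best = cand
        if settings.polish:
            local = optimize.minimize(neg, res.x, method="L-BFGS-B", bounds=bounds)
            nfev += local.nfev
            cand = (float(-local.fun), tuple(float(v) for v in local.x))
            if _prefer(cand, best):
                best = cand
    ll, x = best
    diagnostics = {
        "restarts": int(settings.restarts),
        "converged": converged,
        "seed": int(settings.seed),
        "nfev": int(nfev),
    }
    return np.array(x), ll, diagnostics


def fit_subject(
    record: BehavioralRecord,
    model: Model,
    settings: OptimizerSettings = OptimizerSettings(),
    v_initial: tuple[float, float] = (0.0, 0.0),
    reset_between_runs: bool = False,
) -> FitResult:
    """Maximum-likelihood fit of one model to one subject's record."""
    if record.n_valid_trials < 2:
        raise ValueError("need at least two valid trials to fit")
    objective = _mean_loglik_fn([record], model, v_initial, reset_between_runs)
    x, log_l, diagnostics = _maximize(objective, model_bounds(model), settings)
    params = unpack_parameters(model, x)
    n = record.n_valid_trials
    return FitResult(
        subject_id=record.subject_id,
        model=model,
        params=params,
        log_likelihood=log_l,
        aic=compute_aic(log_l, model.n_free_parameters, n),
        n_trials=n,
        diagnostics=diagnostics,
    )


@dataclass
class CanonicalFit:
    """One shared parameter vector maximizing the mean of per-subject mean
    log-likelihoods — used to build common RPE regressors for all subjects."""

    model: Model
    params: SubjectParameters
    pooled_log_likelihood: float
    n_subjects: int
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model": self.model.value,
            "params": self.params.as_dict(),
            "pooled_log_likelihood": self.pooled_log_likelihood,
            "n_subjects": self.n_subjects,
            "diagnostics": self.diagnostics,
        }


def fit_canonical(
    records: Sequence[BehavioralRecord],
    model: Model,
    settings: OptimizerSettings = OptimizerSettings(),
    v_initial: tuple[float, float] = (0.0, 0.0),
    reset_between_runs: bool = False,
) -> CanonicalFit:
    """Fit one parameter vector jointly over all subjects (unweighted mean of
    per-subject mean log-likelihoods)."""
    if len(records) < 1:
        raise ValueError("need at least one record")
    objective = _mean_loglik_fn(records, model, v_initial, reset_between_runs)
    x, log_l, diagnostics = _maximize(objective, model_bounds(model), settings)
    return CanonicalFit(
        model=model,
        params=unpack_parameters(model, x),
        pooled_log_likelihood=log_l,
        n_subjects=len(records),
        diagnostics=diagnostics,
    )


def fit_all_models(
    record: BehavioralRecord,
    settings: OptimizerSettings = OptimizerSettings(),
    models: Sequence[Model] = tuple(Model),
) -> dict[Model, FitResult]:
    """Fit every candidate model to one record."""
    return {m: fit_subject(record, m, settings) for m in models}
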