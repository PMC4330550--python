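"""Random-effects Bayesian model selection (BMS) for groups.

Treats the model identity as a random effect across subjects: model
frequencies ``r`` in the population follow a Dirichlet whose posterior is
estimated by the standard variational iteration (posterior subject-wise model
assignments proportional to ``exp(log-evidence + digamma terms)``, Dirichlet
counts updated from the assignments).  The *exceedance probability* of model
``k`` is the posterior probability that ``r_k`` exceeds every other model's
frequency, estimated by seeded Monte-Carlo sampling from the Dirichlet
posterior.

Per-subject log model evidence is approximated from AIC: since the fitting
stage reports AIC on a per-trial scale, the proxy is ``-0.5 * N * AIC``
(equivalently ``total logL - M``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import digamma

from .fitting import FitResult
from .rl_models import Model

MIN_MC_SAMPLES = 10_000


def log_evidence_from_fit(fit: FitResult) -> float:
    """AIC-based log model evidence proxy on the total-data scale."""
    return -0.5 * fit.n_trials * fit.aic


def evidence_matrix(
    fits_by_subject: Sequence[Mapping[Model, FitResult]],
    models: Sequence[Model] = tuple(Model),
) -> np.ndarray:
    """Stack per-subject, per-model log evidences (subjects x models)."""
    return np.array(
        [[log_evidence_from_fit(fits[m]) for m in models] for fits in fits_by_subject]
    )


@dataclass
class BMSResult:
    """Posterior over model frequencies for a group of subjects."""

    models: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    mc_samples: int
    seed: int
    n_iterations: int

    def as_dict(self) -> dict:
        return {
            "models": list(self.models),
            "dirichlet_alpha": [float(a) for a in self.dirichlet_alpha],
            "expected_frequencies": [float(f) for f in self.expected_frequencies],
            "exceedance_prob": [float(p) for p in self.exceedance_prob],
            "mc_samples": self.mc_samples,
            "seed": self.seed,
            "n_iterations": self.n_iterations,
        }


def exceedance_probabilities(
    dirichlet_alpha: Sequence[float],
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo estimate of P(r_k > r_j for all j != k) under Dirichlet(alpha)."""
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("all Dirichlet concentrations must be > 0")
    if n_samples < MIN_MC_SAMPLES:
        raise ValueError(f"n_samples must be >= {MIN_MC_SAMPLES}")
    rng = np.random.default_rng(seed)
    # sample in blocks to bound memory at large n_samples
    counts = np.zeros(len(alpha), dtype=np.int64)
    block = 200_000
    remaining = int(n_samples)
    while remaining > 0:
        k = min(block, remaining)
        samples = rng.dirichlet(alpha, size=k)
        counts += np.bincount(np.argmax(samples, axis=1), minlength=len(alpha))
        remaining -= k
    return counts / float(n_samples)


def bms_group(
    evidence: np.ndarray,
    prior_alpha: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_samples: int = 1_000_000,
    seed: int = 0,
    models: Sequence[Model] = tuple(Model),
) -> BMSResult:
    """Variational random-effects BMS over a (subjects x models) evidence matrix.

    Iterates subject-wise posterior model assignments and Dirichlet counts to
    convergence (max |delta alpha| < tol), then estimates exceedance
    probabilities by Monte Carlo.
    """
    lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise ValueError("evidence must be (n_subjects >= 1) x (n_models >= 2)")
    if not np.all(np.isfinite(lme)):
        raise ValueError("non-finite model evidence")

    n_subjects, n_models = lme.shape
    alpha0 = np.full(n_models, float(prior_alpha))
    alpha = alpha0.copy()
    trace = []
    for iteration in range(1, max_iter + 1):
        # posterior assignment of each subject to each model
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        g = u / u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        delta = float(np.max(np.abs(alpha_new - alpha)))
        alpha = alpha_new
        trace.append(delta)
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"BMS did not converge in {max_iter} iterations; "
            f"last |delta alpha| trace: {trace[-5:]}"
        )

    expected = alpha / alpha.sum()
    px = exceedance_probabilities(alpha, n_samples=n_samples, seed=seed)
    return BMSResult(
        models=tuple(m.value for m in models[:n_models]),
        dirichlet_alpha=alpha,
        expected_frequencies=expected,
        exceedance_prob=px,
        mc_samples=int(n_samples),
        seed=int(seed),
        n_iterations=iteration,
    )


def bms_from_fits(
    fits_by_subject: Sequence[Mapping[Model, FitResult]],
    models: Sequence[Model] = tuple(Model),
    **kwargs,
) -> BMSResult:
    """Convenience wrapper: per-subject fit dicts -> BMS result."""
    return bms_group(evidence_matrix(fits_by_subject, models), models=models, **kwargs)
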