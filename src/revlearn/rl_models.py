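"""Reinforcement-learning models of reversal-learning behavior.

Three nested models share the prediction-error update ``RPE_t = R_t - V_t``
and a softmax choice rule:

* **Rescorla-Wagner (RW)** — one learning rate ``alpha`` applied to the chosen
  option's value; the unchosen option is not updated.  2 free parameters
  (``alpha``, ``tau``).
* **Risk-sensitive (RS)** — separate learning rates for positive
  (``alpha_c_pos``) and negative (``alpha_c_neg``) prediction errors on the
  chosen option.  3 free parameters.
* **Risk-sensitive with anticorrelated valuation (RSAV)** — additionally moves
  the *unchosen* option's value in the opposite direction of the chosen
  option's prediction error, with its own positive/negative rates
  (``alpha_u_pos``, ``alpha_u_neg``); in a two-option reversal task the
  feedback about the chosen option is informative about the other one.
  5 free parameters.

Choice probabilities follow a logistic softmax on the value difference with
temperature ``tau``: ``p(A) = 1 / (1 + exp(-(V_A - V_B)/tau))``.

Initial values default to 0 for both stimuli and values persist across the
runs of a session; both are configurable.  A prediction error of exactly zero
takes the positive-rate branch (a fixed convention; the event has measure zero
for continuous values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from numba import njit

from .task_engine import BehavioralRecord, TaskConfig, run_session, stimulus_index

TAU_MIN = 0.01
TAU_MAX = 10.0


class Model(str, Enum):
    """The three candidate learning models."""

    RESCORLA_WAGNER = "rw"
    RISK_SENSITIVE = "rs"
    RSAV = "rsav"

    @property
    def n_free_parameters(self) -> int:
        return {"rw": 2, "rs": 3, "rsav": 5}[self.value]

    @property
    def label(self) -> str:
        return {
            "rw": "Rescorla-Wagner",
            "rs": "Risk-sensitive",
            "rsav": "RSAV",
        }[self.value]


@dataclass(frozen=True)
class SubjectParameters:
    """Free parameters of the (largest) model.

    ``alpha_c_pos``/``alpha_c_neg`` are the chosen-option learning rates for
    positive/negative prediction errors, ``alpha_u_pos``/``alpha_u_neg`` the
    anticorrelated unchosen-option rates, and ``tau`` the softmax temperature.
    Smaller models use subsets: RW ties the chosen rates and zeroes the
    unchosen ones, RS zeroes the unchosen ones.
    """

    alpha_c_pos: float
    alpha_c_neg: float
    alpha_u_pos: float
    alpha_u_neg: float
    tau: float

    def __post_init__(self) -> None:
        for name in ("alpha_c_pos", "alpha_c_neg", "alpha_u_pos", "alpha_u_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.tau > 0.0:
            raise ValueError(f"tau={self.tau} must be > 0")

    @classmethod
    def rescorla_wagner(cls, alpha: float, tau: float) -> "SubjectParameters":
        return cls(alpha, alpha, 0.0, 0.0, tau)

    @classmethod
    def risk_sensitive(
        cls, alpha_pos: float, alpha_neg: float, tau: float
    ) -> "SubjectParameters":
        return cls(alpha_pos, alpha_neg, 0.0, 0.0, tau)

    def validate_for(self, model: Model) -> None:
        """Check the model-specific constraints (tied / zeroed rates)."""
        if model is Model.RESCORLA_WAGNER and self.alpha_c_pos != self.alpha_c_neg:
            raise ValueError("RW requires alpha_c_pos == alpha_c_neg")
        if model in (Model.RESCORLA_WAGNER, Model.RISK_SENSITIVE):
            if self.alpha_u_pos != 0.0 or self.alpha_u_neg != 0.0:
                raise ValueError(f"{model.value} requires zero unchosen learning rates")

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha_c_pos": self.alpha_c_pos,
            "alpha_c_neg": self.alpha_c_neg,
            "alpha_u_pos": self.alpha_u_pos,
            "alpha_u_neg": self.alpha_u_neg,
            "tau": self.tau,
        }


@dataclass(frozen=True)
class ValueState:
    """Expected values of the two stimuli (unit outcome scale)."""

    v_a: float = 0.0
    v_b: float = 0.0

    def chosen(self, choice: "int | str") -> float:
        return self.v_a if stimulus_index(choice) == 0 else self.v_b


def compute_rpe(outcome: float, chosen_value: float) -> float:
    """Reward prediction error: received minus expected outcome."""
    return outcome - chosen_value


def effective_rates(model: Model, params: SubjectParameters) -> tuple[float, float, float, float]:
    """Map (model, params) to the four update rates of the general recursion."""
    params.validate_for(model)
    if model is Model.RESCORLA_WAGNER:
        return params.alpha_c_pos, params.alpha_c_pos, 0.0, 0.0
    if model is Model.RISK_SENSITIVE:
        return params.alpha_c_pos, params.alpha_c_neg, 0.0, 0.0
    return params.alpha_c_pos, params.alpha_c_neg, params.alpha_u_pos, params.alpha_u_neg


def update_values(
    model: Model,
    params: SubjectParameters,
    state: ValueState,
    choice: "int | str",
    outcome: float,
) -> ValueState:
    """One value update given the trial's choice and outcome.

    The chosen value moves toward the outcome by ``alpha^{+/-} * RPE``
    (branching on the RPE sign); under RSAV the unchosen value moves by
    ``-alpha_u^{+/-} * RPE`` with the branch taken on the *same* RPE.
    """
    a_cp, a_cn, a_up, a_un = effective_rates(model, params)
    c = stimulus_index(choice)
    v_c = state.v_a if c == 0 else state.v_b
    rpe = compute_rpe(outcome, v_c)
    a_c = a_cp if rpe >= 0 else a_cn
    a_u = a_up if rpe >= 0 else a_un
    if c == 0:
        return ValueState(state.v_a + a_c * rpe, state.v_b - a_u * rpe)
    return ValueState(state.v_a - a_u * rpe, state.v_b + a_c * rpe)


def softmax_choice_probabilities(state: ValueState, tau: float) -> tuple[float, float]:
    """Softmax policy on the value difference; returns (p_A, p_B)."""
    if not tau > 0:
        raise ValueError(f"tau={tau} must be > 0")
    x = (state.v_a - state.v_b) / tau
    if x >= 0:
        p_a = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        p_a = e / (1.0 + e)
    return p_a, 1.0 - p_a


# ---------------------------------------------------------------------------
# Deterministic replay core
#
# The same sequential recursion serves value/RPE trace extraction and the
# switch/stay likelihood, so it is written once and JIT-compiled.  Misses
# (valid[t] == False) are skipped entirely: no value update, no likelihood
# term, and the previous-choice pointer is not advanced.
# ---------------------------------------------------------------------------


@njit(cache=False)
def _replay_core(
    choices, outcomes, valid, runs,
    a_cp, a_cn, a_up, a_un, tau,
    v0_a, v0_b, reset_between_runs,
):  # pragma: no cover - exercised via wrappers
    n = choices.shape[0]
    rpe = np.full(n, np.nan)
    v_chosen = np.full(n, np.nan)
    p_choice = np.full(n, np.nan)
    v_a = v0_a
    v_b = v0_b
    prev = -1
    current_run = -1
    loglik = 0.0
    n_terms = 0
    for t in range(n):
        if reset_between_runs and runs[t] != current_run:
            v_a = v0_a
            v_b = v0_b
            prev = -1
        current_run = runs[t]
        if not valid[t]:
            continue
        c = choices[t]
        x = (v_a - v_b) / tau
        if x >= 0.0:
            p_a = 1.0 / (1.0 + math.exp(-x))
        else:
            e = math.exp(x)
            p_a = e / (1.0 + e)
        p_obs = p_a if c == 0 else 1.0 - p_a
        p_choice[t] = p_obs
        if prev >= 0:
            # switch/stay term; for two options it equals the probability of
            # the observed choice
            loglik += math.log(max(p_obs, 1e-300))
            n_terms += 1
        v_c = v_a if c == 0 else v_b
        v_chosen[t] = v_c
        delta = outcomes[t] - v_c
        rpe[t] = delta
        if delta >= 0.0:
            a_c = a_cp
            a_u = a_up
        else:
            a_c = a_cn
            a_u = a_un
        if c == 0:
            v_a = v_a + a_c * delta
            v_b = v_b - a_u * delta
        else:
            v_b = v_b + a_c * delta
            v_a = v_a - a_u * delta
        prev = c
    return rpe, v_chosen, p_choice, loglik, n_terms


def replay_record(
    record: BehavioralRecord,
    model: Model,
    params: SubjectParameters,
    v_initial: tuple[float, float] = (0.0, 0.0),
    reset_between_runs: bool = False,
):
    """Run the deterministic replay; returns full-length per-trial arrays
    (NaN on misses) plus the summed switch/stay log-likelihood and its term
    count."""
    a_cp, a_cn, a_up, a_un = effective_rates(model, params)
    return _replay_core(
        np.ascontiguousarray(record.choice, dtype=np.int64),
        np.ascontiguousarray(record.outcome, dtype=np.float64),
        np.ascontiguousarray(record.valid, dtype=np.bool_),
        np.ascontiguousarray(record.run, dtype=np.int64),
        float(a_cp), float(a_cn), float(a_up), float(a_un), float(params.tau),
        float(v_initial[0]), float(v_initial[1]), bool(reset_between_runs),
    )


@dataclass
class RPETrace:
    """Per-trial prediction errors and chosen values from a deterministic replay.

    Arrays cover the non-missed trials only; ``trial`` holds their indices in
    the original record.
    """

    trial: np.ndarray
    rpe: np.ndarray
    chosen_value: np.ndarray
    choice_prob: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.trial)

    def to_frame(self, onsets=None) -> pd.DataFrame:
        onset = np.full(self.n_trials, np.nan) if onsets is None else np.asarray(onsets)
        return pd.DataFrame(
            {
                "trial": self.trial,
                "onset": onset,
                "rpe": self.rpe,
                "chosen_value": self.chosen_value,
                "choice_prob": self.choice_prob,
            }
        )

    def to_tsv(self, path, onsets=None) -> None:
        self.to_frame(onsets).to_csv(path, sep="\t", index=False, float_format="%.12g")


def compute_rpe_trace(
    record: BehavioralRecord,
    model: Model,
    params: SubjectParameters,
    v_initial: tuple[float, float] = (0.0, 0.0),
    reset_between_runs: bool = False,
) -> RPETrace:
    """Replay observed choices/outcomes through the model and emit the RPE,
    chosen-value and choice-probability sequence.  Pure function of its
    arguments; misses are skipped without a value update."""
    rpe, v_chosen, p_choice, _, _ = replay_record(
        record, model, params, v_initial, reset_between_runs
    )
    idx = np.flatnonzero(record.valid)
    return RPETrace(
        trial=idx,
        rpe=rpe[idx],
        chosen_value=v_chosen[idx],
        choice_prob=p_choice[idx],
    )


class SoftmaxAgent:
    """Simulated subject: softmax choices over model-maintained values."""

    def __init__(
        self,
        model: Model,
        params: SubjectParameters,
        v_initial: tuple[float, float] = (0.0, 0.0),
        reset_between_runs: bool = False,
    ):
        params.validate_for(model)
        self.model = model
        self.params = params
        self._v_initial = v_initial
        self._reset = reset_between_runs
        self.values = ValueState(*v_initial)

    def begin_run(self, run_index: int) -> None:
        if self._reset:
            self.values = ValueState(*self._v_initial)

    def choose(self, rng: np.random.Generator) -> int:
        p_a, _ = softmax_choice_probabilities(self.values, self.params.tau)
        return 0 if rng.random() < p_a else 1

    def observe(self, choice: int, outcome: int) -> None:
        self.values = update_values(self.model, self.params, self.values, choice, outcome)


def simulate_agent(
    model: Model,
    params: SubjectParameters,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "sub-01",
    group: str = "custom",
    v_initial: tuple[float, float] = (0.0, 0.0),
    reset_between_runs: bool = False,
) -> BehavioralRecord:
    """Forward-simulate a softmax learner on the reversal task."""
    agent = SoftmaxAgent(model, params, v_initial, reset_between_runs)
    return run_session(config, agent, rng, subject_id=subject_id, group=group)
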