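"""Probabilistic reversal-learning task environment.

Two stimuli (``A`` and ``B``) are presented on every trial; one of them is
covertly designated *correct* and pays a reward with high probability (default
80%), the other pays a punishment with the same probability.  After the subject
has accumulated a criterion number of correct choices since the last reversal
(drawn uniformly between 6 and 10 per block), of which at least 3 must be
consecutive, the contingencies flip and the previously incorrect stimulus
becomes the correct one.

Outcomes are coded on a unit scale, ``+1`` for reward and ``-1`` for
punishment; the monetary amounts attached to outcomes in the original task are
labels only and carried in :class:`TaskConfig` for reference.  Missed trials
(no response in time) carry no outcome and never advance the reversal
counters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

STIMULI = ("A", "B")

#: sentinel choice index for a missed (no-response) trial
MISSED = -1

_TSV_COLUMNS = [
    "subject_id",
    "group",
    "run",
    "trial",
    "choice",
    "correct_stimulus",
    "outcome",
    "missed",
    "reversal_after",
]


def stimulus_index(stimulus: "int | str") -> int:
    """Normalize a stimulus id ('A'/'B' or 0/1) to an integer index."""
    if isinstance(stimulus, str):
        s = stimulus.strip().upper()
        if s in STIMULI:
            return STIMULI.index(s)
        raise ValueError(f"invalid stimulus id {stimulus!r}; expected one of {STIMULI}")
    idx = int(stimulus)
    if idx in (0, 1):
        return idx
    raise ValueError(f"invalid stimulus id {stimulus!r}; expected 0/1 or 'A'/'B'")


def stimulus_label(index: int) -> str:
    return "NA" if index == MISSED else STIMULI[index]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the reversal-learning task.

    Defaults reproduce the study design: two runs of 60 trials, 80/20 reward
    contingencies, reversal after 6-10 correct choices with at least 3
    consecutive correct.
    """

    n_runs: int = 2
    trials_per_run: int = 60
    p_reward_correct: float = 0.8
    p_reward_incorrect: float = 0.2
    reversal_min_correct: int = 6
    reversal_max_correct: int = 10
    consecutive_correct_required: int = 3
    reward_magnitude: float = 50.0
    punishment_magnitude: float = -50.0
    miss_penalty: float = -100.0
    miss_probability: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_reward_incorrect < self.p_reward_correct <= 1.0):
            raise ValueError(
                "require 0 <= p_reward_incorrect < p_reward_correct <= 1, got "
                f"{self.p_reward_incorrect} and {self.p_reward_correct}"
            )
        if self.reversal_min_correct > self.reversal_max_correct:
            raise ValueError("reversal_min_correct must be <= reversal_max_correct")
        if self.consecutive_correct_required > self.reversal_min_correct:
            raise ValueError(
                "consecutive_correct_required must be <= reversal_min_correct"
            )
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise ValueError("n_runs and trials_per_run must be >= 1")
        if not (0.0 <= self.miss_probability <= 1.0):
            raise ValueError("miss_probability must be a probability")


@dataclass(frozen=True)
class TaskState:
    """Hidden state of the task: which stimulus is correct and the reversal counters."""

    current_correct_stimulus: int
    reversal_criterion: int
    correct_count_since_reversal: int = 0
    consecutive_correct: int = 0
    trial_index: int = 0


@dataclass(frozen=True)
class TrialOutcome:
    """Result of a single completed (or missed) trial."""

    chosen_stimulus: int
    was_correct_choice: bool
    reward_delivered: bool
    outcome_value: int  # +1 reward, -1 punishment, 0 on a miss
    reversal_occurred_after: bool
    missed: bool = False


def draw_reversal_criterion(config: TaskConfig, rng: np.random.Generator) -> int:
    """Draw the per-block reversal criterion, uniform on [min, max] inclusive."""
    return int(
        rng.integers(config.reversal_min_correct, config.reversal_max_correct + 1)
    )


def initial_state(config: TaskConfig, rng: np.random.Generator) -> TaskState:
    """Initialize task state: random correct stimulus, fresh criterion."""
    correct = int(rng.integers(0, 2))
    return TaskState(
        current_correct_stimulus=correct,
        reversal_criterion=draw_reversal_criterion(config, rng),
    )


def step_trial(
    state: TaskState,
    config: TaskConfig,
    choice: "int | str",
    rng: np.random.Generator,
) -> tuple[TrialOutcome, TaskState]:
    """Play one trial: sample the outcome, update counters, maybe reverse.

    The reversal (flip of the correct stimulus, counter reset, new criterion)
    fires once the count of correct choices since the last reversal reaches the
    block's criterion *and* at least ``consecutive_correct_required`` of them
    were consecutive; it takes effect from the next trial.
    """
    chosen = stimulus_index(choice)
    was_correct = chosen == state.current_correct_stimulus
    p_reward = config.p_reward_correct if was_correct else config.p_reward_incorrect
    rewarded = bool(rng.random() < p_reward)

    correct_count = state.correct_count_since_reversal
    consecutive = state.consecutive_correct
    if was_correct:
        correct_count += 1
        consecutive += 1
    else:
        consecutive = 0

    reverse = (
        correct_count >= state.reversal_criterion
        and consecutive >= config.consecutive_correct_required
    )
    if reverse:
        new_state = TaskState(
            current_correct_stimulus=1 - state.current_correct_stimulus,
            reversal_criterion=draw_reversal_criterion(config, rng),
            correct_count_since_reversal=0,
            consecutive_correct=0,
            trial_index=state.trial_index + 1,
        )
    else:
        new_state = replace(
            state,
            correct_count_since_reversal=correct_count,
            consecutive_correct=consecutive,
            trial_index=state.trial_index + 1,
        )

    outcome = TrialOutcome(
        chosen_stimulus=chosen,
        was_correct_choice=was_correct,
        reward_delivered=rewarded,
        outcome_value=1 if rewarded else -1,
        reversal_occurred_after=reverse,
    )
    return outcome, new_state


@dataclass
class BehavioralRecord:
    """One subject's trial sequence across the whole session (all runs).

    Missed trials have ``choice == -1``, ``outcome == 0`` and ``missed`` set;
    they carry no outcome and are skipped by all downstream likelihood and
    value computations.
    """

    subject_id: str
    group: str
    run: np.ndarray  # int, run index per trial (0-based)
    choice: np.ndarray  # int, 0=A, 1=B, -1=missed
    correct_stimulus: np.ndarray  # int, currently correct stimulus per trial
    outcome: np.ndarray  # int, +1 / -1, 0 on missed trials
    missed: np.ndarray  # bool
    reversal_after: np.ndarray  # bool, contingencies flip after this trial

    def __post_init__(self) -> None:
        self.run = np.asarray(self.run, dtype=np.int64)
        self.choice = np.asarray(self.choice, dtype=np.int64)
        self.correct_stimulus = np.asarray(self.correct_stimulus, dtype=np.int64)
        self.outcome = np.asarray(self.outcome, dtype=np.int64)
        self.missed = np.asarray(self.missed, dtype=bool)
        self.reversal_after = np.asarray(self.reversal_after, dtype=bool)
        n = len(self.choice)
        for name in ("run", "correct_stimulus", "outcome", "missed", "reversal_after"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has length != {n}")

    @property
    def n_trials(self) -> int:
        return len(self.choice)

    @property
    def valid(self) -> np.ndarray:
        """Mask of non-missed trials."""
        return ~self.missed

    @property
    def n_valid_trials(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "run": self.run,
                "trial": np.arange(self.n_trials),
                "choice": [stimulus_label(c) for c in self.choice],
                "correct_stimulus": [stimulus_label(c) for c in self.correct_stimulus],
                "outcome": self.outcome,
                "missed": self.missed.astype(int),
                "reversal_after": self.reversal_after.astype(int),
            }
        )[_TSV_COLUMNS]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BehavioralRecord":
        subject_id = str(frame["subject_id"].iloc[0])
        group = str(frame["group"].iloc[0])
        missed = frame["missed"].astype(bool).to_numpy()
        choice = np.array(
            [MISSED if m else stimulus_index(c) for c, m in zip(frame["choice"], missed)]
        )
        correct = np.array([stimulus_index(c) for c in frame["correct_stimulus"]])
        return cls(
            subject_id=subject_id,
            group=group,
            run=frame["run"].to_numpy(),
            choice=choice,
            correct_stimulus=correct,
            outcome=frame["outcome"].to_numpy(),
            missed=missed,
            reversal_after=frame["reversal_after"].astype(bool).to_numpy(),
        )

    @classmethod
    def from_tsv(cls, path) -> "BehavioralRecord":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@runtime_checkable
class Agent(Protocol):
    """Choice policy driven by :func:`run_session`.

    ``choose`` returns a stimulus id given the random stream; ``observe`` is
    called with the normalized choice index and the outcome value (+1/-1) of
    every completed trial.  An optional ``begin_run(run_index)`` hook is called
    at the start of each run.
    """

    def choose(self, rng: np.random.Generator) -> "int | str": ...

    def observe(self, choice: int, outcome: int) -> None: ...


class CallbackAgent:
    """Adapter wrapping a plain callable ``history -> stimulus id``.

    ``history`` is the list of :class:`TrialOutcome` seen so far (misses
    included).
    """

    def __init__(self, fn: Callable[[Sequence[TrialOutcome]], "int | str"]):
        self._fn = fn
        self.history: list[TrialOutcome] = []

    def choose(self, rng: np.random.Generator) -> "int | str":
        return self._fn(self.history)

    def observe(self, choice: int, outcome: int) -> None:
        pass


def run_session(
    config: TaskConfig,
    agent: "Agent | Callable[[Sequence[TrialOutcome]], int | str]",
    rng: np.random.Generator,
    subject_id: str = "sub-01",
    group: str = "custom",
) -> BehavioralRecord:
    """Run a full session (``n_runs`` x ``trials_per_run`` trials) with an agent.

    Task state, including the identity of the correct stimulus, persists
    across runs.  Miss trials are injected with ``config.miss_probability``
    before the agent is consulted; they are flagged and do not advance the
    reversal counters.
    """
    if callable(agent) and not isinstance(agent, Agent):
        agent = CallbackAgent(agent)

    state = initial_state(config, rng)
    history: list[TrialOutcome] = []
    if isinstance(agent, CallbackAgent):
        agent.history = history  # share the session's trial history
    runs, choices, corrects, outcomes, missed, rev_after = [], [], [], [], [], []

    for run_idx in range(config.n_runs):
        begin = getattr(agent, "begin_run", None)
        if begin is not None:
            begin(run_idx)
        for trial_idx in range(config.trials_per_run):
            corrects.append(state.current_correct_stimulus)
            runs.append(run_idx)
            if config.miss_probability > 0 and rng.random() < config.miss_probability:
                miss = TrialOutcome(
                    chosen_stimulus=MISSED,
                    was_correct_choice=False,
                    reward_delivered=False,
                    outcome_value=0,
                    reversal_occurred_after=False,
                    missed=True,
                )
                history.append(miss)
                choices.append(MISSED)
                outcomes.append(0)
                missed.append(True)
                rev_after.append(False)
                continue
            raw_choice = agent.choose(rng)
            try:
                outcome, state = step_trial(state, config, raw_choice, rng)
            except ValueError as err:
                raise ValueError(
                    f"agent returned invalid stimulus at run {run_idx}, "
                    f"trial {trial_idx}: {err}"
                ) from err
            agent.observe(outcome.chosen_stimulus, outcome.outcome_value)
            history.append(outcome)
            choices.append(outcome.chosen_stimulus)
            outcomes.append(outcome.outcome_value)
            missed.append(False)
            rev_after.append(outcome.reversal_occurred_after)

    return BehavioralRecord(
        subject_id=subject_id,
        group=group,
        run=np.array(runs),
        choice=np.array(choices),
        correct_stimulus=np.array(corrects),
        outcome=np.array(outcomes),
        missed=np.array(missed),
        reversal_after=np.array(rev_after),
    )
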