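"""Behavioral summaries, group statistics on fitted parameters, and RPE
binning / regressor export.

Behavioral summaries follow the constructs reported for the task: percent of
non-missed trials on which the currently correct stimulus was chosen, number
of choice switches, and the mean number of consecutive punished trials
immediately preceding each switch.

Group comparisons mirror the published analysis: a mixed-design ANOVA with
between-subject factor group and within-subject factor parameter, followed by
per-parameter two-sample t-tests Bonferroni-corrected over the five-parameter
family.

For regressor export, each subject's trial-wise prediction errors are split
into three equally sized bins (negative / neutral / positive) by empirical
tertiles, and an events table with mean-centered parametric modulators is
written (RPE at feedback, chosen value at cue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .rl_models import RPETrace
from .task_engine import BehavioralRecord

PARAMETER_NAMES = ("alpha_c_pos", "alpha_c_neg", "alpha_u_pos", "alpha_u_neg", "tau")
BIN_LABELS = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class BehavioralSummary:
    percent_correct: float
    n_switches: int
    mean_punishments_before_switch: float

    def as_dict(self) -> dict:
        return {
            "percent_correct": self.percent_correct,
            "n_switches": self.n_switches,
            "mean_punishments_before_switch": self.mean_punishments_before_switch,
        }


def summarize_behavior(record: BehavioralRecord) -> BehavioralSummary:
    """Percent correct, switch count, and punishments-before-switch.

    All three are computed on the non-missed trials; a switch is a trial whose
    choice differs from the previous non-missed choice, and the punishment
    count preceding a switch is the length of the run of consecutive punished
    (non-missed) trials immediately before it.
    """
    valid = record.valid
    if not valid.any():
        raise ValueError("record has no valid trials")
    choices = record.choice[valid]
    outcomes = record.outcome[valid]
    correct = record.correct_stimulus[valid]

    percent_correct = 100.0 * float(np.mean(choices == correct))

    switches = choices[1:] != choices[:-1]
    n_switches = int(switches.sum())

    punish_runs = []
    for t in np.flatnonzero(switches) + 1:  # index of the switch trial
        run = 0
        s = t - 1
        while s >= 0 and outcomes[s] == -1:
            run += 1
            s -= 1
        punish_runs.append(run)
    mean_punish = float(np.mean(punish_runs)) if punish_runs else float("nan")

    return BehavioralSummary(percent_correct, n_switches, mean_punish)


@dataclass(frozen=True)
class GroupTestResult:
    """One statistical test: statistic, df, raw and corrected p."""

    name: str
    statistic: float
    df: float
    p_raw: float
    p_corrected: float
    correction: str

    def __post_init__(self) -> None:
        if self.p_corrected < self.p_raw - 1e-12 or self.p_corrected > 1 + 1e-12:
            raise ValueError("corrected p must lie in [raw p, 1]")

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
            "correction": self.correction,
        }


def bonferroni(p: float, n_tests: int) -> float:
    return float(min(1.0, n_tests * p))


def ttest_from_summary(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> GroupTestResult:
    """Two-sample pooled t-test reconstructed from group means and SEMs."""
    res = stats.ttest_ind_from_stats(
        mean1, sem1 * np.sqrt(n1), n1, mean2, sem2 * np.sqrt(n2), n2
    )
    return GroupTestResult(
        name="summary_ttest",
        statistic=float(res.statistic),
        df=float(n1 + n2 - 2),
        p_raw=float(res.pvalue),
        p_corrected=float(res.pvalue),
        correction="none",
    )


def parameters_long_frame(
    fits_by_group: Mapping[str, Sequence[FitResult]],
    parameters: Sequence[str] = PARAMETER_NAMES,
) -> pd.DataFrame:
    """Fitted parameters in long format (subject, group, parameter, value)."""
    rows = []
    for group, fits in fits_by_group.items():
        for fit in fits:
            values = fit.params.as_dict()
            for p in parameters:
                rows.append(
                    {
                        "subject": fit.subject_id,
                        "group": group,
                        "parameter": p,
                        "value": values[p],
                    }
                )
    return pd.DataFrame(rows)


def compare_groups_parameters(
    fits_by_group: Mapping[str, Sequence[FitResult]],
    parameters: Sequence[str] = PARAMETER_NAMES,
) -> dict:
    """Mixed-design ANOVA (between: group, within: parameter) plus
    Bonferroni-corrected per-parameter two-sample t-tests.

    The ANOVA uses the classical split-plot sums-of-squares decomposition
    without sphericity correction.  Returns ``{"anova": [...], "ttests":
    {...}}`` with :class:`GroupTestResult` entries.
    """
    groups = list(fits_by_group)
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    for g in groups:
        if len(fits_by_group[g]) < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")

    long = parameters_long_frame(fits_by_group, parameters)

    import pingouin as pg  # deferred: heavy import

    anova_results = []
    anova_flag = None
    try:
        aov = pg.mixed_anova(
            data=long, dv="value", within="parameter", between="group", subject="subject"
        )
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        for _, row in aov.iterrows():
            if not np.isfinite(row["F"]):
                anova_flag = "degenerate variance: non-finite F statistic"
                continue
            anova_results.append(
                GroupTestResult(
                    name=str(row["Source"]),
                    statistic=float(row["F"]),
                    df=float(row["DF1"]),
                    p_raw=float(row[p_col]),
                    p_corrected=float(row[p_col]),
                    correction="none",
                )
            )
    except Exception as err:  # zero-variance input breaks the decomposition
        anova_flag = f"degenerate variance: {err}"

    n_tests = len(parameters)
    ttests = {}
    for p in parameters:
        x = long.query("parameter == @p and group == @groups[0]")["value"].to_numpy()
        y = long.query("parameter == @p and group == @groups[1]")["value"].to_numpy()
        if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
            t_stat, p_raw = 0.0, 1.0
        else:
            res = stats.ttest_ind(x, y)
            t_stat, p_raw = float(res.statistic), float(res.pvalue)
        ttests[p] = GroupTestResult(
            name=p,
            statistic=t_stat,
            df=float(len(x) + len(y) - 2),
            p_raw=p_raw,
            p_corrected=bonferroni(p_raw, n_tests),
            correction=f"bonferroni_{n_tests}",
        )
    return {"anova": anova_results, "ttests": ttests, "anova_flag": anova_flag}


@dataclass
class RPEBins:
    """Tertile split of a subject's RPE trace into equally sized bins."""

    labels: tuple[str, str, str]
    boundaries: tuple[float, float]  # (max of negative bin, max of neutral bin)
    bin_indices: dict[str, np.ndarray]  # trial indices (positions in the trace)

    def bin_of_trial(self, n_trials: int) -> np.ndarray:
        """Per-trial bin label array aligned with the trace."""
        out = np.empty(n_trials, dtype=object)
        for label, idx in self.bin_indices.items():
            out[idx] = label
        return out


def bin_rpes(trace: RPETrace) -> RPEBins:
    """Split the trace's RPEs into three equally sized bins by sorted order.

    Ties are broken by trial order (stable sort); when the trial count is not
    divisible by 3, the earlier (more negative) bins take the extra trials.
    Boundaries are the largest RPE of the negative and neutral bins.
    """
    n = trace.n_trials
    if n < 3:
        raise ValueError("need at least 3 trials to form tertile bins")
    order = np.argsort(trace.rpe, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    splits = np.cumsum(sizes)[:-1]
    chunks = np.split(order, splits)
    bin_indices = {label: np.sort(chunk) for label, chunk in zip(BIN_LABELS, chunks)}
    boundaries = (
        float(trace.rpe[chunks[0]].max()),
        float(trace.rpe[chunks[1]].max()),
    )
    return RPEBins(labels=BIN_LABELS, boundaries=boundaries, bin_indices=bin_indices)


def export_regressors(
    trace: RPETrace,
    bins: RPEBins,
    onsets: np.ndarray,
    path=None,
    cue_onsets: "np.ndarray | None" = None,
) -> pd.DataFrame:
    """Build (and optionally write) an events table for parametric-modulator
    regressors: RPE and its tertile bin at feedback, chosen value at cue.
    Continuous modulators are mean-centered; onsets are in seconds, durations
    0 (impulse regressors)."""
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) != trace.n_trials:
        raise ValueError(
            f"onsets length {len(onsets)} != trace length {trace.n_trials}"
        )
    if cue_onsets is None:
        cue_onsets = onsets
    cue_onsets = np.asarray(cue_onsets, dtype=float)
    if len(cue_onsets) != trace.n_trials:
        raise ValueError("cue_onsets length mismatch")

    rpe_c = trace.rpe - trace.rpe.mean()
    value_c = trace.chosen_value - trace.chosen_value.mean()
    bin_labels = bins.bin_of_trial(trace.n_trials)

    feedback = pd.DataFrame(
        {
            "onset": onsets,
            "duration": 0.0,
            "trial_type": "feedback",
            "trial": trace.trial,
            "rpe": rpe_c,
            "chosen_value": np.nan,
            "rpe_bin": bin_labels,
        }
    )
    cue = pd.DataFrame(
        {
            "onset": cue_onsets,
            "duration": 0.0,
            "trial_type": "cue",
            "trial": trace.trial,
            "rpe": np.nan,
            "chosen_value": value_c,
            "rpe_bin": "n/a",
        }
    )
    events = (
        pd.concat([cue, feedback], ignore_index=True)
        .sort_values(["trial", "trial_type"], kind="stable")
        .reset_index(drop=True)
    )
    if path is not None:
        events.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return events


def group_bin_boundaries(
    bins_by_subject: Sequence[RPEBins],
) -> dict[str, float]:
    """Group mean and SEM of the per-subject tertile boundaries."""
    lower = np.array([b.boundaries[0] for b in bins_by_subject])
    upper = np.array([b.boundaries[1] for b in bins_by_subject])
    n = len(bins_by_subject)
    return {
        "lower_mean": float(lower.mean()),
        "lower_sem": float(lower.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "upper_mean": float(upper.mean()),
        "upper_sem": float(upper.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "n": n,
    }
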