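"""End-to-end orchestration: simulate -> fit -> select -> analyze -> export.

A :class:`PipelineConfig` (JSON or YAML document, schema-validated) drives the
full analysis: cohort simulation, per-subject fits of all three models, a
model-comparison table with group Bayesian model selection, the canonical
(all-subject) RSAV fit, per-parameter group statistics, and RPE trace /
tertile-bin / regressor export.  All randomness derives from the single
config seed, and per-subject work uses per-subject derived seeds so results
do not depend on execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .cohort_synthesis import (
    ADOLESCENT_SPEC,
    ADULT_SPEC,
    CohortDataset,
    GroupSpec,
    generate_cohort,
    generate_group,
)
from .fitting import (
    FitResult,
    OptimizerSettings,
    fit_canonical,
    fit_subject,
)
from .group_analysis import (
    bin_rpes,
    compare_groups_parameters,
    export_regressors,
    group_bin_boundaries,
    summarize_behavior,
)
from .model_selection import bms_from_fits
from .rl_models import Model, SubjectParameters, compute_rpe_trace
from .task_engine import TaskConfig

logger = logging.getLogger("revlearn")

RESULTS_SCHEMA_VERSION = "1"

#: average trial duration in seconds, used for synthetic regressor onsets
TRIAL_DURATION_S = 9.0


@dataclass(frozen=True)
class SelectionConfig:
    prior_alpha: float = 1.0
    mc_samples: int = 1_000_000


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int
    task: TaskConfig = TaskConfig()
    adolescent: GroupSpec = ADOLESCENT_SPEC
    adult: GroupSpec = ADULT_SPEC
    fitting: OptimizerSettings = OptimizerSettings()
    selection: SelectionConfig = SelectionConfig()
    preset: str = "custom"

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if "seed" not in doc:
            raise ValueError("config requires an explicit 'seed'")
        kwargs: dict = {"seed": int(doc["seed"]), "preset": doc.get("preset", "custom")}
        if "task" in doc:
            kwargs["task"] = TaskConfig(**doc["task"])
        for key in ("adolescent", "adult"):
            if key in doc:
                g = dict(doc[key])
                g["means"] = SubjectParameters(**g["means"])
                kwargs[key] = GroupSpec(**g)
        if "fitting" in doc:
            kwargs["fitting"] = OptimizerSettings(**doc["fitting"])
        if "selection" in doc:
            kwargs["selection"] = SelectionConfig(**doc["selection"])
        unknown = set(doc) - {
            "seed", "preset", "task", "adolescent", "adult", "fitting", "selection",
        }
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        try:
            doc = json.loads(text)  # JSON first: YAML 1.1 misreads '1e-07'
        except json.JSONDecodeError:
            doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ValueError("config document must be a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        def encode(obj):
            if isinstance(obj, SubjectParameters):
                return obj.as_dict()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            return obj

        return {
            "seed": self.seed,
            "preset": self.preset,
            "task": encode(self.task),
            "adolescent": encode(self.adolescent),
            "adult": encode(self.adult),
            "fitting": encode(self.fitting),
            "selection": encode(self.selection),
        }


def paper_preset(seed: int) -> PipelineConfig:
    """Full study design: 19 + 17 subjects, 2 runs x 60 trials."""
    return PipelineConfig(seed=seed, preset="paper", fitting=OptimizerSettings(seed=seed))


def tiny_preset(seed: int) -> PipelineConfig:
    """Smoke-test scale: 2 + 2 subjects, 2 runs x 15 trials, light optimizer."""
    return PipelineConfig(
        seed=seed,
        preset="tiny",
        task=TaskConfig(trials_per_run=15),
        adolescent=dataclasses.replace(ADOLESCENT_SPEC, n_subjects=2),
        adult=dataclasses.replace(ADULT_SPEC, n_subjects=2),
        fitting=OptimizerSettings(seed=seed, restarts=1, de_popsize=8, de_maxiter=40),
        selection=SelectionConfig(mc_samples=100_000),
    )


PRESETS = {"paper": paper_preset, "tiny": tiny_preset}


def _subject_settings(base: OptimizerSettings, subject_index: int, salt: int) -> OptimizerSettings:
    seed = int(
        np.random.SeedSequence([base.seed, salt, subject_index]).generate_state(1)[0]
        % (2**31 - 1)
    )
    return dataclasses.replace(base, seed=seed)


def fit_cohort(
    cohort: CohortDataset,
    settings: OptimizerSettings,
    models: Sequence[Model] = tuple(Model),
) -> list[dict[Model, FitResult]]:
    """Fit every model to every subject; per-subject derived seeds keep the
    result independent of execution order."""
    fits = []
    for i, subject in enumerate(cohort.subjects):
        sub_fits = {}
        for j, model in enumerate(models):
            s = _subject_settings(settings, i, salt=j)
            sub_fits[model] = fit_subject(subject.record, model, s)
        fits.append(sub_fits)
        logger.info("fitted subject %s (%d models)", subject.subject_id, len(models))
    return fits


def model_comparison_table(
    cohort: CohortDataset,
    fits: list[dict[Model, FitResult]],
    selection: SelectionConfig,
    seed: int,
) -> dict:
    """Per-group and overall model-comparison summary: mean +- SD of logL and
    AIC per model, with exceedance probabilities from group BMS."""
    groups = {"all": list(range(len(cohort.subjects)))}
    for i, s in enumerate(cohort.subjects):
        groups.setdefault(s.group, []).append(i)

    table = {}
    for gname, idx in groups.items():
        sub_fits = [fits[i] for i in idx]
        bms = bms_from_fits(
            sub_fits,
            prior_alpha=selection.prior_alpha,
            n_samples=selection.mc_samples,
            seed=seed,
        )
        entry = {"n_subjects": len(idx), "bms": bms.as_dict(), "models": {}}
        for k, model in enumerate(Model):
            lls = np.array([f[model].log_likelihood for f in sub_fits])
            aics = np.array([f[model].aic for f in sub_fits])
            entry["models"][model.value] = {
                "logL_mean": float(lls.mean()),
                "logL_sd": float(lls.std(ddof=1)) if len(lls) > 1 else float("nan"),
                "AIC_mean": float(aics.mean()),
                "AIC_sd": float(aics.std(ddof=1)) if len(aics) > 1 else float("nan"),
                "exceedance_prob": float(bms.exceedance_prob[k]),
            }
        table[gname] = entry
    return table


def run_recovery(
    spec: GroupSpec,
    task: TaskConfig = TaskConfig(),
    model: Model = Model.RSAV,
    n_replications: int = 10,
    seed: int = 0,
    settings: "OptimizerSettings | None" = None,
) -> dict:
    """Parameter-recovery study: simulate cohorts from the group's generative
    parameters, refit the generating model, and report the cohort-mean fitted
    parameters per replication and overall."""
    settings = settings or OptimizerSettings(seed=seed)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replications)
    per_rep = []
    for r, rep_seed in enumerate(rep_seeds):
        cohort_seed = int(rep_seed % (2**31 - 1))
        cohort = CohortDataset(
            subjects=generate_group(spec, task, model, np.random.SeedSequence(cohort_seed)),
            model=model,
            master_seed=cohort_seed,
        )
        fitted, truth = [], []
        for i, subject in enumerate(cohort.subjects):
            s = _subject_settings(settings, i, salt=1000 + r)
            fit = fit_subject(subject.record, model, s)
            fitted.append(fit.params.as_dict())
            truth.append(subject.true_params.as_dict())
        rep = {
            "replication": r,
            "cohort_seed": cohort_seed,
            "fitted_mean": {
                k: float(np.mean([f[k] for f in fitted])) for k in fitted[0]
            },
            "true_mean": {k: float(np.mean([t[k] for t in truth])) for k in truth[0]},
        }
        per_rep.append(rep)
        logger.info("recovery replication %d/%d done", r + 1, n_replications)
    overall = {
        k: float(np.mean([rep["fitted_mean"][k] for rep in per_rep]))
        for k in per_rep[0]["fitted_mean"]
    }
    return {
        "group": spec.label,
        "model": model.value,
        "n_replications": n_replications,
        "n_subjects": spec.n_subjects,
        "seed": seed,
        "replications": per_rep,
        "recovered_mean": overall,
        "generating_mean": spec.means.as_dict(),
    }


def validate_results(results: dict) -> None:
    """Schema check for the machine-readable results document."""
    required = {
        "schema_version",
        "package_version",
        "config",
        "model_comparison",
        "canonical_fit",
        "group_tests",
        "behavior",
        "rpe_bins",
    }
    missing = required - set(results)
    if missing:
        raise ValueError(f"results document missing keys: {sorted(missing)}")
    if results["schema_version"] != RESULTS_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported results schema {results['schema_version']!r}"
        )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis; writes a report bundle and returns the results
    document (also written as ``results.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("pipeline start: preset=%s seed=%d", config.preset, config.seed)

    # 1. simulate the cohort
    cohort = generate_cohort(
        adolescent=config.adolescent,
        adult=config.adult,
        task=config.task,
        master_seed=config.seed,
    )
    cohort.write(outdir / "cohort")
    logger.info("simulated %d subjects", len(cohort.subjects))

    # 2. fit all models per subject
    fits = fit_cohort(cohort, config.fitting)
    fits_doc = [
        {
            "subject_id": cohort.subjects[i].subject_id,
            "group": cohort.subjects[i].group,
            "fits": {m.value: f.as_dict() for m, f in sub.items()},
        }
        for i, sub in enumerate(fits)
    ]
    (outdir / "fits.json").write_text(json.dumps(fits_doc, indent=2))

    # 3. model comparison with group BMS
    table = model_comparison_table(cohort, fits, config.selection, seed=config.seed)
    (outdir / "bms.json").write_text(json.dumps(table, indent=2))

    # 4. canonical RSAV fit over all subjects
    canonical = fit_canonical(cohort.records, Model.RSAV, config.fitting)
    (outdir / "canonical.json").write_text(json.dumps(canonical.as_dict(), indent=2))
    logger.info("canonical RSAV fit: logL=%.4f", canonical.pooled_log_likelihood)

    # 5. group statistics on the RSAV parameters
    fits_by_group: dict[str, list[FitResult]] = {}
    for i, sub in enumerate(fits):
        fits_by_group.setdefault(cohort.subjects[i].group, []).append(sub[Model.RSAV])
    group_tests = compare_groups_parameters(fits_by_group)
    group_tests_doc = {
        "anova": [t.as_dict() for t in group_tests["anova"]],
        "ttests": {k: t.as_dict() for k, t in group_tests["ttests"].items()},
    }

    # 6. RPE traces, tertile bins and regressors from the canonical parameters
    regressor_dir = outdir / "regressors"
    regressor_dir.mkdir(exist_ok=True)
    bins_by_group: dict[str, list] = {}
    for subject in cohort.subjects:
        trace = compute_rpe_trace(subject.record, Model.RSAV, canonical.params)
        bins = bin_rpes(trace)
        onsets = TRIAL_DURATION_S * np.arange(trace.n_trials)
        export_regressors(
            trace, bins, onsets, path=regressor_dir / f"{subject.subject_id}_events.tsv"
        )
        bins_by_group.setdefault(subject.group, []).append(bins)
    rpe_bins_doc = {
        g: group_bin_boundaries(b) for g, b in bins_by_group.items()
    }

    # 7. behavioral summaries
    behavior: dict[str, dict] = {}
    for subject in cohort.subjects:
        summary = summarize_behavior(subject.record)
        behavior.setdefault(subject.group, []).append(summary.as_dict())
    behavior_doc = {
        g: {
            key: float(np.nanmean([s[key] for s in summaries]))
            for key in summaries[0]
        }
        for g, summaries in behavior.items()
    }

    results = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.to_dict(),
        "model_comparison": table,
        "canonical_fit": canonical.as_dict(),
        "group_tests": group_tests_doc,
        "behavior": behavior_doc,
        "rpe_bins": rpe_bins_doc,
    }
    validate_results(results)
    (outdir / "results.json").write_text(json.dumps(results, indent=2))
    _write_report(outdir / "report.md", results)
    logger.info("pipeline done: %s", outdir)
    return results


def _format_model_table(table: dict) -> str:
    lines = []
    header = f"{'Group':<12}{'Model':<18}{'logL':>14}{'AIC':>16}{'p_x':>8}"
    lines.append(header)
    lines.append("-" * len(header))
    for gname, entry in table.items():
        for model in Model:
            m = entry["models"][model.value]
            lines.append(
                f"{gname:<12}{model.label:<18}"
                f"{m['logL_mean']:>7.3f} ± {m['logL_sd']:<5.3f}"
                f"{m['AIC_mean']:>8.3f} ± {m['AIC_sd']:<5.3f}"
                f"{m['exceedance_prob']:>8.3f}"
            )
    return "\n".join(lines)


def _write_report(path: Path, results: dict) -> None:
    cfg = results["config"]
    lines = [
        "# Reversal-learning model comparison report",
        "",
        f"- package version: {results['package_version']}",
        f"- preset: {cfg['preset']}, seed: {cfg['seed']}",
        "",
        "## Model comparison (mean ± SD; p_x = exceedance probability)",
        "",
        "```",
        _format_model_table(results["model_comparison"]),
        "```",
        "",
        "## Canonical RSAV parameters (all subjects)",
        "",
    ]
    for k, v in results["canonical_fit"]["params"].items():
        lines.append(f"- {k}: {v:.4f}")
    lines += ["", "## Group tests on RSAV parameters (Bonferroni-corrected)", ""]
    for name, t in results["group_tests"]["ttests"].items():
        lines.append(
            f"- {name}: t({t['df']:.0f}) = {t['statistic']:.3f}, "
            f"p = {t['p_raw']:.4f} (corrected {t['p_corrected']:.4f})"
        )
    lines += ["", "## Behavior (group means)", ""]
    for g, b in results["behavior"].items():
        lines.append(
            f"- {g}: {b['percent_correct']:.2f}% correct, "
            f"{b['n_switches']:.2f} switches, "
            f"{b['mean_punishments_before_switch']:.2f} punishments before switch"
        )
    lines += ["", "## RPE tertile boundaries (group mean ± SEM)", ""]
    for g, b in results["rpe_bins"].items():
        lines.append(
            f"- {g}: [{b['lower_mean']:.2f} ± {b['lower_sem']:.2f}, "
            f"{b['upper_mean']:.2f} ± {b['upper_sem']:.2f}]"
        )
    path.write_text("\n".join(lines) + "\n")
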