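"""Synthetic cohorts emulating the study design.

Two groups — 19 adolescents and 17 adults — each perform two runs of 60 trials
of the 80/20 reversal task.  Subjects behave according to the RSAV model with
parameters drawn per subject from independent truncated normals centered on
the published group means.  Printed dispersions are standard errors of the
mean; the subject-level SD is recovered as ``SEM * sqrt(n)``.  Learning rates
are truncated to [0, 1] and the temperature to (0.01, 10].

Ground-truth parameters are retained so downstream fits can be scored for
parameter recovery, and every record regenerates bit-identically from the
(spec, master seed) pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .rl_models import TAU_MAX, TAU_MIN, Model, SubjectParameters, simulate_agent
from .task_engine import BehavioralRecord, TaskConfig

PARAMETER_NAMES = ("alpha_c_pos", "alpha_c_neg", "alpha_u_pos", "alpha_u_neg", "tau")


@dataclass(frozen=True)
class GroupSpec:
    """Generative description of one group: size, parameter means, SEMs."""

    label: str
    n_subjects: int
    means: SubjectParameters
    sems: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        missing = set(PARAMETER_NAMES) - set(self.sems)
        if missing:
            raise ValueError(f"sems missing entries for {sorted(missing)}")

    def sd(self, name: str) -> float:
        """Subject-level SD implied by the printed SEM: SD = SEM * sqrt(n)."""
        return self.sems[name] * math.sqrt(self.n_subjects)


#: published RSAV group means and SEMs (adolescents n=19, adults n=17)
ADOLESCENT_SPEC = GroupSpec(
    label="adolescent",
    n_subjects=19,
    means=SubjectParameters(0.62, 0.69, 0.78, 0.63, 1.9),
    sems={
        "alpha_c_pos": 0.07,
        "alpha_c_neg": 0.05,
        "alpha_u_pos": 0.07,
        "alpha_u_neg": 0.04,
        "tau": 0.2,
    },
)

ADULT_SPEC = GroupSpec(
    label="adult",
    n_subjects=17,
    means=SubjectParameters(0.45, 0.49, 0.72, 0.58, 2.4),
    sems={
        "alpha_c_pos": 0.10,
        "alpha_c_neg": 0.05,
        "alpha_u_pos": 0.08,
        "alpha_u_neg": 0.06,
        "tau": 0.2,
    },
)


def _truncated_normal(mean, sd, lo, hi, rng) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_subject_parameters(
    spec: GroupSpec, rng: np.random.Generator
) -> SubjectParameters:
    """Draw one subject's parameters: independent truncated normals per
    parameter (rates on [0, 1], temperature on (0.01, 10])."""
    means = spec.means.as_dict()
    values = {}
    for name in PARAMETER_NAMES:
        lo, hi = (TAU_MIN, TAU_MAX) if name == "tau" else (0.0, 1.0)
        values[name] = _truncated_normal(means[name], spec.sd(name), lo, hi, rng)
    return SubjectParameters(**values)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    true_params: SubjectParameters
    record: BehavioralRecord
    seed: int


@dataclass
class CohortDataset:
    """A generated cohort with per-subject ground truth."""

    subjects: list[SyntheticSubject]
    model: Model
    master_seed: int

    @property
    def records(self) -> list[BehavioralRecord]:
        return [s.record for s in self.subjects]

    def by_group(self) -> dict[str, list[SyntheticSubject]]:
        groups: dict[str, list[SyntheticSubject]] = {}
        for s in self.subjects:
            groups.setdefault(s.group, []).append(s)
        return groups

    def write(self, outdir) -> None:
        """Write per-subject TSVs plus a ground-truth JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "model": self.model.value,
            "master_seed": self.master_seed,
            "subjects": [],
        }
        for s in self.subjects:
            fname = f"{s.subject_id}_trials.tsv"
            s.record.to_tsv(outdir / fname)
            manifest["subjects"].append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "seed": s.seed,
                    "file": fname,
                    "true_params": s.true_params.as_dict(),
                }
            )
        (outdir / "ground_truth.json").write_text(json.dumps(manifest, indent=2))


def generate_group(
    spec: GroupSpec,
    task: TaskConfig,
    model: Model,
    seed_seq: np.random.SeedSequence,
    id_offset: int = 0,
) -> list[SyntheticSubject]:
    """Simulate one group; each subject gets its own derived seed."""
    subjects = []
    children = seed_seq.spawn(spec.n_subjects)
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(seed)
        params = sample_subject_parameters(spec, rng)
        subject_id = f"sub-{id_offset + i + 1:02d}"
        record = simulate_agent(
            model, params, task, rng, subject_id=subject_id, group=spec.label
        )
        subjects.append(SyntheticSubject(subject_id, spec.label, params, record, seed))
    return subjects


def generate_cohort(
    adolescent: GroupSpec = ADOLESCENT_SPEC,
    adult: GroupSpec = ADULT_SPEC,
    task: TaskConfig = TaskConfig(),
    model: Model = Model.RSAV,
    master_seed: int = 0,
) -> CohortDataset:
    """Generate the full two-group cohort (defaults: 19 + 17 subjects,
    2 x 60 trials, RSAV agents at the published group means)."""
    root = np.random.SeedSequence(master_seed)
    adolescent_seq, adult_seq = root.spawn(2)
    subjects = generate_group(adolescent, task, model, adolescent_seq, id_offset=0)
    subjects += generate_group(
        adult, task, model, adult_seq, id_offset=adolescent.n_subjects
    )
    return CohortDataset(subjects=subjects, model=model, master_seed=master_seed)


def load_cohort(indir) -> CohortDataset:
    """Re-load a cohort written by :meth:`CohortDataset.write`."""
    indir = Path(indir)
    manifest = json.loads((indir / "ground_truth.json").read_text())
    subjects = []
    for entry in manifest["subjects"]:
        record = BehavioralRecord.from_tsv(indir / entry["file"])
        subjects.append(
            SyntheticSubject(
                subject_id=entry["subject_id"],
                group=entry["group"],
                true_params=SubjectParameters(**entry["true_params"]),
                record=record,
                seed=entry["seed"],
            )
        )
    return CohortDataset(
        subjects=subjects,
        model=Model(manifest["model"]),
        master_seed=manifest["master_seed"],
    )
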