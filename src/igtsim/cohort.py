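"""Synthetic cohort generator: surrogate subjects with known parameters.

Produces two (or more) groups of simulated subjects whose generating
(M, Gs, Ls) triples are drawn from per-group uniform distributions, with
optional lapse noise so trajectories are not perfectly model-consistent.
The ground truth is kept alongside the trajectories, which makes the
fitting and summary procedures testable end to end without human data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .agent import AgentParams, ParameterError
from .engine import SimulationResult, TrialRecord, run_agent, trials_to_frame
from .fitting import FitTarget
from .task import TaskConfig, default_task

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "SyntheticSubject",
    "default_cohort_spec",
    "generate_cohort",
    "cohort_to_fit_targets",
    "cohort_targets_frame",
    "cohort_truth_frame",
    "write_cohort",
    "read_targets_csv",
    "load_cohort_spec",
]

_Bounds = tuple[float, float]


def _check_bounds(name: str, bounds: _Bounds, low: float, high: float) -> None:
    lo, hi = bounds
    if not (low <= lo <= hi <= high):
        raise ParameterError(
            f"{name} bounds {bounds} must satisfy {low} <= lo <= hi <= {high}"
        )


@dataclass(frozen=True)
class GroupSpec:
    """Uniform parameter distribution and size for one cohort group."""

    name: str
    n_subjects: int = 20
    memory: _Bounds = (0.6, 0.95)
    gain_sensitivity: _Bounds = (0.1, 0.6)
    loss_sensitivity: _Bounds = (0.4, 0.9)

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ParameterError(f"n_subjects must be positive, got {self.n_subjects}")
        _check_bounds("memory", self.memory, 0.0, 1.0)
        _check_bounds("gain_sensitivity", self.gain_sensitivity, 0.01, 1.0)
        _check_bounds("loss_sensitivity", self.loss_sensitivity, 0.01, 1.0)

    def sample_params(self, rng: np.random.Generator) -> AgentParams:
        return AgentParams(
            memory=float(rng.uniform(*self.memory)),
            gain_sensitivity=float(rng.uniform(*self.gain_sensitivity)),
            loss_sensitivity=float(rng.uniform(*self.loss_sensitivity)),
        )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: groups, lapse-noise probability, master seed."""

    groups: tuple[GroupSpec, ...]
    lapse: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ParameterError("cohort needs at least one group")
        if not 0.0 <= self.lapse <= 0.5:
            raise ParameterError(f"lapse must be in [0, 0.5], got {self.lapse}")

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)


def default_cohort_spec(seed: int | None = None, lapse: float = 0.05) -> CohortSpec:
    """Two groups of 20: a learner-like group (high memory, high loss
    sensitivity, low gain sensitivity) and a gain-driven group with the
    opposite profile. Ranges are anchored to the fitted subgroup values
    reported for control vs. substance-abuse cohorts."""
    return CohortSpec(
        groups=(
            GroupSpec(
                name="control",
                n_subjects=20,
                memory=(0.6, 0.95),
                gain_sensitivity=(0.1, 0.6),
                loss_sensitivity=(0.4, 0.9),
            ),
            GroupSpec(
                name="abuse",
                n_subjects=20,
                memory=(0.05, 0.5),
                gain_sensitivity=(0.5, 0.95),
                loss_sensitivity=(0.1, 0.9),
            ),
        ),
        lapse=lapse,
        seed=seed,
    )


@dataclass
class SyntheticSubject:
    """One surrogate participant with its generating parameters."""

    subject_id: str
    group: str
    true_params: AgentParams
    trials: list[TrialRecord]
    block_preferences: np.ndarray
    sim_seed: int | None = None

    @property
    def overall_preference(self) -> float:
        return float(np.mean(self.block_preferences))


def generate_cohort(
    spec: CohortSpec, task: TaskConfig | None = None
) -> list[SyntheticSubject]:
    """Simulate every subject in the spec; a pure function of the spec.

    Per subject, parameters are drawn from the group's distributions and a
    full task run is simulated with lapse noise ``spec.lapse`` (each choice
    independently replaced by a uniformly random deck with that
    probability).
    """
    if task is None:
        task = default_task()
    children = iter(np.random.SeedSequence(spec.seed).spawn(spec.n_subjects))
    subjects = []
    idx = 0
    for group in spec.groups:
        for _ in range(group.n_subjects):
            idx += 1
            child = next(children)
            rng = np.random.default_rng(child)
            params = group.sample_params(rng)
            sim_seed = int(rng.integers(0, 2**63 - 1))
            result = run_agent(params, task, sim_seed, lapse=spec.lapse)
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{group.name}-{idx:03d}",
                    group=group.name,
                    true_params=params,
                    trials=result.trials,
                    block_preferences=result.block_preferences,
                    sim_seed=sim_seed,
                )
            )
    return subjects


def cohort_to_fit_targets(cohort: Sequence[SyntheticSubject]) -> list[FitTarget]:
    """Project a cohort onto the shape the fitting module consumes."""
    return [
        FitTarget(
            subject_id=s.subject_id,
            block_preferences=tuple(float(p) for p in s.block_preferences),
            group=s.group,
        )
        for s in cohort
    ]


def cohort_targets_frame(cohort: Sequence[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        row = {"subject_id": s.subject_id, "group": s.group}
        row.update(
            {f"b{i + 1}": float(p) for i, p in enumerate(s.block_preferences)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_truth_frame(cohort: Sequence[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "group": [s.group for s in cohort],
            "M": [s.true_params.memory for s in cohort],
            "Gs": [s.true_params.gain_sensitivity for s in cohort],
            "Ls": [s.true_params.loss_sensitivity for s in cohort],
        }
    )


def write_cohort(cohort: Sequence[SyntheticSubject], out_dir: str | Path) -> None:
    """Write per-subject trial logs plus targets.csv and truth.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials_dir = out_dir / "trials"
    trials_dir.mkdir(exist_ok=True)
    for s in cohort:
        trials_to_frame(s.trials).to_csv(
            trials_dir / f"{s.subject_id}.csv", index=False
        )
    cohort_targets_frame(cohort).to_csv(out_dir / "targets.csv", index=False)
    cohort_truth_frame(cohort).to_csv(out_dir / "truth.csv", index=False)


def read_targets_csv(path: str | Path) -> list[FitTarget]:
    """Read fit targets from a CSV with columns subject_id, group, b1..b5."""
    frame = pd.read_csv(path)
    block_cols = sorted(
        (c for c in frame.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not block_cols:
        raise ParameterError(f"no block columns (b1..bN) found in {path}")
    return [
        FitTarget(
            subject_id=str(row["subject_id"]),
            block_preferences=tuple(float(row[c]) for c in block_cols),
            group=str(row["group"]) if "group" in frame.columns else "",
        )
        for _, row in frame.iterrows()
    ]


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a cohort spec from YAML/JSON.

    Layout::

        groups:
          - {name: control, n_subjects: 20, memory: [0.6, 0.95],
             gain_sensitivity: [0.1, 0.6], loss_sensitivity: [0.4, 0.9]}
        lapse: 0.05
        seed: 7
    """
    path = Path(path)
    text = path.read_text()
    data = (
        yaml.safe_load(text)
        if path.suffix.lower() in {".yaml", ".yml"}
        else json.loads(text)
    )
    groups = tuple(
        GroupSpec(
            name=g["name"],
            n_subjects=int(g.get("n_subjects", 20)),
            memory=tuple(g.get("memory", (0.6, 0.95))),
            gain_sensitivity=tuple(g.get("gain_sensitivity", (0.1, 0.6))),
            loss_sensitivity=tuple(g.get("loss_sensitivity", (0.4, 0.9))),
        )
        for g in data["groups"]
    )
    return CohortSpec(
        groups=groups,
        lapse=float(data.get("lapse", 0.05)),
        seed=data.get("seed"),
    )
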