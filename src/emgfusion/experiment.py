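"""End-to-end experiments: simulate -> preprocess -> fused CV -> statistics.

The top-level interface follows the model/results idiom: a
:class:`FusionExperiment` is constructed from a cohort and the stage
configs, ``fit()`` executes the full protocol for both training
conditions, and the returned :class:`FusionResults` carries the per-fold
metric estimates, their SDs, the paretic-vs-fused test diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import pandas as pd

from .cohort import Cohort, load_cohort, select_dataset
from .fusion import (CVConfig, Condition, EvalRun, plan_folds, run_condition,
                     prepare_segments)
from .model import ArchitectureConfig, TrainConfig
from .report import subset_definition, compare_runs, make_report, ComparisonRow, export_roc
from .synth import SimConfig, simulate_cohort, RecordingSet


@dataclass(frozen=True)
class ExperimentConfig:
    dataset: str = "A"
    subset: str = "3G"
    conditions: tuple[str, ...] = ("paretic_only", "fused")
    sim: SimConfig = field(default_factory=SimConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.dataset not in ("A", "B"):
            raise ValueError(f"dataset must be 'A' or 'B', got {self.dataset!r}")
        subset_definition(self.subset)        # raises early on unknown subsets
        for c in self.conditions:
            Condition(c)

    def seeded(self) -> "ExperimentConfig":
        """Fan the master seed out to every stage that consumes randomness."""
        return replace(self,
                       sim=replace(self.sim, seed=self.seed),
                       cv=replace(self.cv, seed=self.seed + 1),
                       train=replace(self.train, seed=self.seed + 2))


class FusionExperiment:
    """Model object: a cohort plus the full experimental protocol.

    ``recordings`` may be supplied to evaluate existing data; otherwise the
    synthetic cohort simulator generates them from the experiment seed.
    """

    def __init__(self, config: ExperimentConfig, cohort: Cohort | None = None,
                 recordings: RecordingSet | None = None):
        self.config = config.seeded()
        self.cohort = select_dataset(cohort or load_cohort(), config.dataset)
        self.recordings = recordings

    @classmethod
    def from_cohort_file(cls, path, config: ExperimentConfig) -> "FusionExperiment":
        return cls(config, cohort=load_cohort(path))

    def fit(self, verbose: bool = False) -> "FusionResults":
        cfg = self.config
        t0 = time.time()
        recordings = self.recordings
        if recordings is None:
            recordings = simulate_cohort(self.cohort, cfg.sim)
        segments = prepare_segments(recordings)
        plans = plan_folds(self.cohort.patient_ids, cfg.cv)
        subset = subset_definition(cfg.subset)
        runs: dict[str, EvalRun] = {}
        for cond in cfg.conditions:
            if verbose:
                print(f"[{time.time() - t0:7.1f}s] condition {cond}: "
                      f"{len(plans)} folds ...")
            runs[cond] = run_condition(
                segments, plans, Condition(cond), cfg.arch, cfg.train, subset,
                include_test_subjects_nonparetic=cfg.cv.include_test_subjects_nonparetic,
                cv_config=cfg.cv)
        row = None
        if {"paretic_only", "fused"} <= set(runs):
            row = compare_runs(runs["paretic_only"], runs["fused"],
                               f"{cfg.subset}-{cfg.dataset}")
        return FusionResults(config=cfg, runs=runs, comparison=row,
                             wall_time_s=time.time() - t0)


@dataclass
class FusionResults:
    """Fitted experiment: per-fold estimates, diagnostics and reports."""

    config: ExperimentConfig
    runs: dict[str, EvalRun]
    comparison: ComparisonRow | None
    wall_time_s: float = 0.0

    def metric_table(self) -> pd.DataFrame:
        frames = []
        for cond, run in self.runs.items():
            df = run.fold_metrics.copy()
            df.insert(0, "condition", cond)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Bilateral EMG fusion experiment",
            "=" * 48,
            f"dataset:        {cfg.dataset}",
            f"gesture subset: {cfg.subset} "
            f"({', '.join(g.value for g in subset_definition(cfg.subset))})",
            f"cross-val:      {cfg.cv.n_iterations} iteration(s) x {cfg.cv.n_folds} fold(s), "
            f"{cfg.cv.test_subjects_per_fold} test subject(s)/fold",
            f"training:       {cfg.train.max_epochs} epochs, batch {cfg.train.batch_size}, "
            f"lr {cfg.train.initial_lr}",
            f"seed:           {cfg.seed}",
            "",
        ]
        if self.comparison is not None:
            from .report import format_table
            lines.append(format_table([self.comparison]).rstrip("\n"))
        else:
            for cond, run in self.runs.items():
                means = run.fold_metrics[["SENS", "SP", "ACC", "F1"]].mean()
                lines.append(f"{cond}: " + "  ".join(
                    f"{m}={means[m]:.2f}%" for m in ("SENS", "SP", "ACC", "F1")))
        return "\n".join(lines) + "\n"

    def save(self, out_dir: str | Path) -> dict[str, str]:
        """Persist the report bundle; every artifact re-derivable from the config."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cond, run in self.runs.items():
            run.save(out_dir / cond)
            export_roc(run, out_dir / cond)
            paths[cond] = str(out_dir / cond)
        if self.comparison is not None:
            table = make_report([self.comparison], out_dir=out_dir)
            paths["table"] = str(out_dir / "comparison_table.tsv")
        echo = asdict(self.config)
        echo["wall_time_s"] = self.wall_time_s
        (out_dir / "experiment_config.json").write_text(json.dumps(echo, indent=1))
        paths["config"] = str(out_dir / "experiment_config.json")
        return paths


def run_experiment(config: ExperimentConfig, cohort: Cohort | None = None,
                   verbose: bool = False) -> FusionResults:
    """Convenience wrapper: build, fit and optionally persist an experiment."""
    results = FusionExperiment(config, cohort=cohort).fit(verbose=verbose)
    if config.out_dir:
        results.save(config.out_dir)
    return results


def generate_fixture(out_dir: str | Path, seed: int = 0,
                     cohort: Cohort | None = None,
                     sim: SimConfig | None = None) -> dict[str, str]:
    """Write the cohort table plus seeded synthetic recordings for A and B."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = cohort or load_cohort()
    sim = replace(sim or SimConfig(), seed=seed)
    cohort_path = out_dir / "cohort.csv"
    cohort.save(cohort_path)
    paths = {"cohort": str(cohort_path)}
    recordings = simulate_cohort(cohort, sim)
    for which in ("A", "B"):
        ds = select_dataset(cohort, which)
        sessions = {r.session for r in ds.records}
        subset = RecordingSet([r for r in recordings.recordings
                               if r.session in sessions], sim)
        subset.save(out_dir / f"dataset_{which}")
        paths[f"dataset_{which}"] = str(out_dir / f"dataset_{which}")
    return paths
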