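"""Bilateral data-fusion cross-validation protocol.

Splitting is subject-wise: for each of ``n_iterations`` iterations the
subjects are shuffled and the first ``n_folds * test_subjects_per_fold``
are partitioned into disjoint test groups, so no patient's paretic data
ever appears on both sides of a split. Two training conditions are
compared per fold:

* ``paretic_only`` — paretic-arm segments of the training subjects;
* ``fused`` — the same set plus non-paretic-arm segments (by default from
  *all* subjects, including the held-out ones: the non-paretic arm is
  never tested, so adding it leaks no test data).

The test set is always the paretic segments of the held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .gestures import as_gesture
from .metrics import confusion, macro_metrics
from .model import ArchitectureConfig, TrainConfig, build_model, train, predict_label
from .preprocess import SegmentSet, segments_from_recordings, mav_normalize, FilterSpec
from .synth import RecordingSet


class Condition(str, Enum):
    PARETIC_ONLY = "paretic_only"
    FUSED = "fused"


@dataclass(frozen=True)
class CVConfig:
    n_iterations: int = 100
    n_folds: int = 10
    test_subjects_per_fold: int = 2
    include_test_subjects_nonparetic: bool = True
    seed: int = 0

    def validate_for(self, n_subjects: int) -> None:
        need = self.n_folds * self.test_subjects_per_fold
        if need > n_subjects:
            raise ValueError(
                f"{self.n_folds} folds x {self.test_subjects_per_fold} test subjects "
                f"need {need} subjects but the cohort has {n_subjects}")


@dataclass(frozen=True)
class FoldPlan:
    iteration: int
    fold: int
    test_subjects: tuple[str, ...]
    train_subjects: tuple[str, ...]


def plan_folds(subject_ids, config: CVConfig,
               rng: np.random.Generator | None = None) -> list[FoldPlan]:
    """Repeated random disjoint test draws, ``n_folds`` per iteration.

    Within one iteration the test groups are disjoint; training subjects
    are all remaining subjects (cohort minus that fold's test group), so
    each split is |train| = n - test_subjects_per_fold.
    """
    subject_ids = list(subject_ids)
    config.validate_for(len(subject_ids))
    rng = rng or np.random.default_rng(config.seed)
    plans = []
    for it in range(config.n_iterations):
        order = [subject_ids[i] for i in rng.permutation(len(subject_ids))]
        for fold in range(config.n_folds):
            lo = fold * config.test_subjects_per_fold
            test = tuple(sorted(order[lo:lo + config.test_subjects_per_fold]))
            train_subj = tuple(sorted(set(subject_ids) - set(test)))
            plans.append(FoldPlan(iteration=it, fold=fold,
                                  test_subjects=test, train_subjects=train_subj))
    return plans


def _check_subjects(segset: SegmentSet, subjects) -> None:
    have = set(segset.meta["subject_id"])
    missing = sorted(set(subjects) - have)
    if missing:
        raise ValueError(f"subjects in the fold plan have no segments: {missing}")


def _subset_mask(segset: SegmentSet, gesture_subset) -> np.ndarray:
    if gesture_subset is None:
        return np.ones(len(segset), dtype=bool)
    names = {as_gesture(g).value for g in gesture_subset}
    return segset.gestures.isin(names).to_numpy()


def assemble_training_set(segset: SegmentSet, plan: FoldPlan, condition: Condition,
                          gesture_subset=None,
                          include_test_subjects_nonparetic: bool = True) -> SegmentSet:
    """Training segments for one fold under one condition."""
    condition = Condition(condition)
    _check_subjects(segset, plan.train_subjects + plan.test_subjects)
    meta = segset.meta
    gmask = _subset_mask(segset, gesture_subset)
    train_subj = meta["subject_id"].isin(plan.train_subjects).to_numpy()
    paretic = (meta["arm"] == "paretic").to_numpy()
    mask = train_subj & paretic & gmask
    if condition is Condition.FUSED:
        np_pool = (meta["subject_id"].isin(plan.train_subjects + plan.test_subjects)
                   if include_test_subjects_nonparetic
                   else meta["subject_id"].isin(plan.train_subjects)).to_numpy()
        mask |= np_pool & ~paretic & gmask
    return segset.subset(mask)


def assemble_test_set(segset: SegmentSet, plan: FoldPlan,
                      gesture_subset=None) -> SegmentSet:
    """Paretic segments of the held-out subjects only."""
    _check_subjects(segset, plan.test_subjects)
    meta = segset.meta
    mask = (meta["subject_id"].isin(plan.test_subjects).to_numpy()
            & (meta["arm"] == "paretic").to_numpy()
            & _subset_mask(segset, gesture_subset))
    return segset.subset(mask)


@dataclass
class EvalRun:
    """Per-fold metrics plus pooled test scores for one condition."""

    condition: Condition
    gesture_subset: tuple[str, ...]
    fold_metrics: pd.DataFrame      # iteration, fold, SENS, SP, ACC, F1
    pooled_scores: pd.DataFrame     # keys, true label + one score column per gesture
    cv_config: CVConfig | None = None
    arch: ArchitectureConfig | None = None
    train_config: TrainConfig | None = None

    def metric_values(self, metric: str) -> np.ndarray:
        return self.fold_metrics[metric].to_numpy(dtype=float)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.fold_metrics.to_csv(out_dir / "fold_metrics.csv", index=False)
        self.pooled_scores.to_csv(out_dir / "pooled_scores.csv", index=False)
        from dataclasses import asdict
        echo = {"condition": self.condition.value,
                "gesture_subset": list(self.gesture_subset),
                "cv_config": asdict(self.cv_config) if self.cv_config else None,
                "arch": asdict(self.arch) if self.arch else None,
                "train_config": asdict(self.train_config) if self.train_config else None}
        (out_dir / "config.json").write_text(json.dumps(echo, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "EvalRun":
        in_dir = Path(in_dir)
        echo = json.loads((in_dir / "config.json").read_text())
        def _tup(d, keys):
            for k in keys:
                if d and k in d and isinstance(d[k], list):
                    d[k] = tuple(d[k])
            return d
        return cls(
            condition=Condition(echo["condition"]),
            gesture_subset=tuple(echo["gesture_subset"]),
            fold_metrics=pd.read_csv(in_dir / "fold_metrics.csv"),
            pooled_scores=pd.read_csv(in_dir / "pooled_scores.csv"),
            cv_config=CVConfig(**echo["cv_config"]) if echo["cv_config"] else None,
            arch=ArchitectureConfig(**_tup(echo["arch"], ["conv_filters", "lstm_units",
                                                          "dropout_rates"]))
            if echo["arch"] else None,
            train_config=TrainConfig(**echo["train_config"]) if echo["train_config"] else None,
        )


def derived_seed(master_seed: int, iteration: int, fold: int) -> int:
    """Deterministic per-plan training seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, iteration, fold])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def prepare_segments(recordings: RecordingSet,
                     filter_spec: FilterSpec | None = None) -> SegmentSet:
    """Standard preprocessing: bandpass filter then per-group MAV scaling."""
    return mav_normalize(segments_from_recordings(recordings, filter_spec))


def run_condition(data: RecordingSet | SegmentSet, plans: list[FoldPlan],
                  condition: Condition, arch: ArchitectureConfig,
                  train_config: TrainConfig, gesture_subset,
                  include_test_subjects_nonparetic: bool = True,
                  cv_config: CVConfig | None = None) -> EvalRun:
    """Train and score one condition across all fold plans.

    ``data`` may be raw recordings (preprocessed here with defaults) or an
    already preprocessed SegmentSet. Each plan trains an independent model
    whose seed derives from (train_config.seed, iteration, fold).
    """
    condition = Condition(condition)
    segset = prepare_segments(data) if isinstance(data, RecordingSet) else data
    subset = tuple(as_gesture(g).value for g in gesture_subset)
    if arch.n_classes != len(subset):
        arch = replace(arch, n_classes=len(subset))
    rows, score_rows = [], []
    for plan in plans:
        tr = assemble_training_set(segset, plan, condition, subset,
                                   include_test_subjects_nonparetic)
        te = assemble_test_set(segset, plan, subset)
        seed = derived_seed(train_config.seed, plan.iteration, plan.fold)
        cfg = replace(train_config, seed=seed)
        model = build_model(arch, seed)
        train(model, tr.X, tr.labels_for(subset), cfg)
        probs = model.predict_proba(te.X)
        y_true = te.labels_for(subset)
        cm = confusion(y_true, predict_label(probs), len(subset))
        ms = macro_metrics(cm)
        rows.append({"iteration": plan.iteration, "fold": plan.fold, **ms.as_dict()})
        sc = te.meta[["subject_id", "session", "arm", "gesture", "repetition"]].copy()
        sc.insert(0, "fold", plan.fold)
        sc.insert(0, "iteration", plan.iteration)
        sc["true_label"] = y_true
        for k, name in enumerate(subset):
            sc[f"score_{name}"] = probs[:, k]
        score_rows.append(sc)
    return EvalRun(condition=condition, gesture_subset=subset,
                   fold_metrics=pd.DataFrame(rows),
                   pooled_scores=pd.concat(score_rows, ignore_index=True),
                   cv_config=cv_config, arch=arch, train_config=train_config)
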