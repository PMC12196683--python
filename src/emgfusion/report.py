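"""Gesture-subset registry, paretic-vs-fused statistics, and report tables.

Sub-models are named by class count: 2G = {rest, wrist extension} up to 7G
(all gestures), plus 6G-NR (all except rest); a dataset suffix (-A / -B)
is appended at report time. Conditions are compared per metric with a
two-sided unpaired Student t-test over per-fold values, annotated with the
conventional significance tiers (* p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gestures import Gesture
from .fusion import EvalRun
from .metrics import roc_curve

G = Gesture
SUBSETS: dict[str, tuple[Gesture, ...]] = {
    "2G": (G.REST, G.WRIST_EXTENSION),
    "3G": (G.REST, G.WRIST_EXTENSION, G.THUMBS_UP),
    "4G": (G.REST, G.FIST, G.WRIST_FLEXION, G.WRIST_EXTENSION),
    "5G": (G.REST, G.INDEX_PINCH, G.WRIST_FLEXION, G.WRIST_EXTENSION, G.THUMBS_UP),
    "6G": (G.REST, G.INDEX_PINCH, G.WRIST_FLEXION, G.WRIST_EXTENSION,
           G.FINGERS_OPENING, G.THUMBS_UP),
    "7G": tuple(G),
    "6G-NR": (G.FIST, G.INDEX_PINCH, G.WRIST_FLEXION, G.WRIST_EXTENSION,
              G.FINGERS_OPENING, G.THUMBS_UP),
}

#: (cut-off, annotation), strictly decreasing cut-offs
SIGNIFICANCE_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.05, "*"), (0.01, "**"), (0.001, "***"), (0.0001, "****"))

METRICS = ("SENS", "SP", "ACC", "F1")


def subset_definition(name: str) -> tuple[Gesture, ...]:
    """Resolve a sub-model name ('3G', '6G-NR', optionally '-A'/'-B' suffixed)."""
    base = name
    for suffix in ("-A", "-B"):
        if base.endswith(suffix) and base[:-2] in SUBSETS:
            base = base[:-2]
            break
    if base not in SUBSETS:
        raise KeyError(f"unknown gesture subset {name!r}; known: {sorted(SUBSETS)}")
    return SUBSETS[base]


def unpaired_t(sample_a, sample_b, equal_var: bool = True):
    """Two-sided two-sample t-test; Student (pooled variance) by default.

    Returns ``(t, df, p)``. Degenerate zero-variance input with equal means
    gives (0, df, 1); with unequal means it is an error.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = len(a) + len(b) - 2 if equal_var else None
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(df if df is not None else len(a) + len(b) - 2), 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if df is None:
        df = float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


def stars(p: float, thresholds=SIGNIFICANCE_THRESHOLDS) -> str:
    """Significance annotation: the smallest tier whose cut-off exceeds p."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    annotation = "ns"
    for cutoff, mark in thresholds:
        if p < cutoff:
            annotation = mark
    return annotation


@dataclass(frozen=True)
class ComparisonRow:
    """One Table-style row: a sub-model's paretic vs fused comparison."""

    model_name: str
    paretic_mean: dict[str, float]
    paretic_sd: dict[str, float]
    fused_mean: dict[str, float]
    fused_sd: dict[str, float]
    p_values: dict[str, float]
    annotations: dict[str, str]
    n_folds: int = 0


def compare_runs(run_paretic: EvalRun, run_fused: EvalRun,
                 model_name: str) -> ComparisonRow:
    """Per-metric means, sample SDs and unpaired t-tests across conditions."""
    if run_paretic.gesture_subset != run_fused.gesture_subset:
        raise ValueError("runs use different gesture subsets")
    if (run_paretic.cv_config is not None and run_fused.cv_config is not None
            and run_paretic.cv_config != run_fused.cv_config):
        raise ValueError("runs use different cross-validation configs")
    pm, psd, fm, fsd, ps, ann = {}, {}, {}, {}, {}, {}
    for metric in METRICS:
        a = run_paretic.metric_values(metric)
        b = run_fused.metric_values(metric)
        pm[metric] = float(a.mean())
        psd[metric] = float(a.std(ddof=1)) if len(a) > 1 else 0.0
        fm[metric] = float(b.mean())
        fsd[metric] = float(b.std(ddof=1)) if len(b) > 1 else 0.0
        _, _, p = unpaired_t(a, b)
        ps[metric] = p
        ann[metric] = stars(p)
    return ComparisonRow(model_name=model_name, paretic_mean=pm, paretic_sd=psd,
                         fused_mean=fm, fused_sd=fsd, p_values=ps, annotations=ann,
                         n_folds=len(run_paretic.fold_metrics))


def _fmt_p(p: float) -> str:
    return f"{p:.4g}"


def format_table(rows: list[ComparisonRow]) -> str:
    """Comparison table in the Model / EMG type / metric±SD / p layout."""
    header = ["Model", "EMGType"]
    for m in METRICS:
        header += [f"{m}±SD(%)", "p-Value"]
    lines = ["\t".join(header)]
    for row in rows:
        paretic = [row.model_name, "Paretic"]
        fused = ["", "Fusion"]
        for m in METRICS:
            p_str = _fmt_p(row.p_values[m])
            if row.annotations[m] != "ns":
                p_str += f" {row.annotations[m]}"
            paretic += [f"{row.paretic_mean[m]:.2f} ± {row.paretic_sd[m]:.2f}", p_str]
            fused += [f"{row.fused_mean[m]:.2f} ± {row.fused_sd[m]:.2f}", ""]
        lines.append("\t".join(paretic))
        lines.append("\t".join(fused))
    return "\n".join(lines) + "\n"


def export_roc(run: EvalRun, out_dir: str | Path, prefix: str = "") -> dict[str, float]:
    """Write per-gesture (fpr, tpr) point files from pooled scores; returns AUCs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subset = run.gesture_subset
    scores = run.pooled_scores[[f"score_{g}" for g in subset]].to_numpy()
    y = run.pooled_scores["true_label"].to_numpy()
    aucs = {}
    for k, g in enumerate(subset):
        curve = roc_curve(scores[:, k], (y == k).astype(int), gesture=g)
        pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(
            out_dir / f"{prefix}roc_{g}.csv", index=False)
        aucs[g] = curve.auc
    pd.Series(aucs, name="auc").rename_axis("gesture").to_csv(
        out_dir / f"{prefix}auc.csv")
    return aucs


def make_report(rows: list[ComparisonRow], roc_runs: dict[str, EvalRun] | None = None,
                out_dir: str | Path | None = None) -> str:
    """Assemble the comparison table and optional ROC exports.

    Returns the table text; when ``out_dir`` is given the table and the ROC
    point files are also written there (deterministically, so re-running
    from persisted EvalRuns reproduces the bytes).
    """
    if not rows:
        raise ValueError("need at least one comparison row")
    table = format_table(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "comparison_table.tsv").write_text(table)
        for name, run in (roc_runs or {}).items():
            export_roc(run, out_dir, prefix=f"{name}_")
    return table
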