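"""End-to-end validation benchmarks of the pipeline.

Each function here recomputes, from scratch and at a fixed problem size,
one family of checkable quantities: cohort demographics from the packaged
table, acquisition-protocol constants, agreement of the metric
implementations with independent brute-force oracles, subject-leakage
counts across a full fold plan, learnability of the network on an easy
synthetic task, the bilateral-fusion benefit on a degraded synthetic
cohort, and determinism of the experiment pipeline. They are consumed by
the test suite and by ``scripts/acceptance.py``.

The oracle helpers in this module are deliberately written as plain
enumeration loops, independent of the vectorized / scikit-learn paths in
:mod:`emgfusion.metrics`.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, load_cohort, select_dataset, summarize
from .fusion import (CVConfig, Condition, assemble_test_set,
                     assemble_training_set, plan_folds, run_condition)
from .gestures import GESTURES
from .metrics import macro_metrics, roc_curve
from .model import (ArchitectureConfig, TrainConfig, build_model,
                    parameter_count, predict_label, train)
from .preprocess import FilterSpec, bandpass_gain
from .synth import SimConfig, simulate_cohort


# ------------------------------------------------------------ brute oracles

def brute_macro_metrics(cm: np.ndarray) -> dict[str, float]:
    """One-vs-rest metric means via explicit per-class tallies."""
    cm = np.asarray(cm)
    K = cm.shape[0]
    total = int(cm.sum())
    sens = sp = f1 = 0.0
    for k in range(K):
        tp = fn = fp = tn = 0
        for i in range(K):
            for j in range(K):
                c = int(cm[i, j])
                if i == k and j == k:
                    tp += c
                elif i == k:
                    fn += c
                elif j == k:
                    fp += c
                else:
                    tn += c
        sens_k = tp / (tp + fn) if tp + fn else 0.0
        sp_k = tn / (tn + fp) if tn + fp else 0.0
        prec_k = tp / (tp + fp) if tp + fp else 0.0
        f1_k = (2 * prec_k * sens_k / (prec_k + sens_k)) if prec_k + sens_k else 0.0
        sens += sens_k
        sp += sp_k
        f1 += f1_k
    acc = sum(int(cm[k, k]) for k in range(K)) / total
    return {"SENS": 100 * sens / K, "SP": 100 * sp / K,
            "ACC": 100 * acc, "F1": 100 * f1 / K}


def mann_whitney_auc(scores, truth) -> float:
    """AUC as the positive-over-negative win rate, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def butterworth_bandpass_magnitude(spec: FilterSpec, freq_hz: float) -> float:
    """Closed-form magnitude of a digital Butterworth bandpass.

    Uses the analog prototype response |H|^2 = 1 / (1 + W^(2n)) evaluated at
    the bilinear-prewarped, lowpass-to-bandpass-transformed frequency
    W(f) = (v^2 - v1 v2) / (v (v2 - v1)) with v = tan(pi f / fs); this is
    independent of the designed filter coefficients.
    """
    v = np.tan(np.pi * freq_hz / spec.sampling_rate)
    v1 = np.tan(np.pi * spec.low_cut / spec.sampling_rate)
    v2 = np.tan(np.pi * spec.high_cut / spec.sampling_rate)
    if v == 0:
        return 0.0
    W = (v * v - v1 * v2) / (v * (v2 - v1))
    return float(1.0 / np.sqrt(1.0 + W ** (2 * spec.order)))


def layer_arithmetic_param_count(arch: ArchitectureConfig) -> int:
    """Parameter count from layer arithmetic alone."""
    K = arch.kernel_size
    total = 0
    cin = arch.input_channels
    for f in arch.conv_filters:
        total += cin * f * K + f        # conv weights + bias
        total += 2 * f                  # layer-norm scale + offset
        cin = f
    nin = arch.conv_filters[-1]
    for units in arch.lstm_units:
        total += 4 * (nin + units + 1) * units
        nin = units
    total += nin * arch.n_classes + arch.n_classes
    return total


# ------------------------------------------------------------- benchmarks

def cohort_counts() -> dict[str, float]:
    """Demographic counts of dataset A from the packaged cohort table."""
    cohort = load_cohort()
    ds_a = select_dataset(cohort, "A")
    s = summarize(ds_a)
    return {
        "cohort_n_patients": s.n_patients,
        "cohort_males": s.sex_counts.get("M", 0),
        "cohort_females": s.sex_counts.get("F", 0),
        "cohort_ich_cases": s.stroke_type_counts.get("ICH", 0),
        "cohort_ci_cases": s.stroke_type_counts.get("CI", 0),
        "cohort_right_paresis": s.paretic_side_counts.get("R", 0),
        "cohort_left_paresis": s.paretic_side_counts.get("L", 0),
    }


def protocol_constants(seed: int) -> dict[str, float]:
    """Segment length and per-class balance measured on simulated output."""
    cohort = Cohort(load_cohort().records[:2])
    sim = SimConfig(seed=seed)
    recs = simulate_cohort(cohort, sim)
    lengths = {r.signal.shape[0] for r in recs.recordings}
    counts = recs.manifest().groupby(
        ["subject_id", "session", "arm", "gesture"]).size()
    peak = max(float(np.abs(r.signal).max()) for r in recs.recordings)
    return {
        "segment_samples": lengths.pop() if len(lengths) == 1 else -1,
        "reps_per_class": int(counts.max()) if counts.min() == counts.max() else -1,
        "peak_amplitude_mv": peak,
    }


def oracle_discrepancies(seed: int, n_trials: int = 200) -> dict[str, float]:
    """Max absolute deviation of the implementations from brute-force oracles."""
    rng = np.random.default_rng(seed)
    worst_metrics = 0.0
    for _ in range(n_trials):
        K = int(rng.integers(2, 8))
        cm = rng.integers(0, 30, size=(K, K))
        if cm.sum() == 0:
            cm[0, 0] = 1
        got = macro_metrics(cm).as_dict()
        want = brute_macro_metrics(cm)
        worst_metrics = max(worst_metrics,
                            max(abs(got[k] - want[k]) for k in want))
    worst_auc = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(6, 40))
        scores = np.round(rng.random(n), 2)   # coarse grid forces ties
        truth = rng.integers(0, 2, size=n)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        got = roc_curve(scores, truth).auc
        worst_auc = max(worst_auc, abs(got - mann_whitney_auc(scores, truth)))
    spec = FilterSpec()
    worst_filter = 0.0
    for freq in (5.0, 20.0, 77.5, 150.0, 300.0, 450.0):
        worst_filter = max(worst_filter, abs(bandpass_gain(spec, freq)
                                             - butterworth_bandpass_magnitude(spec, freq)))
    arch = ArchitectureConfig(n_classes=7)
    param_diff = abs(parameter_count(arch) - layer_arithmetic_param_count(arch))
    return {
        "macro_metrics_oracle_max_abs_diff": worst_metrics,
        "auc_mannwhitney_max_abs_diff": worst_auc,
        "filter_gain_oracle_max_abs_diff": worst_filter,
        "param_count_diff": param_diff,
        "param_count_7g": parameter_count(arch),
    }


def leakage_check(seed: int) -> dict[str, float]:
    """Count test/train key intersections across a full default fold plan."""
    cohort = select_dataset(load_cohort(), "A")
    sim = SimConfig(seed=seed)
    recs = simulate_cohort(Cohort(cohort.records), sim)
    from .preprocess import segments_from_recordings
    segs = segments_from_recordings(recs)   # filtering only; stats not needed
    cv = CVConfig(seed=seed)
    plans = plan_folds(cohort.patient_ids, cv)
    subset = tuple(g.value for g in GESTURES)
    intersections = 0
    nonparetic_in_test = 0
    fused_sizes, paretic_sizes, test_sizes = set(), set(), set()
    def keys(s):
        return set(map(tuple, s.meta[["subject_id", "session", "arm", "gesture",
                                      "repetition"]].itertuples(index=False)))
    for plan in plans:
        te = assemble_test_set(segs, plan, subset)
        tr = assemble_training_set(segs, plan, Condition.FUSED, subset)
        tr_p = assemble_training_set(segs, plan, Condition.PARETIC_ONLY, subset)
        kt = keys(te)
        intersections += len(kt & keys(tr)) + len(kt & keys(tr_p))
        nonparetic_in_test += int((te.meta["arm"] == "non_paretic").sum())
        fused_sizes.add(len(tr))
        paretic_sizes.add(len(tr_p))
        test_sizes.add(len(te))
    def only(sizes):
        return sizes.pop() if len(sizes) == 1 else -1
    return {"n_fold_plans": len(plans),
            "leakage_intersections": intersections,
            "nonparetic_segments_in_test": nonparetic_in_test,
            "fused_train_segments": only(fused_sizes),
            "paretic_train_segments": only(paretic_sizes),
            "test_segments": only(test_sizes)}


def learnability(seed: int, max_epochs: int = 100) -> dict[str, float]:
    """Held-out accuracy on an easy 7-class task (no paresis, 20 reps/class)."""
    sim = SimConfig(seed=seed, reps_per_class=20, raw_reps_range=(20, 20),
                    paresis_alpha=1.0, paresis_cocontraction=0.0,
                    paresis_tremor_depth=0.0, paresis_noise_mult=1.0)
    cohort = Cohort(load_cohort().records[:1])
    recs = simulate_cohort(cohort, sim).select(arm="non_paretic")
    from .fusion import prepare_segments
    segs = prepare_segments(recs)
    order = [g.value for g in GESTURES]
    y = segs.labels_for(order)
    rng = np.random.default_rng(seed)
    test_idx = []
    for c in range(7):
        idx = rng.permutation(np.flatnonzero(y == c))
        test_idx.extend(idx[:5])
    test_idx = np.sort(np.asarray(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    arch = ArchitectureConfig(n_classes=7)
    tc = TrainConfig(max_epochs=max_epochs, seed=seed)
    model = build_model(arch, seed)
    train(model, segs.X[train_idx], y[train_idx], tc)
    acc = float(np.mean(predict_label(model.predict_proba(segs.X[test_idx]))
                        == y[test_idx]))
    return {"learnability_holdout_acc": acc,
            "learnability_n_train": int(len(train_idx)),
            "learnability_n_test": int(len(test_idx))}


FUSION_SUBSET = ("rest", "wrist_extension", "thumbs_up")
FUSION_N_SUBJECTS = 12
FUSION_N_ITERATIONS = 2
FUSION_N_FOLDS = 3
FUSION_EPOCHS = 15
FUSION_N_SEEDS = 5


def fusion_benefit(seed: int, n_seeds: int = FUSION_N_SEEDS,
                   verbose: bool = False) -> dict[str, float]:
    """Paretic-only vs fused mean accuracy on a degraded synthetic cohort.

    Study conditions: 12 dataset-A patients with the default paresis model,
    the 3-gesture subset, 2 iterations x 3 subject-wise folds of 2 held-out
    patients each, 15 training epochs; repeated over ``n_seeds`` master
    seeds. The
    benefit statistic is the number of seeds in which the fused condition's
    mean accuracy exceeds the paretic-only condition's.
    """
    cohort = select_dataset(load_cohort(), "A")
    sub = Cohort(cohort.records[:FUSION_N_SUBJECTS])
    arch = ArchitectureConfig(n_classes=len(FUSION_SUBSET))
    wins = 0
    paretic_means, fused_means = [], []
    for s in range(n_seeds):
        master = (seed + 1) * 1000 + s
        sim = SimConfig(seed=master)
        recs = simulate_cohort(sub, sim)
        from .fusion import prepare_segments
        segs = prepare_segments(recs)
        cv = CVConfig(n_iterations=FUSION_N_ITERATIONS, n_folds=FUSION_N_FOLDS,
                      test_subjects_per_fold=2, seed=master)
        plans = plan_folds(sub.patient_ids, cv)
        tc = TrainConfig(max_epochs=FUSION_EPOCHS, seed=master)
        acc = {}
        for cond in (Condition.PARETIC_ONLY, Condition.FUSED):
            run = run_condition(segs, plans, cond, arch, tc, FUSION_SUBSET,
                                cv_config=cv)
            acc[cond] = float(run.fold_metrics["ACC"].mean())
        paretic_means.append(acc[Condition.PARETIC_ONLY])
        fused_means.append(acc[Condition.FUSED])
        wins += int(acc[Condition.FUSED] > acc[Condition.PARETIC_ONLY])
        if verbose:
            print(f"seed {s}: paretic {paretic_means[-1]:.2f} "
                  f"fused {fused_means[-1]:.2f}")
    return {"fusion_seeds_won": wins,
            "fusion_n_seeds": n_seeds,
            "fusion_mean_acc_paretic": float(np.mean(paretic_means)),
            "fusion_mean_acc_fused": float(np.mean(fused_means)),
            "fusion_mean_acc_gain": float(np.mean(fused_means) - np.mean(paretic_means))}


def determinism_check(seed: int) -> dict[str, float]:
    """Identical seeds must reproduce fold plans, manifests and tables."""
    from .experiment import ExperimentConfig, FusionExperiment
    from .report import format_table
    cohort = Cohort(load_cohort().records[:6])
    cfg = ExperimentConfig(
        dataset="A", subset="2G",
        sim=SimConfig(reps_per_class=3, raw_reps_range=(3, 5)),
        cv=CVConfig(n_iterations=1, n_folds=2, test_subjects_per_fold=1),
        train=TrainConfig(max_epochs=3),
        seed=seed)
    tables = []
    manifests = []
    for _ in range(2):
        exp = FusionExperiment(cfg, cohort=cohort)
        recs = simulate_cohort(exp.cohort, exp.config.sim)
        manifests.append(recs.manifest().to_csv())
        res = exp.fit()
        tables.append(format_table([res.comparison]))
    plans_equal = plan_folds(cohort.patient_ids, CVConfig(n_iterations=2, n_folds=2,
                                                          test_subjects_per_fold=1,
                                                          seed=seed)) == \
        plan_folds(cohort.patient_ids, CVConfig(n_iterations=2, n_folds=2,
                                                test_subjects_per_fold=1, seed=seed))
    return {"determinism_identical": int(tables[0] == tables[1]
                                         and manifests[0] == manifests[1]
                                         and plans_equal)}
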