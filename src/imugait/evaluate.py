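"""Subject-wise evaluation protocol, metrics, and paired statistics.

Splitting is by subject, never by window: train/validation/test get 60/20/20
of the subjects (11/4/4 at n=19), all windows of a subject travel together,
and the whole partition is redrawn ten times with different seeds.

Metrics come from one-vs-rest confusion counts per class:
``accuracy = (TP + TN) / (TP + TN + FP + FN)``, which in the multiclass
setting reduces to the fraction of correctly labelled windows, and
``recall = TP / (TP + FN)`` macro-averaged over classes (robust to the
two-fold over-representation of the side-mimicked classes).

Paired model comparisons follow a normality-gated procedure: Shapiro–Wilk
on both samples at alpha = 0.05, then a paired t-test if both pass, else a
Wilcoxon signed-rank test (exact null distribution for n <= 25,
zero-differences discarded).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import (COMPONENT_ORDER, SENSOR_ORDER, SensorSelection,
                 ValidationError)
from .preprocess import PreprocessConfig, assemble_dataset

__all__ = ["SplitPlan", "make_split", "repeated_splits", "ConfusionCounts",
           "confusion", "accuracy", "recall", "per_class_accuracy",
           "StatTestResult", "compare_paired", "run_experiment",
           "all_sensor_subsets"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """A subject-disjoint train/validation/test assignment."""

    train_subjects: tuple[str, ...]
    val_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    repeat_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        groups = [set(self.train_subjects), set(self.val_subjects),
                  set(self.test_subjects)]
        for a, b in itertools.combinations(groups, 2):
            if a & b:
                raise ValidationError(
                    f"subject sets overlap: {sorted(a & b)}")


def make_split(subject_ids, ratios=(0.6, 0.2, 0.2), seed: int = 0,
               repeat_index: int = 0) -> SplitPlan:
    """Shuffle subjects by seed and split 60/20/20.

    Validation and test each get ``round(r * n)`` subjects and training the
    remainder, which reproduces (11, 4, 4) at n = 19.
    """
    subject_ids = list(subject_ids)
    n = len(subject_ids)
    if n < 3:
        raise ValidationError("need at least 3 subjects to split")
    if len(set(subject_ids)) != n:
        raise ValidationError("duplicate subject ids")
    _, r_val, r_test = ratios
    n_val = max(1, int(round(r_val * n)))
    n_test = max(1, int(round(r_test * n)))
    if n_val + n_test >= n:
        raise ValidationError("split ratios leave no training subjects")
    rng = np.random.default_rng(seed)
    order = [subject_ids[i] for i in rng.permutation(n)]
    return SplitPlan(
        train_subjects=tuple(order[n_val + n_test:]),
        val_subjects=tuple(order[:n_val]),
        test_subjects=tuple(order[n_val:n_val + n_test]),
        repeat_index=repeat_index,
        seed=seed,
    )


def repeated_splits(subject_ids, n_repeats: int = 10,
                    base_seed: int = 0) -> list[SplitPlan]:
    """Independent re-draws of the subject partition, one per repeat."""
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    return [make_split(subject_ids, seed=base_seed + r, repeat_index=r)
            for r in range(n_repeats)]


@dataclasses.dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class; each class's four counts sum to N."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])


def confusion(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors differ in length")
    if y_true.size == 0:
        raise ValidationError("empty label vectors")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValidationError(f"{name} outside [0, {n_classes})")
    tp = np.zeros(n_classes, dtype=np.int64)
    tn = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        pos_true = y_true == c
        pos_pred = y_pred == c
        tp[c] = np.sum(pos_true & pos_pred)
        fn[c] = np.sum(pos_true & ~pos_pred)
        fp[c] = np.sum(~pos_true & pos_pred)
        tn[c] = np.sum(~pos_true & ~pos_pred)
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(counts: ConfusionCounts) -> float:
    """Overall fraction of correctly labelled windows (multiclass lifting
    of (TP+TN)/(TP+TN+FP+FN), which it equals exactly in the binary case)."""
    if counts.total == 0:
        raise ValidationError("empty confusion counts")
    return float(counts.tp.sum() / counts.total)


def recall(counts: ConfusionCounts) -> float:
    """Macro average over classes of TP / (TP + FN)."""
    support = counts.tp + counts.fn
    if np.any(support == 0):
        raise ValidationError("a class has no true instances; "
                              "macro recall undefined")
    return float(np.mean(counts.tp / support))


def per_class_accuracy(counts: ConfusionCounts) -> np.ndarray:
    """One-vs-rest (TP+TN)/N for each class."""
    n = counts.total
    if n == 0:
        raise ValidationError("empty confusion counts")
    return (counts.tp + counts.tn) / n


@dataclasses.dataclass
class StatTestResult:
    test_name: str  # "wilcoxon_signed_rank" or "paired_t"
    p_value: float
    normality_p_a: float
    normality_p_b: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _shapiro_p(values: np.ndarray) -> float:
    # constant samples have no defined Shapiro statistic; treat as
    # non-normal so the comparison falls through to the rank test
    if np.ptp(values) == 0:
        return 0.0
    return float(stats.shapiro(values).pvalue)


def compare_paired(values_a, values_b, alpha: float = 0.05,
                   ) -> StatTestResult:
    """Normality-gated paired comparison of two matched metric samples.

    Shapiro–Wilk on each sample; if both p > alpha a paired t-test is used,
    otherwise a Wilcoxon signed-rank test with the exact null distribution
    for n <= 25.  Zero differences are discarded (Wilcoxon's rule); if all
    differences are zero the samples are identical and p = 1.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError("paired samples differ in length")
    if a.size < 3:
        raise ValidationError("need at least 3 pairs")
    p_a = _shapiro_p(a)
    p_b = _shapiro_p(b)
    diffs = a - b
    if np.all(diffs == 0):
        return StatTestResult("wilcoxon_signed_rank", 1.0, p_a, p_b, alpha)
    if p_a > alpha and p_b > alpha:
        p = float(stats.ttest_rel(a, b).pvalue)
        return StatTestResult("paired_t", p, p_a, p_b, alpha)
    nz = diffs[diffs != 0]
    method = "exact" if nz.size <= 25 else "auto"
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return StatTestResult("wilcoxon_signed_rank", float(res.pvalue),
                          p_a, p_b, alpha)


def all_sensor_subsets() -> list[SensorSelection]:
    """All 31 non-empty sensor subsets, all three components."""
    out = []
    for r in range(1, len(SENSOR_ORDER) + 1):
        for combo in itertools.combinations(SENSOR_ORDER, r):
            out.append(SensorSelection(sensors=combo))
    return out


def _mode_components(mode: str) -> tuple[str, ...]:
    if mode == "all":
        return COMPONENT_ORDER
    if mode in COMPONENT_ORDER:
        return (mode,)
    raise ValidationError(f"unknown component mode {mode!r}")


def run_experiment(recordings, selections=None, architectures=("smCNN-1D",),
                   component_modes=("all",), n_repeats: int = 10,
                   preprocess_cfg: PreprocessConfig | None = None,
                   train_cfg=None, base_seed: int = 0,
                   time_trials: int = 3,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train/evaluate every (selection, architecture, component, repeat) cell.

    For each cell: subject-wise split, dataset assembly for the selection
    and component mode, training with early stopping, then test-set
    accuracy, macro recall and inference time.  Afterwards, architectures
    are compared pairwise per (selection, component mode, metric) on their
    matched per-repeat values.

    Returns tidy ``(metrics, stats)`` DataFrames.  A failed cell is logged
    and marked, and the run continues.
    """
    from .models import GaitCNN, TrainConfig  # deferred: avoids cycle

    recordings = list(recordings)
    if not recordings:
        raise ValidationError("no recordings supplied")
    if selections is None:
        selections = [SensorSelection()]
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    train_cfg = train_cfg or TrainConfig()
    subjects = sorted({rec.subject_id for rec in recordings})
    plans = repeated_splits(subjects, n_repeats, base_seed)

    rows = []
    for sel in selections:
        for mode in component_modes:
            run_sel = SensorSelection(sensors=sel.sensors,
                                      components=_mode_components(mode))
            data = assemble_dataset(recordings, run_sel, preprocess_cfg)
            for plan in plans:
                parts = {name: data.subset(subs) for name, subs in (
                    ("train", plan.train_subjects),
                    ("val", plan.val_subjects),
                    ("test", plan.test_subjects))}
                for arch in architectures:
                    row = {
                        "selection": "+".join(run_sel.sensors),
                        "components": "+".join(run_sel.components),
                        "architecture": arch,
                        "repeat": plan.repeat_index,
                        "n_test_windows": parts["test"].n_windows,
                    }
                    try:
                        cfg = dataclasses.replace(
                            train_cfg,
                            seed=train_cfg.seed + 1000 * plan.repeat_index)
                        res = GaitCNN(parts["train"], parts["val"],
                                      architecture=arch).fit(cfg)
                        y_pred = res.predict(parts["test"].tensor)
                        counts = confusion(parts["test"].labels, y_pred,
                                           res.spec.n_classes)
                        timing = res.measure_inference_time(
                            parts["test"].tensor, n_trials=time_trials)
                        row.update({
                            "accuracy": accuracy(counts),
                            "macro_recall": recall(counts),
                            "inference_time_s": timing["median_s"],
                            "epochs": res.n_epochs,
                            "failed": False,
                        })
                    except Exception:  # noqa: BLE001 - runs must survive
                        logger.exception(
                            "cell failed: %s %s repeat %d",
                            row["selection"], arch, plan.repeat_index)
                        row.update({"accuracy": np.nan,
                                    "macro_recall": np.nan,
                                    "inference_time_s": np.nan,
                                    "epochs": 0, "failed": True})
                    rows.append(row)
    metrics = pd.DataFrame(rows)

    stat_rows = []
    group_cols = ["selection", "components"]
    for keys, group in metrics[~metrics["failed"]].groupby(group_cols):
        archs = sorted(group["architecture"].unique())
        for arch_a, arch_b in itertools.combinations(archs, 2):
            ga = group[group["architecture"] == arch_a].sort_values("repeat")
            gb = group[group["architecture"] == arch_b].sort_values("repeat")
            if len(ga) != len(gb) or len(ga) < 3:
                continue
            for metric in ("accuracy", "macro_recall", "inference_time_s"):
                test = compare_paired(ga[metric].to_numpy(),
                                      gb[metric].to_numpy())
                stat_rows.append({
                    "selection": keys[0], "components": keys[1],
                    "metric": metric, "arch_a": arch_a, "arch_b": arch_b,
                    "test": test.test_name, "p_value": test.p_value,
                    "significant": test.significant,
                })
    stats_df = pd.DataFrame(stat_rows)
    return metrics, stats_df
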