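"""Classification metrics and the repeated stratified k-fold protocol.

Metrics follow the usual confusion-matrix definitions: ACC = (TP+TN)/(P+N),
SEN = TP/P, SPE = TN/N, PRE = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN); TPR and TNR
are synonyms for SEN and SPE used when the two classes are survival strata.
Metrics whose denominator is zero are reported as ``None`` (undefined), not
silently as 0, so averages over tiny folds are not distorted.

The cross-validation runner repeats a stratified k-fold split (re-randomized
per run via run-indexed seeds), trains one class-modeling bi-LSTM per fold
on the training split only — standardizer, donors and all — and evaluates on
the held-out fold. Results are summarized as mean +/- sd over the per-run
fold means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    FeatureSequence,
    TrainingConfig,
    build_class_modeling_set,
    fit_standardizer,
    train,
)

METRIC_NAMES = ("acc", "sen", "spe", "pre", "f1")


@dataclass
class ConfusionCounts:
    """Binary confusion counts; P = TP + FN, N = TN + FP."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP

    @property
    def total(self) -> int:
        return self.P + self.N


@dataclass
class MetricsReport:
    """Proportions in [0, 1]; ``None`` marks an undefined (0/0) metric."""

    acc: float | None
    sen: float | None
    spe: float | None
    pre: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class CVResult:
    """Repeated k-fold summary: per-fold reports and mean +/- sd per metric."""

    n_runs: int
    n_folds: int
    fold_reports: list  # [run][fold] -> MetricsReport
    fold_assignments: list  # [run] -> np.ndarray of fold index per sample
    mean: dict = field(default_factory=dict)  # metric -> mean over runs
    sd: dict = field(default_factory=dict)  # metric -> sd over runs
    histories: list = field(default_factory=list)  # [run][fold] -> loss history


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Count TP/TN/FP/FN treating ``positive_class`` as positive."""
    yt = list(y_true)
    yp = list(y_pred)
    if len(yt) != len(yp):
        raise ValueError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted")
    t = np.array([y == positive_class for y in yt])
    p = np.array([y == positive_class for y in yp])
    return ConfusionCounts(
        TP=int((t & p).sum()),
        TN=int((~t & ~p).sum()),
        FP=int((~t & p).sum()),
        FN=int((t & ~p).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """ACC, SEN, SPE, PRE and F1 from confusion counts."""
    if c.total == 0:
        raise ValueError("no samples")
    return MetricsReport(
        acc=_ratio(c.TP + c.TN, c.total),
        sen=_ratio(c.TP, c.P),
        spe=_ratio(c.TN, c.N),
        pre=_ratio(c.TP, c.TP + c.FP),
        f1=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
    )


def tpr_tnr(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """True positive and true negative rates (None when undefined)."""
    return _ratio(c.TP, c.P), _ratio(c.TN, c.N)


def multiclass_accuracy(y_true, y_pred) -> float:
    """Overall fraction of correct predictions."""
    yt = list(y_true)
    yp = list(y_pred)
    if len(yt) != len(yp):
        raise ValueError("length mismatch")
    return float(np.mean([a == b for a, b in zip(yt, yp)]))


def per_class_reports(y_true, y_pred, classes) -> dict:
    """One-vs-rest MetricsReport per class."""
    return {
        cls: compute_metrics(confusion_counts(y_true, y_pred, cls))
        for cls in classes
    }


def repeated_kfold_cv(
    dataset: list[FeatureSequence],
    cfg: TrainingConfig | None = None,
    k: int = 10,
    runs: int = 10,
    seed: int = 0,
    target_class=None,
    class_modeling: bool = True,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the class-modeling bi-LSTM.

    Per fold, the standardizer and the class-modeling training set are built
    from the training split only; metrics are computed on the held-out fold
    with ``target_class`` (default: the first class in sorted order) as
    positive. Fold splits are stratified and re-randomized each run with a
    run-indexed seed, so a given (seed, run) pair always yields the same
    folds.
    """
    if cfg is None:
        cfg = TrainingConfig()
    labels = [s.label for s in dataset]
    classes = sorted(set(labels), key=repr)
    if target_class is None:
        target_class = classes[0]
    counts = {c: labels.count(c) for c in classes}
    smallest = min(counts.values())
    if smallest < k:
        raise ValueError(
            f"smallest class has {smallest} samples (< k={k}); use a smaller k"
        )
    y = np.array([classes.index(l) for l in labels])

    fold_reports: list[list[MetricsReport]] = []
    assignments: list[np.ndarray] = []
    histories: list[list[list[float]]] = []
    for run in range(runs):
        run_seed = int((seed * 1009 + run) % (2**31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=run_seed)
        assign = np.empty(len(dataset), dtype=int)
        run_reports = []
        run_histories = []
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            assign[test_idx] = fold
            train_split = [dataset[i] for i in train_idx]
            test_split = [dataset[i] for i in test_idx]
            standardizer = fit_standardizer(train_split)
            fit_set = (
                build_class_modeling_set(train_split, target_class, seed=run_seed + fold)
                if class_modeling
                else train_split
            )
            model = train(
                fit_set,
                replace(cfg, seed=int((cfg.seed * 7919 + run * 101 + fold) % (2**31 - 1))),
                standardizer,
            )
            y_pred = model.predict(test_split)
            y_true = [s.label for s in test_split]
            run_reports.append(
                compute_metrics(confusion_counts(y_true, y_pred, target_class))
            )
            run_histories.append(model.history["loss"])
        fold_reports.append(run_reports)
        assignments.append(assign)
        histories.append(run_histories)

    result = CVResult(
        n_runs=runs,
        n_folds=k,
        fold_reports=fold_reports,
        fold_assignments=assignments,
        histories=histories,
    )
    for metric in METRIC_NAMES:
        run_means = []
        for run_reports in fold_reports:
            vals = [getattr(r, metric) for r in run_reports if getattr(r, metric) is not None]
            if vals:
                run_means.append(float(np.mean(vals)))
        if run_means:
            result.mean[metric] = float(np.mean(run_means))
            result.sd[metric] = float(np.std(run_means))
    return result


def format_report(result: CVResult) -> str:
    """Plain-text `mean +/- sd` table in percent."""
    lines = [f"{result.n_runs} runs of {result.n_folds}-fold cross-validation"]
    for metric in METRIC_NAMES:
        if metric in result.mean:
            scale = 1.0 if metric == "f1" else 100.0
            unit = "" if metric == "f1" else " %"
            lines.append(
                f"  {metric.upper():>4}: {result.mean[metric] * scale:.2f} "
                f"± {result.sd[metric] * scale:.2f}{unit}"
            )
    return "\n".join(lines)
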