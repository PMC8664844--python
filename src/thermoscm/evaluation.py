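"""Confusion-matrix metrics, ROC/AUC, cross-validation and table harnesses.

Conventions: the positive class is the thermophilic one; a zero factor in
the MCC denominator, or an empty truth class for Sn/Sp, yields 0 so reports
stay total and comparable across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import POSITIVE, LabeledDataset
from .scm import classify, score_dataset


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """ACC/Sn/Sp/MCC (and optionally AUC) for one evaluation."""

    counts: ConfusionCounts | None
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None
    context: dict = field(default_factory=dict)

    _METRICS = ("acc", "sn", "sp", "mcc", "auc")

    def as_dict(self) -> dict[str, float | None]:
        return {m: getattr(self, m) for m in self._METRICS}


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """Standard 2x2 tally with positive = thermophilic."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(predicted)} predictions")
    t = np.asarray(truth) == POSITIVE
    p = np.asarray(predicted) == POSITIVE
    return ConfusionCounts(
        TP=int((t & p).sum()),
        TN=int((~t & ~p).sum()),
        FP=int((~t & p).sum()),
        FN=int((t & ~p).sum()),
    )


def compute_metrics(
    counts: ConfusionCounts, auc: float | None = None, context: dict | None = None
) -> MetricsReport:
    """ACC, Sn, Sp and MCC from confusion counts.

    ACC = (TP+TN)/total; Sn = TP/(TP+FN); Sp = TN/(TN+FP);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Zero denominators yield 0 by convention.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    total = counts.total
    if total == 0:
        raise ValueError("cannot compute metrics on zero evaluated items")
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(denom) if denom else 0.0
    return MetricsReport(
        counts=counts, acc=acc, sn=sn, sp=sp, mcc=mcc, auc=auc, context=context or {}
    )


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 0.5.

    Equals the trapezoidal area under the ROC curve.
    """
    y = np.asarray(labels) == POSITIVE
    if y.all() or not y.any():
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def stratified_fold_plan(
    labels: Sequence[str], folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified K-fold index plan over a label vector."""
    y = (np.asarray(labels) == POSITIVE).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _subset(dataset: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    records = dataset.records
    chosen = [records[i] for i in idx]
    return LabeledDataset(
        positives=[r for r in chosen if r.label == POSITIVE],
        negatives=[r for r in chosen if r.label != POSITIVE],
    )


def evaluate_table(table, dataset: LabeledDataset, mode: str = "fraction") -> MetricsReport:
    """Score a dataset with a thresholded card and report all metrics."""
    scores = score_dataset(dataset.sequences, table, mode=mode)
    predicted = [classify(s, table.threshold) for s in scores]
    counts = confusion(dataset.labels, predicted)
    return compute_metrics(counts, auc=roc_auc(scores, dataset.labels))


def cross_validate(
    train: LabeledDataset,
    g: int,
    ga_config,
    folds: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Honest stratified cross-validation of the whole card-building pipeline.

    For each fold a card is estimated and GA-optimized on the in-fold part
    only, then evaluated on the held-out part; the returned report is the
    fold mean, with the per-fold reports retained under
    ``context["per_fold"]`` and the fold standard deviations under
    ``context["sd"]``.
    """
    from .ga import optimize  # deferred: ga imports this module
    from .scm import estimate_initial
    from dataclasses import replace as dc_replace

    plan = stratified_fold_plan(train.labels, folds, seed)
    per_fold: list[MetricsReport] = []
    for fold_idx, (tr_idx, te_idx) in enumerate(plan):
        fold_train = _subset(train, tr_idx)
        fold_test = _subset(train, te_idx)
        initial = estimate_initial(fold_train, g)
        table = optimize(initial, fold_train, dc_replace(ga_config, seed=ga_config.seed + fold_idx))
        report = evaluate_table(table, fold_test)
        report.context = {"g": g, "fold": fold_idx, "cutoff": table.threshold}
        per_fold.append(report)
    mean, sd = aggregate(per_fold)
    mean.context = {"g": g, "folds": folds, "seed": seed, "per_fold": per_fold, "sd": sd}
    return mean


def aggregate(reports: Sequence[MetricsReport]) -> tuple[MetricsReport, MetricsReport]:
    """Per-metric arithmetic mean and sample (n-1) standard deviation.

    Aggregated reports carry no confusion counts.  The SD of a single report
    is 0 by convention.
    """
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")

    def col(metric: str) -> np.ndarray | None:
        vals = [getattr(r, metric) for r in reports]
        return None if any(v is None for v in vals) else np.asarray(vals, dtype=float)

    means: dict[str, float | None] = {}
    sds: dict[str, float | None] = {}
    for metric in MetricsReport._METRICS:
        vals = col(metric)
        if vals is None:
            means[metric] = sds[metric] = None
        else:
            means[metric] = float(vals.mean())
            sds[metric] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    mean = MetricsReport(counts=None, **means)  # type: ignore[arg-type]
    sd = MetricsReport(counts=None, **sds)  # type: ignore[arg-type]
    return mean, sd


def percentage_point_gain(before: MetricsReport, after: MetricsReport) -> dict[str, float]:
    """Metric improvements of *after* over *before* in percentage points."""
    gains = {}
    for metric in MetricsReport._METRICS:
        b, a = getattr(before, metric), getattr(after, metric)
        if b is not None and a is not None:
            gains[metric] = round((a - b) * 100.0, 10)
    return gains


def gap_sweep(
    train: LabeledDataset,
    test: LabeledDataset | None,
    gaps: Sequence[int],
    ga_config,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validation (and optional independent-test) sweep over gap sizes.

    One row per gap with columns g, R, Cutoff, ACC, Sn, Sp, MCC, AUC —
    R being the Pearson correlation between the selected card and its
    initial card — plus Mean and SD summary rows.
    """
    from .ga import pearson_to_initial, run_repeated
    from .scm import estimate_initial

    rows = []
    cv_reports, ind_reports = [], []
    for g in gaps:
        initial = estimate_initial(train, g)
        table = run_repeated(initial, train, ga_config)
        cv = cross_validate(train, g, ga_config, folds=folds, seed=seed)
        cv_reports.append(cv)
        row = {
            "g": g,
            "R": pearson_to_initial(table, initial),
            "Cutoff": table.threshold,
            **{m.upper() if m != "acc" else "ACC": cv.as_dict()[m] for m in ("acc", "sn", "sp", "mcc", "auc")},
        }
        if test is not None:
            ind = evaluate_table(table, test)
            ind_reports.append(ind)
            row.update({f"IND_{k}": v for k, v in ind.as_dict().items() if v is not None})
        rows.append(row)
    frame = pd.DataFrame(rows)
    mean, sd = aggregate(cv_reports)
    summary = pd.DataFrame(
        [
            {"g": "Mean", "R": frame["R"].mean(), "Cutoff": frame["Cutoff"].mean(),
             **{k.upper() if k != "acc" else "ACC": v for k, v in mean.as_dict().items()}},
            {"g": "SD", "R": frame["R"].std(ddof=1), "Cutoff": frame["Cutoff"].std(ddof=1),
             **{k.upper() if k != "acc" else "ACC": v for k, v in sd.as_dict().items()}},
        ]
    )
    return pd.concat([frame, summary], ignore_index=True)


def initial_vs_optimized(
    train: LabeledDataset,
    test: LabeledDataset | None,
    g: int,
    ga_config,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare the statistical card against its GA-optimized refinement.

    Rows: cross-validation and (optionally) independent-test metrics for the
    initial and optimized cards, mirroring an initial-vs-optimized summary
    table, plus the percentage-point gains.
    """
    from .ga import GaConfig, choose_threshold, run_repeated
    from .scm import estimate_initial
    from dataclasses import replace as dc_replace

    initial = estimate_initial(train, g)
    scores = score_dataset(train.sequences, initial)
    initial.threshold = choose_threshold(scores, train.labels)
    optimized = run_repeated(initial, train, ga_config)

    # "initial" CV = same honest pipeline with a generations-0, single-run GA,
    # i.e. per-fold statistical estimation with threshold selection only.
    degenerate = dc_replace(ga_config, generations=0, population_size=2, runs=1)
    rows = []
    cv_init = cross_validate(train, g, degenerate, folds=folds, seed=seed)
    cv_opt = cross_validate(train, g, ga_config, folds=folds, seed=seed)
    rows.append({"evaluation": "cross-validation", "card": "initial", **cv_init.as_dict()})
    rows.append({"evaluation": "cross-validation", "card": "optimized", **cv_opt.as_dict()})
    rows.append(
        {"evaluation": "cross-validation", "card": "gain (pp)", **percentage_point_gain(cv_init, cv_opt)}
    )
    if test is not None:
        ind_init = evaluate_table(initial, test)
        ind_opt = evaluate_table(optimized, test)
        rows.append({"evaluation": "independent", "card": "initial", **ind_init.as_dict()})
        rows.append({"evaluation": "independent", "card": "optimized", **ind_opt.as_dict()})
        rows.append(
            {"evaluation": "independent", "card": "gain (pp)", **percentage_point_gain(ind_init, ind_opt)}
        )
    return pd.DataFrame(rows)
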