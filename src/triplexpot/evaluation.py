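"""Evaluation metrics and the cross-validation / leave-gene-out protocols.

Closed-form metrics from the 2x2 confusion table:

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Hm  = 2 * Sn * Sp / (Sn + Sp)
    F1  = 2 * PRE * Sn / (PRE + Sn),   PRE = TP / (TP + FP)

plus AUROC (trapezoidal over score thresholds, ties processed as blocks)
and AUPRC (step-wise precision-at-recall summation); both threshold-free
curves come from scikit-learn. Metrics with a zero denominator are
reported as absent (None) with a warning, never coerced to 0.

The cross-validation harness follows the training protocol of the
triplex models: per fold, class-mean profiles are fitted on the training
folds only, positives are optionally augmented by weighted bagging,
negatives are down-sampled to the augmented positive count, and the
untouched test fold is evaluated at its natural class imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .cnn import (
    CNNConfig,
    TrainedModel,
    build_model,
    train_network,
)
from .features import (
    DEFAULT_K_RANGE,
    DEFAULT_PSEUDOCOUNT,
    fit_class_means,
    featurize_dataset,
)
from .io import Dataset, NEGATIVE, POSITIVE
from .sampling import (
    BaggingConfig,
    SplitPlan,
    downsample_negatives,
    leave_gene_out_split,
    stratified_kfold,
    weighted_bagging,
)

SCALAR_METRICS = ("acc", "sn", "sp", "hm", "f1", "pre", "auroc", "auprc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Standard 2x2 tally with the positive class as class of interest."""
    yt = np.asarray(y_true).ravel()
    yp = np.asarray(y_pred).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.isin(arr, [0, 1]).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as absent",
                      stacklevel=3)
        return None
    return num / den


@dataclass
class MetricsReport:
    """Confusion counts, derived metrics, and the raw scores of one evaluation."""

    counts: ConfusionCounts
    acc: Optional[float]
    sn: Optional[float]
    sp: Optional[float]
    hm: Optional[float]
    f1: Optional[float]
    pre: Optional[float]
    auroc: Optional[float]
    auprc: Optional[float]
    scores: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    y_true: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        d = {m: getattr(self, m) for m in SCALAR_METRICS}
        d.update(tp=self.counts.tp, tn=self.counts.tn,
                 fp=self.counts.fp, fn=self.counts.fn)
        return d

    def roc_points(self) -> pd.DataFrame:
        """FPR/TPR curve points for plotting export."""
        fpr, tpr, thr = roc_curve(self.y_true, self.scores)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def metrics_from_counts(
    c: ConfusionCounts,
    scores: Optional[Sequence[float]] = None,
    y_true: Optional[Sequence[int]] = None,
) -> MetricsReport:
    """All closed-form metrics from counts, plus curve areas from scores."""
    acc = _ratio(c.tp + c.tn, c.total, "acc")
    sn = _ratio(c.tp, c.tp + c.fn, "sn")
    sp = _ratio(c.tn, c.tn + c.fp, "sp")
    pre = _ratio(c.tp, c.tp + c.fp, "pre")
    hm = None
    if sn is not None and sp is not None and (sn + sp) > 0:
        hm = 2 * sn * sp / (sn + sp)
    f1 = None
    if pre is not None and sn is not None and (pre + sn) > 0:
        f1 = 2 * pre * sn / (pre + sn)
    auroc = auprc = None
    s = yt = np.empty(0)
    if scores is not None and y_true is not None:
        s = np.asarray(scores, dtype=np.float64).ravel()
        yt = np.asarray(y_true).ravel()
        if s.size != yt.size:
            raise ValueError("scores and y_true lengths differ")
        if ((s < 0) | (s > 1)).any():
            raise ValueError("scores must lie in [0, 1]")
        if np.unique(yt).size == 2:
            auroc = float(roc_auc_score(yt, s))
            auprc = float(average_precision_score(yt, s))
        else:
            warnings.warn("single-class truth: AUROC/AUPRC undefined", stacklevel=2)
    return MetricsReport(counts=c, acc=acc, sn=sn, sp=sp, hm=hm, f1=f1, pre=pre,
                         auroc=auroc, auprc=auprc, scores=s, y_true=yt)


def evaluate_scores(y_true: Sequence[int], scores: Sequence[float],
                    threshold: float = 0.5) -> MetricsReport:
    """Threshold scores at ``threshold`` (>= maps to positive) and report."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    y_pred = (scores >= threshold).astype(int)
    return metrics_from_counts(confusion(y_true, y_pred), scores, y_true)


@dataclass
class CVResult:
    """Per-fold metrics of one cross-validation run, with aggregation."""

    per_fold: list[MetricsReport]
    split: SplitPlan
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    def mean(self, metric: str) -> Optional[float]:
        vals = [getattr(r, metric) for r in self.per_fold]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    def value_range(self, metric: str) -> tuple[Optional[float], Optional[float]]:
        vals = [getattr(r, metric) for r in self.per_fold if getattr(r, metric) is not None]
        return (min(vals), max(vals)) if vals else (None, None)

    def summary(self) -> pd.DataFrame:
        """Fold x metric table with a trailing mean row."""
        rows = [r.to_dict() for r in self.per_fold]
        df = pd.DataFrame(rows, index=[f"fold{i}" for i in range(self.n_folds)])
        df.loc["mean"] = {m: self.mean(m) for m in SCALAR_METRICS}
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.summary().rename_axis("fold").to_csv(path, sep="\t")


def _stage_seeds(seed: int, *tags: int) -> np.ndarray:
    """Three derived sub-seeds (< 2**31) for bagging/down-sampling/training."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, *tags]))
    return rng.integers(0, 2**31 - 1, size=3)


def _train_fold(
    train_pos: Dataset,
    train_neg: Dataset,
    bagging: Optional[BaggingConfig],
    cnn: CNNConfig,
    seeds: np.ndarray,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
):
    """One training run of the full protocol; returns (model, profile)."""
    profile = fit_class_means(train_pos, train_neg, k_range, pseudocount)
    if bagging is not None:
        aug_pos = weighted_bagging(train_pos, replace(bagging, seed=int(seeds[0])))
    else:
        aug_pos = train_pos
    target = len(aug_pos)
    if target > len(train_neg):
        warnings.warn(
            f"only {len(train_neg)} training negatives for {target} augmented "
            "positives; using all negatives (training is mildly positive-heavy)",
            stacklevel=2,
        )
        target = len(train_neg)
    neg_sample = downsample_negatives(train_neg, target, seed=int(seeds[1]))
    X = np.vstack([
        featurize_dataset(aug_pos, profile),
        featurize_dataset(neg_sample, profile),
    ])
    y = np.concatenate([np.ones(len(aug_pos)), np.zeros(len(neg_sample))])
    net = build_model(replace(cnn, seed=int(seeds[2])))
    train_network(net, X, y)
    model = TrainedModel(config=net.cfg, net=net, profile=profile)
    return model, profile


def run_cross_validation(
    pos: Dataset,
    neg: Dataset,
    n_folds: int = 5,
    bagging: Optional[BaggingConfig] = None,
    cnn: CNNConfig = CNNConfig(),
    seed: int = 0,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold cross-validation of the full training protocol.

    Per fold: class-mean profiles are fitted on the training folds only,
    training positives are optionally bagged, training negatives are
    down-sampled to the augmented positive count, the network is trained,
    and the untouched test fold is evaluated at full imbalance.
    """
    pos = pos.with_label(POSITIVE)
    neg = neg.with_label(NEGATIVE)
    combined = Dataset(pos.records + neg.records, name="cv")
    plan = stratified_kfold(combined, n_folds, seed)
    reports: list[MetricsReport] = []
    for fold in range(n_folds):
        try:
            train_pos, test_pos = plan.split(pos, fold)
            train_neg, test_neg = plan.split(neg, fold)
            model, profile = _train_fold(
                train_pos, train_neg, bagging, cnn,
                _stage_seeds(seed, 1, fold), k_range, pseudocount,
            )
            test = Dataset(test_pos.records + test_neg.records, name=f"test{fold}")
            scores = model.predict_proba_matrix(featurize_dataset(test, profile))
            y_true = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
            reports.append(evaluate_scores(y_true, scores, threshold))
        except Exception as exc:
            raise RuntimeError(f"cross-validation fold {fold} failed: {exc}") from exc
    return CVResult(per_fold=reports, split=plan, seed=seed)


def run_leave_gene_out(
    pos: Dataset,
    neg: Dataset,
    gene: str,
    reps: int = 5,
    bagging: Optional[BaggingConfig] = None,
    cnn: CNNConfig = CNNConfig(),
    seed: int = 0,
    neg_split: Optional[SplitPlan] = None,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = 0.5,
) -> list[MetricsReport]:
    """Leave-gene-out validation.

    All transcript variants of ``gene`` form the positive test set; the
    remaining positives train the model. The run is repeated ``reps``
    times with fresh negative down-samples; negative test data come from
    the test side of a fold split over the negatives (one fold per rep),
    so test negatives are never part of the same rep's training pool.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pos = pos.with_label(POSITIVE)
    neg = neg.with_label(NEGATIVE)
    train_pos, test_pos = leave_gene_out_split(pos, gene)
    if neg_split is None:
        neg_split = stratified_kfold(neg, reps, seed)
    reports: list[MetricsReport] = []
    for rep in range(reps):
        fold = rep % neg_split.n_folds
        train_neg, test_neg = neg_split.split(neg, fold)
        model, profile = _train_fold(
            train_pos, train_neg, bagging, cnn,
            _stage_seeds(seed, 2, rep), k_range, pseudocount,
        )
        test = Dataset(test_pos.records + test_neg.records, name=f"logo_{gene}_{rep}")
        scores = model.predict_proba_matrix(featurize_dataset(test, profile))
        y_true = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
        reports.append(evaluate_scores(y_true, scores, threshold))
    return reports
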