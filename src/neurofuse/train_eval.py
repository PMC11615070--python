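"""Training protocol and evaluation: stratified 5-fold cross-validation,
Adam training with the reference hyper-parameters (lr 0.001, batch size 2,
weight decay 0.0001, 100 epochs at full scale), fold-averaged metrics, and
the paired-t/Bonferroni comparison across strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import CohortTable
from .metrics import ConfusionCounts, CurveReport, MetricReport, compute_metrics, roc_pr
from .models import (
    FusionModel, ModelConfig, build_model, predict_proba, reduced_model_config,
)
from .nn import Adam, SoftmaxCrossEntropy
from .stats import paired_ttest_bonferroni
from .synthetic import PairedDataset

logger = logging.getLogger("neurofuse")

METRIC_COLUMNS = ["acc", "f1", "sensitivity", "specificity", "mcc"]


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 2
    weight_decay: float = 0.0001
    epochs: int = 100
    folds: int = 5
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.lr < 0 or self.weight_decay < 0:
            raise ValueError("lr and weight_decay must be nonnegative")
        if self.batch_size <= 0 or self.epochs <= 0 or self.folds < 2:
            raise ValueError("batch_size/epochs must be positive, folds >= 2")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def reduced_train_config(seed: int = 0, epochs: int = 8) -> TrainConfig:
    """Desk-scale protocol used by the synthetic benchmarks."""
    return TrainConfig(epochs=epochs, batch_size=8, folds=5, seed=seed)


@dataclass
class FoldResult:
    fold_index: int
    metrics: MetricReport
    val_ids: list[str]
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


# -- cross-validation splits ------------------------------------------------

def _strata_of(records, stratify_by):
    return ["/".join(str(getattr(r, f)) for f in stratify_by) for r in records]


def kfold_split(table: CohortTable, k: int = 5, seed: int = 0,
                stratify_by: tuple[str, ...] = ("group",)):
    """Disjoint, exhaustive, stratified folds of subject ids.

    Per-stratum fold sizes differ by at most one; deterministic given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    strata = np.array(_strata_of(table.records, stratify_by))
    ids = np.array([r.id for r in table.records])
    values, counts = np.unique(strata, return_counts=True)
    small = values[counts < k]
    if small.size:
        raise ValueError(
            f"strata {list(small)} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (list(ids[tr]), list(ids[va]))
        for tr, va in skf.split(np.zeros(len(ids)), strata)
    ]


def _kfold_indices(labels, k, seed):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.size), labels))


# -- training ---------------------------------------------------------------

def train_model(model: FusionModel, dataset: PairedDataset, cfg: TrainConfig,
                indices=None) -> tuple[FusionModel, list[float]]:
    """Train in place for exactly ``cfg.epochs`` epochs; returns the model and
    the per-epoch mean loss trace. Deterministic given the seed."""
    if indices is None:
        indices = np.arange(len(dataset))
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    criterion = SoftmaxCrossEntropy()
    optimizer = Adam(model.parameters(), lr=cfg.lr,
                     weight_decay=cfg.weight_decay)
    model.train()
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(indices)
        losses = []
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            logits = model.forward(dataset.meg[batch], dataset.mri[batch])
            loss = criterion(logits, dataset.labels[batch])
            optimizer.zero_grad()
            model.backward(criterion.backward())
            optimizer.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        logger.info("epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, trace[-1])
    return model, trace


def evaluate_model(model: FusionModel, dataset: PairedDataset,
                   indices=None, batch_size: int = 8
                   ) -> tuple[MetricReport, np.ndarray, np.ndarray]:
    """Threshold metrics at argmax plus AUC/AP from the MCI-class score."""
    if indices is None:
        indices = np.arange(len(dataset))
    indices = np.asarray(indices)
    scores = np.empty(indices.size)
    for start in range(0, indices.size, batch_size):
        batch = indices[start:start + batch_size]
        probs = predict_proba(model, dataset.meg[batch], dataset.mri[batch])
        scores[start:start + batch.size] = probs[:, 1]
    labels = dataset.labels[indices]
    counts = ConfusionCounts.from_predictions(labels, (scores >= 0.5).astype(int))
    report = compute_metrics(counts)
    if labels.min() != labels.max():
        curves = roc_pr(scores, labels)
        report.auc, report.ap = curves.auc, curves.ap
    return report, scores, labels


def cross_validate(strategy: str, dataset: PairedDataset, train_cfg: TrainConfig,
                   model_cfg: ModelConfig | None = None) -> list[FoldResult]:
    """Stratified k-fold train/evaluate of one strategy."""
    if model_cfg is None:
        model_cfg = reduced_model_config(strategy, seed=train_cfg.seed)
    else:
        model_cfg = replace_strategy(model_cfg, strategy)
    results = []
    for fold, (tr, va) in enumerate(
            _kfold_indices(dataset.labels, train_cfg.folds, train_cfg.seed)):
        model = build_model(
            replace_seed(model_cfg, train_cfg.seed * 1000 + fold))
        fold_cfg = replace(train_cfg, seed=train_cfg.seed * 1000 + fold)
        train_model(model, dataset, fold_cfg, indices=tr)
        report, scores, labels = evaluate_model(model, dataset, va)
        results.append(FoldResult(
            fold_index=fold, metrics=report,
            val_ids=[dataset.ids[i] for i in va],
            scores=scores, labels=labels,
        ))
        logger.info("%s fold %d acc %.3f", strategy, fold, report.acc)
    return results


def replace_strategy(cfg: ModelConfig, strategy: str) -> ModelConfig:
    from dataclasses import replace as dc_replace
    return dc_replace(cfg, strategy=strategy)


def replace_seed(cfg: ModelConfig, seed: int) -> ModelConfig:
    from dataclasses import replace as dc_replace
    return dc_replace(cfg, seed=seed)


def mean_metrics(folds: list[FoldResult]) -> MetricReport:
    arr = {k: float(np.mean([f.metrics.as_dict()[k] for f in folds]))
           for k in folds[0].metrics.as_dict()}
    return MetricReport(**arr)


def pooled_curves(folds: list[FoldResult]) -> CurveReport:
    """ROC/PR over all validation scores pooled across folds."""
    scores = np.concatenate([f.scores for f in folds])
    labels = np.concatenate([f.labels for f in folds])
    return roc_pr(scores, labels)


@dataclass
class ExperimentReport:
    folds: dict[str, list[FoldResult]]
    table: pd.DataFrame

    def mean(self, strategy: str) -> MetricReport:
        return mean_metrics(self.folds[strategy])


def run_experiment(strategies: list[str], dataset: PairedDataset,
                   train_cfg: TrainConfig,
                   model_cfg: ModelConfig | None = None) -> ExperimentReport:
    """Train every strategy under identical folds and seeds; produce a
    fold-averaged comparison table with Bonferroni-adjusted paired-t p-values
    against the best strategy (by mean accuracy)."""
    folds: dict[str, list[FoldResult]] = {}
    for i, strategy in enumerate(strategies):
        folds[strategy] = cross_validate(strategy, dataset, train_cfg, model_cfg)
    accs = {s: [f.metrics.acc for f in fr] for s, fr in folds.items()}
    best = max(accs, key=lambda s: np.mean(accs[s]))
    m = max(1, len(set(strategies)) - 1)
    rows = []
    for strategy in strategies:
        mean = mean_metrics(folds[strategy])
        if strategy == best:
            p_adj = np.nan
        else:
            p_adj = paired_ttest_bonferroni(accs[best], accs[strategy], m=m).p_adjusted
        rows.append({"strategy": strategy,
                     **{k: getattr(mean, k) for k in METRIC_COLUMNS},
                     "auc": mean.auc, "ap": mean.ap,
                     "p_adjusted_vs_best": p_adj})
    return ExperimentReport(folds=folds, table=pd.DataFrame(rows))
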