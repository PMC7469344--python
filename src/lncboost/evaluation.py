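"""Metrics, ROC/AUC, validation protocols and per-disease candidate ranking.

The metric suite is accuracy, sensitivity, specificity, precision and the
Matthews correlation coefficient over thresholded scores, plus trapezoidal
ROC AUC (equal to the Mann-Whitney concordance probability with ties
counted 1/2). Protocols: stratified 8:2 hold-out, leave-one-out CV with
pooled scoring, stratified k-fold CV, a repeated-hold-out F1 t-test for
comparing two configurations, and the leave-one-disease-out candidate
ranking used for case studies.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from lncboost.config import RunConfig
from lncboost.feature_builder import LabeledPairSet, positive_pairs, sample_negative_pairs
from lncboost.pipeline import AssociationDataset, PairPipeline

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    acc: float
    sen: float
    spe: float
    pre: float
    mcc: float
    f1: float
    auc: float | None
    counts: ConfusionCounts
    protocol: str = ""
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counts"] = dataclasses.asdict(self.counts)
        return d


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class CvResult:
    fold_reports: list[MetricReport]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    means: dict[str, float]


def counts_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    pred = np.asarray(scores) >= threshold
    labels = np.asarray(labels).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def confusion_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """Exact metric formulas; degenerate margins give 0 with a flag, not an error."""
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    flags: list[str] = []
    acc = (tp + tn) / counts.total
    sen = tp / (tp + fn) if tp + fn else _flagged(flags, "sen undefined")
    spe = tn / (tn + fp) if tn + fp else _flagged(flags, "spe undefined")
    pre = tp / (tp + fp) if tp + fp else _flagged(flags, "pre undefined")
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    if denom == 0:
        mcc = _flagged(flags, "mcc undefined")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else _flagged(flags, "f1 undefined")
    return MetricReport(acc=acc, sen=sen, spe=spe, pre=pre, mcc=float(mcc), f1=f1,
                        auc=auc, counts=counts, flags=flags)


def _flagged(flags: list[str], msg: str) -> float:
    flags.append(msg)
    logger.info("confusion_metrics: %s, reported as 0", msg)
    return 0.0


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Trapezoidal ROC curve and AUC (both classes must be present)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for ROC")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores))
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def _report(scores, labels, threshold, protocol, seed=None) -> MetricReport:
    rep = confusion_metrics(counts_from_scores(scores, labels, threshold),
                            auc=roc_auc(scores, labels).auc)
    rep.protocol, rep.seed = protocol, seed
    return rep


# -- protocols -------------------------------------------------------------------

def holdout_eval(
    dataset: AssociationDataset, config: RunConfig, ratio: float = 0.8, seed: int = 0
) -> MetricReport:
    """Stratified random hold-out: fit on ``ratio``, score the rest at 0.5."""
    idx = np.arange(len(dataset.pairs))
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, random_state=seed,
        stratify=dataset.pairs.labels if config.evaluation.stratified else None,
    )
    pipe = PairPipeline(dataset, config).fit(dataset.pairs.subset(train_idx))
    test = dataset.pairs.subset(test_idx)
    return _report(pipe.score(test), test.labels, config.evaluation.threshold,
                   "holdout", seed)


def loocv_eval(dataset: AssociationDataset, config: RunConfig) -> MetricReport:
    """Leave-one-out CV; one held-out score per sample, metrics on the pool."""
    n = len(dataset.pairs)
    if n < 10:
        raise ValueError("leave-one-out needs at least 10 samples")
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        pipe = PairPipeline(dataset, config).fit(dataset.pairs.subset(idx[idx != i]))
        scores[i] = pipe.score(dataset.pairs.subset(np.array([i])))[0]
    return _report(scores, dataset.pairs.labels, config.evaluation.threshold, "loocv")


def kfold_eval(
    dataset: AssociationDataset, config: RunConfig, k: int = 10, seed: int = 0
) -> CvResult:
    """Stratified k-fold CV; per-fold reports plus their arithmetic means."""
    labels = dataset.pairs.labels
    if k > len(labels):
        raise ValueError("more folds than samples")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    pooled_scores = np.empty(len(labels))
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        pipe = PairPipeline(dataset, config).fit(dataset.pairs.subset(train_idx))
        test = dataset.pairs.subset(test_idx)
        scores = pipe.score(test)
        pooled_scores[test_idx] = scores
        rep = _report(scores, test.labels, config.evaluation.threshold, "kfold", seed)
        reports.append(rep)
        logger.info("fold %d: auc=%.4f acc=%.4f", fold, rep.auc, rep.acc)
    means = {
        m: float(np.mean([getattr(r, m) for r in reports]))
        for m in ("acc", "sen", "spe", "pre", "mcc", "f1", "auc")
    }
    return CvResult(fold_reports=reports, pooled_scores=pooled_scores,
                    pooled_labels=labels.copy(), means=means)


def repeated_f1_ttest(
    dataset: AssociationDataset,
    config_a: RunConfig,
    config_b: RunConfig,
    n_rep: int = 20,
    seed: int = 0,
) -> dict:
    """Repeated hold-out F1 comparison of two configurations.

    Both configurations see the same ``n_rep`` splits; reports mean +/- std
    of F1 per configuration and the two-sample t-test p-value. Zero-variance
    (identical) results are flagged with p = 1.
    """
    if n_rep < 5:
        logger.warning("repeated_f1_ttest: n_rep=%d gives low power", n_rep)
    f1a, f1b = [], []
    for r in range(n_rep):
        split_seed = seed + r
        f1a.append(holdout_eval(dataset, config_a, config_a.evaluation.holdout_ratio, split_seed).f1)
        f1b.append(holdout_eval(dataset, config_b, config_b.evaluation.holdout_ratio, split_seed).f1)
    f1a, f1b = np.array(f1a), np.array(f1b)
    flags = []
    if np.allclose(f1a, f1b) or (f1a.std() == 0 and f1b.std() == 0):
        p_value, t_stat = 1.0, 0.0
        if np.allclose(f1a, f1b):
            flags.append("identical results (zero variance)")
    else:
        t_stat, p_value = stats.ttest_ind(f1a, f1b)
    return {
        "f1_mean_a": float(f1a.mean()), "f1_std_a": float(f1a.std(ddof=1)) if n_rep > 1 else 0.0,
        "f1_mean_b": float(f1b.mean()), "f1_std_b": float(f1b.std(ddof=1)) if n_rep > 1 else 0.0,
        "t_stat": float(t_stat), "p_value": float(p_value),
        "n_rep": n_rep, "flags": flags,
    }


def rank_candidates(
    disease: str, dataset: AssociationDataset, config: RunConfig, seed: int = 0
) -> list[tuple[str, float]]:
    """Rank every lncRNA against a query disease, leave-disease-out.

    All known associations of the query disease are removed from training;
    the model is fit on the remaining positives plus sampled negatives
    (drawn outside the query row), then every (query, lncRNA) pair is scored
    and sorted descending (ties broken by lncRNA index).

    With the query's links removed its disease-side interaction profile is
    identically zero and carries no information, so the ranking model is
    trained on the lncRNA-side interaction block only (logged); the semantic
    and kernel similarity blocks are unaffected.
    """
    from lncboost.data_io import InteractionMatrix
    from lncboost.pipeline import AssociationDataset as ADS

    index = dataset.interaction.index
    if disease not in index.diseases:
        raise KeyError(f"unknown disease {disease!r}")
    d_i = index.disease_position(disease)
    if config.features.interaction_blocks == "both":
        logger.info("rank_candidates: query profile is empty after removal; "
                    "using the lncRNA-side interaction block only")
        config = dataclasses.replace(
            config, features=dataclasses.replace(config.features,
                                                 interaction_blocks="lncrna_col"))

    values = dataset.interaction.values.copy()
    values[d_i, :] = 0
    reduced = InteractionMatrix(values=values, index=index)
    pos = positive_pairs(reduced)
    query_row = {(d_i, j) for j in range(index.n_lncrnas)}
    neg = sample_negative_pairs(reduced, len(pos), seed=seed, exclude=query_row)
    train = LabeledPairSet(
        pairs=pos + neg.pairs,
        labels=np.concatenate([np.ones(len(pos), dtype=np.int8), neg.labels]),
    )
    reduced_ds = ADS(interaction=reduced, hierarchy=dataset.hierarchy, pairs=train,
                     _semantic_cache=dataset._semantic_cache)
    pipe = PairPipeline(reduced_ds, config).fit(train)
    candidates = LabeledPairSet(
        pairs=[(d_i, j) for j in range(index.n_lncrnas)],
        labels=np.zeros(index.n_lncrnas, dtype=np.int8),
    )
    scores = pipe.score(candidates)
    order = np.argsort(-scores, kind="stable")  # ties keep lncRNA index order
    return [(index.lncrnas[j], float(scores[j])) for j in order]
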