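"""Training protocol and evaluation metrics for both prediction tasks.

Training follows the heavy-imbalance recipe for residue-pair interaction
data: all positive pairs are kept and negatives are downsampled to a fixed
negatives-per-positive ratio (10 by default), re-drawn each epoch from a
seeded schedule.  Validation and test complexes are always scored at the
original class ratio.  The loss is binary cross-entropy, jointly over the
sampled residue pairs and the per-residue interface labels.

Evaluation reports per-complex AUROC (summarized by the median over
complexes, which is robust to very small or very large complexes), AUPRC
(both pooled over all pairs and as a per-complex median — the two are
labeled separately in the report), threshold precision/recall, and the
precision of the top-N highest-confidence pairs per complex.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._autograd import Adam, Tensor, concat
from .errors import PairsiteError, SamplingError
from .graph_features import PairLabels
from .model_core import ComplexSample, ModelConfig, PairInteractionModel

logger = logging.getLogger("pairsite")

__all__ = [
    "UndefinedMetricError",
    "MetricsReport",
    "TrainResult",
    "downsample_negatives",
    "bce_loss",
    "train",
    "auroc",
    "auprc",
    "precision_recall_at_threshold",
    "precision_at_top_n",
    "evaluate",
]

TOP_N_GRID = tuple(range(10, 101, 10))


class UndefinedMetricError(PairsiteError):
    """A ranking metric is undefined (single-class labels)."""


# ---------------------------------------------------------------------------
# sampling and loss


def downsample_negatives(labels: PairLabels, ratio: int, rng_seed: int) -> np.ndarray:
    """Indices (row-major into the flattened pair matrix) retained for training.

    All positives are kept; negatives are drawn uniformly without
    replacement, ``min(ratio × n_pos, n_neg)`` of them.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    flat = labels.matrix.ravel()
    pos = np.flatnonzero(flat == 1)
    neg = np.flatnonzero(flat == 0)
    if len(pos) == 0:
        raise SamplingError("no positive pairs; complex cannot be used for training")
    n_keep = min(ratio * len(pos), len(neg))
    rng = np.random.default_rng(rng_seed)
    kept_neg = rng.choice(neg, size=n_keep, replace=False)
    return np.sort(np.concatenate([pos, kept_neg]))


def bce_loss(probs, targets):
    """Mean binary cross-entropy over probabilities.

    Accepts a plain array (returns a float) or an autodiff Tensor (returns a
    Tensor on the tape).  Probabilities are clamped away from {0, 1} by an
    affine squeeze so the log stays finite.
    """
    t = np.asarray(targets, dtype=float)
    eps = 1e-12
    if isinstance(probs, Tensor):
        p = probs * (1.0 - 2 * eps) + eps
        per = -(Tensor(t) * p.log() + Tensor(1.0 - t) * (Tensor(1.0) - p).log())
        return per.mean()
    p = np.clip(np.asarray(probs, dtype=float), eps, 1.0 - eps)
    return float(np.mean(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    model: PairInteractionModel
    history: dict
    best_epoch: Optional[int] = None


def _complex_loss(model, sample: ComplexSample, pair_idx: np.ndarray,
                  config: ModelConfig, dropout_rng) -> Tensor:
    pair_probs, iface_l, iface_r, _ = model.forward_tensors(sample, dropout_rng)
    flat_labels = sample.pair_labels.matrix.ravel()
    loss = Tensor(0.0)
    if config.pairwise_loss_weight > 0:
        sel = pair_probs.gather_rows(pair_idx)
        loss = loss + bce_loss(sel, flat_labels[pair_idx]) * config.pairwise_loss_weight
    if config.interface_loss_weight > 0:
        iface = concat([iface_l, iface_r], axis=0)
        targets = np.concatenate([sample.interface_l, sample.interface_r])
        loss = loss + bce_loss(iface, targets) * config.interface_loss_weight
    return loss


def train(
    dataset: Sequence[ComplexSample],
    config: ModelConfig,
    val_dataset: Optional[Sequence[ComplexSample]] = None,
) -> TrainResult:
    """Seeded training loop with per-epoch negative re-sampling.

    When a validation set is given, the parameters from the epoch with the
    best validation median pairwise AUROC are restored at the end.
    """
    if not dataset:
        raise ValueError("empty training set")
    usable = []
    for s in dataset:
        if s.pair_labels.n_positive == 0:
            warnings.warn(f"complex {s.complex_id} has no positive pairs; skipped")
            continue
        usable.append(s)
    if not usable:
        raise SamplingError("no training complex has positive pairs")

    model = PairInteractionModel(config)
    optimizer = Adam(model.params(), lr=config.lr)
    history = {"epoch_loss": [], "val_median_auroc": []}
    best_score, best_epoch, best_params = -np.inf, None, None

    fixed_idx: dict[str, np.ndarray] = {}
    for epoch in range(config.epochs):
        order_rng = np.random.default_rng([config.seed, 101, epoch])
        order = order_rng.permutation(len(usable))
        epoch_loss = 0.0
        for pos_in_epoch, si in enumerate(order):
            sample = usable[si]
            if config.resample_each_epoch or sample.complex_id not in fixed_idx:
                idx = downsample_negatives(
                    sample.pair_labels, config.neg_ratio,
                    rng_seed=abs(hash((config.seed, epoch, sample.complex_id))) % (2**31),
                )
                if not config.resample_each_epoch:
                    fixed_idx[sample.complex_id] = idx
            else:
                idx = fixed_idx[sample.complex_id]
            dropout_rng = (np.random.default_rng([config.seed, 202, epoch, int(si)])
                           if config.dropout > 0 else None)
            loss = _complex_loss(model, sample, idx, config, dropout_rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, complex {sample.complex_id}: "
                    f"loss={loss.data!r}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
        epoch_loss /= len(usable)
        history["epoch_loss"].append(epoch_loss)

        if val_dataset:
            report = evaluate(model, val_dataset, task="pairwise")
            score = report.median_auroc if report.median_auroc is not None else -np.inf
            history["val_median_auroc"].append(score)
            if score > best_score:
                best_score, best_epoch = score, epoch
                best_params = [p.data.copy() for p in model.params()]
            logger.info("epoch %d: loss=%.4f val_median_auroc=%.4f", epoch, epoch_loss, score)
        else:
            logger.info("epoch %d: loss=%.4f", epoch, epoch_loss)

    if best_params is not None:
        for p, data in zip(model.params(), best_params):
            p.data = data
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# metrics


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int).ravel()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (ties get half credit).

    Equivalent to the Mann–Whitney U statistic normalized by n_pos × n_neg.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under the precision–recall curve (step-wise, no interpolation)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined: no positive labels")
    if labels.sum() == labels.size:
        return 1.0
    return float(average_precision_score(labels, scores))


def precision_recall_at_threshold(scores, labels, threshold: float):
    """Confusion-matrix precision/recall at ``score >= threshold``.

    Precision is ``None`` (flagged undefined) when nothing is predicted
    positive, never silently 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float).ravel()
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return precision, recall


def precision_at_top_n(pair_scores: np.ndarray, labels: PairLabels, n: int) -> float:
    """Fraction of the n highest-scoring residue pairs that truly interact.

    Boundary ties are broken by row-major index order (stable sort).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    scores = np.asarray(pair_scores, dtype=float).ravel()
    truth = labels.matrix.ravel()
    if scores.shape != truth.shape:
        raise ValueError("score matrix and label matrix shapes differ")
    if n > scores.size:
        warnings.warn(f"top-N {n} exceeds {scores.size} pairs; truncated")
        n = scores.size
    top = np.argsort(-scores, kind="stable")[:n]
    return float(truth[top].mean())


# ---------------------------------------------------------------------------
# evaluation over a dataset


@dataclass
class MetricsReport:
    """Per-task metrics over a set of complexes at the original class ratio."""

    task: str
    n_complexes: int
    n_excluded: int
    per_complex_auroc: list = field(default_factory=list)
    median_auroc: Optional[float] = None
    per_complex_auprc: list = field(default_factory=list)
    median_auprc: Optional[float] = None
    auprc_aggregate: Optional[float] = None
    precision: Optional[float] = None     # at threshold 0.5
    recall: Optional[float] = None
    precision_at_n: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _task_scores(model: PairInteractionModel, sample: ComplexSample, task: str):
    result = model.predict(sample)
    if task == "pairwise":
        return result.pair_probs.ravel(), sample.pair_labels.matrix.ravel(), result
    if task == "interface":
        scores = np.concatenate([result.interface_probs_l, result.interface_probs_r])
        labels = np.concatenate([sample.interface_l, sample.interface_r])
        return scores, labels, result
    raise ValueError(f"unknown task {task!r}")


def evaluate(
    model: PairInteractionModel,
    dataset: Sequence[ComplexSample],
    task: str = "pairwise",
    threshold: float = 0.5,
    top_n_grid: Sequence[int] = TOP_N_GRID,
) -> MetricsReport:
    """Score every complex at the original class ratio and aggregate.

    Complexes whose labels contain a single class are excluded from the
    per-complex metric lists and counted in ``n_excluded``.
    """
    report = MetricsReport(task=task, n_complexes=len(dataset), n_excluded=0)
    all_scores, all_labels = [], []
    topn_acc: dict[int, list] = {n: [] for n in top_n_grid}
    for sample in dataset:
        scores, labels, result = _task_scores(model, sample, task)
        all_scores.append(scores)
        all_labels.append(labels)
        try:
            report.per_complex_auroc.append(auroc(scores, labels))
            report.per_complex_auprc.append(auprc(scores, labels))
        except UndefinedMetricError:
            report.n_excluded += 1
            continue
        if task == "pairwise":
            for n in top_n_grid:
                if n <= scores.size:
                    topn_acc[n].append(
                        precision_at_top_n(result.pair_probs, sample.pair_labels, n)
                    )
    if report.per_complex_auroc:
        report.median_auroc = float(np.median(report.per_complex_auroc))
        report.median_auprc = float(np.median(report.per_complex_auprc))
    pooled_scores = np.concatenate(all_scores)
    pooled_labels = np.concatenate(all_labels)
    if pooled_labels.sum() > 0:
        report.auprc_aggregate = auprc(pooled_scores, pooled_labels)
    report.precision, report.recall = precision_recall_at_threshold(
        pooled_scores, pooled_labels, threshold
    )
    if task == "pairwise":
        report.precision_at_n = {
            int(n): float(np.mean(v)) for n, v in topn_acc.items() if v
        }
    return report
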