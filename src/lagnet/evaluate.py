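"""ROC/AUC for ranked directed edges and precision/recall/F1.

Edges are ranked by the penalty level at which they enter the model along a
descending lambda path (larger entry value = earlier = stronger evidence);
pairs that never enter share a single bottom rank.  The AUC is the
Mann-Whitney probability that a randomly chosen true edge outranks a randomly
chosen non-edge, with ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class UndefinedAUCError(ValueError):
    """Raised when the positive or negative class is empty."""


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    include_self: bool = False

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


@dataclass(frozen=True)
class PRFResult:
    precision: float
    recall: float
    f1: float
    degenerate: str | None = None


def candidate_pairs(n_genes, include_self=False, restrict_to=None):
    """All ordered gene pairs (self-pairs per flag), optionally intersected
    with an explicit candidate collection."""
    pairs = [
        (j, i)
        for j in range(n_genes)
        for i in range(n_genes)
        if include_self or j != i
    ]
    if restrict_to is not None:
        allowed = set(restrict_to)
        pairs = [p for p in pairs if p in allowed]
    return pairs


def auc_from_scores(scores, truth_edges, n_genes, include_self=False,
                    candidates=None):
    """Mann-Whitney ROC for a pair -> score mapping.

    ``candidates`` defaults to all ordered cross-gene pairs; pairs missing
    from ``scores`` are placed at the bottom (tied at -inf).  Truth edges
    outside the candidate set are ignored (e.g. self-loops when self-pairs
    are excluded).
    """
    pairs = candidate_pairs(n_genes, include_self, candidates)
    truth = set(truth_edges) & set(pairs)
    if not truth:
        raise UndefinedAUCError("no true edges among the candidate pairs")
    if len(truth) == len(pairs):
        raise UndefinedAUCError("every candidate pair is a true edge")
    pairs = sorted(pairs)  # deterministic curve under ties
    vals = np.array(
        [scores.get(p, -np.inf) for p in pairs], dtype=float
    )
    labels = np.array([p in truth for p in pairs])
    n_pos = int(labels.sum())
    n_neg = len(pairs) - n_pos
    ranks = rankdata(vals, method="average")  # average rank = half tie credit
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # stepwise ROC coordinates, one step per distinct score level
    order = np.argsort(-vals, kind="stable")
    sorted_vals = vals[order]
    sorted_pos = labels[order].astype(float)
    distinct = np.flatnonzero(
        np.r_[sorted_vals[1:] != sorted_vals[:-1], True]
    )  # last index of each tie block (robust to -inf ties)
    tp = np.cumsum(sorted_pos)[distinct]
    fp = (distinct + 1) - tp
    thresholds = sorted_vals[distinct]
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(auc),
        include_self=include_self,
    )


def auc_from_entries(path, truth, include_self=False, candidates=None):
    """ROC of a regularization path's entry values against a truth network.

    Entry value = largest lambda at which an edge is active along the merged
    path; never-entering pairs share the bottom rank.
    """
    if tuple(truth.gene_names) != tuple(path.gene_names):
        raise ValueError("path and truth networks name different genes")
    scores = {
        pair: val for pair, val in path.entry_value.items() if val is not None
    }
    if candidates is None:
        candidates = list(path.entry_value.keys())
    return auc_from_scores(
        scores,
        truth.edges,
        len(path.gene_names),
        include_self=include_self,
        candidates=candidates,
    )


def precision_recall_f1(predicted, truth):
    """Precision, recall and F1 of a predicted edge set against the truth.

    Degenerate cases (no predicted edges, empty truth) are returned with a
    flag rather than raising; an empty prediction has precision 1 by
    convention.
    """
    if tuple(predicted.gene_names) != tuple(truth.gene_names):
        raise ValueError("networks name different genes")
    pred, true = set(predicted.edges), set(truth.edges)
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    degenerate = None
    if not pred:
        precision = 1.0
        degenerate = "no-predicted-edges"
    else:
        precision = tp / (tp + fp)
    if not true:
        recall = 0.0
        degenerate = "empty-truth"
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return PRFResult(precision, recall, f1, degenerate)
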