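"""Clustering evaluation against ground-truth cell-type labels.

ACC is accuracy under the optimal one-to-one cluster-to-class matching
(Hungarian algorithm); precision/recall/F1 are macro-averaged over true
classes after applying that matching; NMI uses arithmetic-mean
normalization; ARI is the adjusted-for-chance Rand index; the silhouette
score (S-score) evaluates the predicted partition in the embedding with
Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    precision_recall_fscore_support,
    silhouette_score,
)


@dataclass
class EvaluationReport:
    acc: float
    nmi: float
    f1: float
    precision: float
    recall: float
    ari: float
    s_score: float | None
    mapping: dict[int, int]
    s_score_error: str | None = None

    def to_dict(self) -> dict:
        out = {
            "acc": self.acc,
            "nmi": self.nmi,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "ari": self.ari,
            "s_score": self.s_score,
            "mapping": {int(k): int(v) for k, v in self.mapping.items()},
        }
        if self.s_score_error:
            out["s_score_error"] = self.s_score_error
        return out


def _encode(labels) -> np.ndarray:
    _, enc = np.unique(np.asarray(labels), return_inverse=True)
    return enc


def hungarian_accuracy(pred, truth) -> tuple[float, dict[int, int]]:
    """Clustering accuracy under the optimal one-to-one label matching.

    Builds the contingency table between predicted and true labels and finds
    the assignment maximizing the total matched count (rectangular tables
    allowed); returns the matched proportion and the predicted-to-true
    mapping.
    """
    pred = _encode(pred)
    truth = _encode(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors differ in length")
    if pred.size == 0:
        raise ValueError("need at least one cell")
    kp, kt = pred.max() + 1, truth.max() + 1
    cont = np.zeros((kp, kt), dtype=int)
    np.add.at(cont, (pred, truth), 1)
    rows, cols = linear_sum_assignment(-cont)
    acc = cont[rows, cols].sum() / pred.size
    return float(acc), dict(zip(rows.tolist(), cols.tolist()))


def compute_report(pred, truth, embedding: np.ndarray | None = None) -> EvaluationReport:
    """Full evaluation report for a predicted partition.

    ``embedding`` is the m x n representation (cells in columns) used only
    for the silhouette score; when the prediction has a single cluster the
    silhouette is undefined and reported as an error flag instead of a
    number.
    """
    pred = _encode(pred)
    truth = _encode(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors differ in length")
    acc, mapping = hungarian_accuracy(pred, truth)
    nmi = float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))
    ari = float(adjusted_rand_score(truth, pred))

    # map predicted ids onto true ids; unmatched predicted clusters get fresh
    # ids beyond the true range so they count as errors for every true class
    n_true = truth.max() + 1
    mapped = np.empty_like(pred)
    next_free = n_true
    full_map = dict(mapping)
    for p in np.unique(pred):
        if p not in full_map:
            full_map[int(p)] = next_free
            next_free += 1
    for p, t in full_map.items():
        mapped[pred == p] = t
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, mapped, labels=np.arange(n_true), average="macro", zero_division=0
    )

    s_score: float | None = None
    s_err: str | None = None
    if embedding is not None:
        if len(np.unique(pred)) < 2:
            s_err = "silhouette undefined for a single predicted cluster"
        else:
            s_score = float(
                silhouette_score(np.asarray(embedding).T, pred, metric="euclidean")
            )
    return EvaluationReport(
        acc=acc,
        nmi=nmi,
        f1=float(f1),
        precision=float(prec),
        recall=float(rec),
        ari=ari,
        s_score=s_score,
        mapping=mapping,
        s_score_error=s_err,
    )
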