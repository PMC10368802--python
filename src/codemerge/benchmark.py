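"""Evaluation: membership classification metrics, pair ROC/AUROC, and the
cell-abundance bias diagnostic.

A cell is predicted to belong to a cluster when its enrichment score for
that cluster is positive. Cluster-pair discrimination is evaluated by
sweeping the significance cutoff over a geometric grid {0} u {2^-c,
c = 0..100}, calling a pair significant when min(p_i, p_j) falls below the
cutoff, and integrating the ROC curve against ground-truth pair labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)

from .data_model import ClusterPartition, ScoreMatrix
from .merge import PairTestResult

_P_FLOOR = 1e-300


@dataclass
class RocResult:
    cutoffs: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    n_pairs: int


@dataclass
class AbundanceBias:
    rho: float
    defined: bool


def membership_metrics(scores: ScoreMatrix, truth: ClusterPartition
                       ) -> pd.DataFrame:
    """Binary classification of cluster membership from positive scores.

    Per cluster: predicted members = cells with score > 0 in that column;
    accuracy / precision / recall / F1 against true membership, plus an
    unweighted mean row ("mean"). Precision and F1 are 0 by convention when
    nothing is predicted positive.
    """
    missing = [c for c in truth.clusters if c not in set(scores.cluster_ids)]
    if missing:
        raise ValueError(f"clusters absent from scores: {missing}")
    rows = {}
    for cluster in truth.clusters:
        y_true = (truth.labels == cluster).astype(int)
        y_pred = (scores.column(cluster) > 0).astype(int)
        rows[cluster] = {
            "accuracy": accuracy_score(y_true, y_pred),
            "precision": precision_score(y_true, y_pred, zero_division=0),
            "recall": recall_score(y_true, y_pred, zero_division=0),
            "f1": f1_score(y_true, y_pred, zero_division=0),
        }
    df = pd.DataFrame(rows).T
    df.loc["mean"] = df.mean()
    df.index.name = "cluster"
    return df


def cutoff_grid() -> np.ndarray:
    """{0} united with {2^-c : c = 0..100}, sorted ascending (length 102)."""
    return np.unique(np.concatenate(([0.0], 2.0 ** -np.arange(101))))


def _min_p(r: PairTestResult) -> float:
    return min(r.p_i, r.p_j)


def pair_roc(results: list[PairTestResult],
             truth: dict[tuple[str, str], bool],
             cutoffs: np.ndarray | None = None) -> RocResult:
    """ROC over the significance-cutoff sweep, AUROC by trapezoid.

    The pair statistic is min(p_i, p_j) — the continuous analogue of the
    either-direction significance call; a pair is predicted significant at a
    cutoff when its statistic is strictly below it. (0,0) and (1,1) anchors
    are appended before integration.
    """
    if cutoffs is None:
        cutoffs = cutoff_grid()
    stat, y = [], []
    for r in results:
        key = tuple(sorted((r.cluster_i, r.cluster_j)))
        if key not in truth:
            raise ValueError(f"no truth label for pair {key}")
        stat.append(_min_p(r))
        y.append(bool(truth[key]))
    stat = np.asarray(stat)
    y = np.asarray(y)
    pos, neg = int(y.sum()), int((~y).sum())
    if pos == 0 or neg == 0:
        raise ValueError("truth labels contain only one class; "
                         "AUROC undefined")
    tpr = np.array([(stat[y] < c).mean() for c in cutoffs])
    fpr = np.array([(stat[~y] < c).mean() for c in cutoffs])
    f = np.concatenate(([0.0], fpr, [1.0]))
    t = np.concatenate(([0.0], tpr, [1.0]))
    order = np.lexsort((t, f))
    auroc = float(np.trapezoid(t[order], f[order]))
    return RocResult(np.asarray(cutoffs), fpr, tpr, auroc, len(results))


def abundance_bias(results: list[PairTestResult]) -> AbundanceBias:
    """Spearman correlation of -log10(min p) with log2(pair cell count).

    A positive correlation means bigger cluster pairs get smaller p-values —
    the pseudoreplication signature that score summarization is meant to
    remove. Undefined (constant input) correlations are reported as 0 with
    ``defined=False``.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 pairs")
    neglogp = np.array([-np.log10(max(_min_p(r), _P_FLOOR))
                        for r in results])
    size = np.array([np.log2(r.n_i + r.n_j) for r in results])
    if np.all(neglogp == neglogp[0]) or np.all(size == size[0]):
        return AbundanceBias(0.0, False)
    rho = stats.spearmanr(neglogp, size).statistic
    return AbundanceBias(float(rho), True)
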