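"""Negative gene set construction and per-cell enrichment scoring.

The code-score for cell kappa and cluster i is

    log2( H(kappa, G_i) / P(kappa, G_i) )

where H is the number of cluster-i marker genes expressed in the cell and P
is the empirical joint probability, across all cells, of expressing every
marker at or above the level observed in this cell. The score is zeroed
unless H reaches the winsorized minimum intersection count f(|G_i|) and the
cell co-expresses none of cluster i's *negative* gene sets — the genes that
distinguish any other cluster whose marker set heavily overlaps G_i. The
coexpr-score drops the negative-set condition; an additive control scorer
(mean marker expression minus the matrix-wide marker mean) is provided to
exhibit the cross-scoring failure mode that code-scoring is designed to
suppress, with ``additive_neg`` applying the same negative-set masking to
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    EXPRESSION_THRESHOLD,
    ClusterPartition,
    ExpressionMatrix,
    ScoreMatrix,
)
from .markers import MarkerGeneSets

_METHODS = ("code", "coexpr", "additive", "additive_neg")
_NEG_RULES = ("winsorized_ge", "strict_gt")


@dataclass
class ScoreConfig:
    """Scoring parameters.

    method : "code" (default), "coexpr", "additive", or "additive_neg".
    negative_rule : how a negative set counts as co-expressed —
        "strict_gt" (default; expressed count strictly > f(|N|), so sets of
        size <= 2 never trigger and larger sets must be fully co-expressed)
        or "winsorized_ge" (expressed count >= f(|N|)). The strict rule is
        deliberately conservative: small set differences between
        nearly identical marker sets (e.g. sub-clusters of one population
        that pick a different fifth marker) would otherwise veto the very
        cells the cluster is made of.
    """

    method: str = "code"
    negative_rule: str = "strict_gt"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.negative_rule not in _NEG_RULES:
            raise ValueError(f"negative_rule must be one of {_NEG_RULES}")


def min_intersection(set_size: int) -> int:
    """Winsorized minimum intersection count f: |S| if |S| <= 2 else |S|-1."""
    if set_size < 0:
        raise ValueError("set size must be non-negative")
    return set_size if set_size <= 2 else set_size - 1


def negative_gene_sets(markers: MarkerGeneSets) -> dict[str, list[frozenset]]:
    """Negative gene sets N_i = {G_j - G_i : |G_j ∩ G_i| >= f(|G_i|), j != i}.

    Full overlap (G_j ⊆ G_i) contributes nothing since the difference is
    empty. Identical difference sets arising from different j are stored
    once.
    """
    for c, genes in markers.sets.items():
        if not genes:
            raise ValueError(f"cluster {c!r} has an empty marker set")
    out: dict[str, list[frozenset]] = {}
    clusters = markers.clusters
    for i in clusters:
        gi = set(markers[i])
        thresh = min_intersection(len(gi))
        negs: list[frozenset] = []
        for j in clusters:
            if j == i:
                continue
            gj = set(markers[j])
            if len(gj & gi) >= thresh:
                diff = frozenset(gj - gi)
                if diff and diff not in negs:
                    negs.append(diff)
        out[i] = negs
    return out


def expressed_count(expr: ExpressionMatrix, cell: int, genes) -> int:
    """Number of the given genes expressed (value > 0) in one cell."""
    genes = list(genes)
    if not genes:
        return 0
    row = expr.columns(genes)[cell]
    return int(np.sum(row > EXPRESSION_THRESHOLD))


def negative_hits(expr: ExpressionMatrix, cell: int, negsets,
                  rule: str = "strict_gt") -> int:
    """Number of negative gene sets co-expressed by one cell.

    Under ``strict_gt`` (the default) a set counts only when its expressed
    count strictly exceeds f(|N|); under ``winsorized_ge`` reaching f(|N|)
    suffices.
    """
    if rule not in _NEG_RULES:
        raise ValueError(f"rule must be one of {_NEG_RULES}")
    hits = 0
    for ns in negsets:
        ns = list(ns)
        h = expressed_count(expr, cell, ns)
        f = min_intersection(len(ns))
        if (h >= f) if rule == "winsorized_ge" else (h > f):
            hits += 1
    return hits


def joint_coexpr_prob(expr: ExpressionMatrix, cell: int, genes) -> float:
    """Empirical probability of co-expressing genes at the cell's levels.

    Product over genes of (# cells with expression >= this cell's value)/T.
    The cell itself always counts, so each factor is in [1/T, 1].
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene set must be non-empty")
    cols = expr.columns(genes)
    t = expr.n_cells
    p = 1.0
    for k in range(cols.shape[1]):
        p *= np.sum(cols[:, k] >= cols[cell, k]) / t
    return float(p)


def _counts_ge(col: np.ndarray) -> np.ndarray:
    """For each entry, the number of entries >= it (vectorized via sort)."""
    order = np.sort(col)
    # index of first element not less than col[k] = count of elements < col[k]
    less = np.searchsorted(order, col, side="left")
    return col.size - less


def _negative_mask(expr: ExpressionMatrix, negsets, rule: str) -> np.ndarray:
    """Boolean mask of cells co-expressing at least one negative set."""
    mask = np.zeros(expr.n_cells, dtype=bool)
    for ns in negsets:
        ns = list(ns)
        h = np.sum(expr.columns(ns) > EXPRESSION_THRESHOLD, axis=1)
        f = min_intersection(len(ns))
        mask |= (h >= f) if rule == "winsorized_ge" else (h > f)
    return mask


def score_matrix(expr: ExpressionMatrix, partition: ClusterPartition,
                 markers: MarkerGeneSets,
                 config: ScoreConfig | None = None) -> ScoreMatrix:
    """Score every cell for every cluster's marker gene combination."""
    config = config or ScoreConfig()
    clusters = partition.clusters
    missing = [c for c in clusters if c not in markers]
    if missing:
        raise ValueError(f"clusters missing from markers: {missing}")

    t = expr.n_cells
    values = np.zeros((t, len(clusters)))
    negs = (negative_gene_sets(markers)
            if config.method in ("code", "additive_neg") else None)

    for col, cluster in enumerate(clusters):
        genes = markers[cluster]
        sub = expr.columns(genes)

        if config.method in ("additive", "additive_neg"):
            score = sub.mean(axis=1) - float(sub.mean())
        else:
            h = np.sum(sub > EXPRESSION_THRESHOLD, axis=1)
            prob = np.ones(t)
            for k in range(sub.shape[1]):
                prob *= _counts_ge(sub[:, k]) / t
            keep = h >= min_intersection(len(genes))
            score = np.zeros(t)
            with np.errstate(divide="ignore"):
                score[keep] = np.log2(h[keep] / prob[keep])

        if config.method in ("code", "additive_neg") and negs[cluster]:
            score[_negative_mask(expr, negs[cluster],
                                 config.negative_rule)] = 0.0
        values[:, col] = score

    return ScoreMatrix(values, expr.cell_ids, np.asarray(clusters,
                                                         dtype=object),
                       method=config.method)


def diagnostic_order(scores: ScoreMatrix, partition: ClusterPartition
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Row/column orderings placing own-cluster scores on the diagonal.

    Returns (cell_order, cluster_order): cells grouped by cluster in the
    score matrix's cluster order, clusters ordered identically on both axes,
    so that a heatmap of ``scores.values[cell_order][:, cluster_order]``
    shows per-cluster blocks down the diagonal.
    """
    if scores.values.shape[0] != partition.n_cells:
        raise ValueError("scores and partition are not aligned")
    cluster_order = np.arange(len(scores.cluster_ids))
    cell_order = np.concatenate([
        np.flatnonzero(partition.labels == c) for c in scores.cluster_ids
    ]).astype(int)
    return cell_order, cluster_order
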