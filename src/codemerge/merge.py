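"""The cluster-merge test: summarization, pair testing, merging, iteration.

For a cluster pair (i, j) the four score vectors

    Omega_{i~i}, Omega_{j~i}  (column i, cells of i and of j)
    Omega_{i~j}, Omega_{j~j}  (column j)

are each summarized to k values (default: 15 evenly spaced quantiles) and
compared with two-sided Welch t-tests: p_i tests column i between the two
cell groups, p_j column j. After Benjamini-Hochberg adjustment across all
tested pairs, a pair is significantly different when either adjusted p-value
falls below p_cut; mutually non-significant pairs are merged (transitively,
via connected components). Summarization curbs the pseudoreplication that
makes per-cell tests both anti-conservative and correlated with cluster
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .data_model import ClusterPartition, ExpressionMatrix, ScoreMatrix
from .markers import MarkerConfig, MarkerGeneSets, bh_adjust, select_markers
from .scoring import ScoreConfig, score_matrix

_SUMMARIZATIONS = ("k_quantiles", "k_bins", "k_means", "none")
_PAIR_SELECTIONS = ("all_pairs", "mnn")


@dataclass
class MergeConfig:
    """Cluster-merge parameters.

    p_cut : significance threshold on (adjusted) p-values (default 0.01).
    summarization : "k_quantiles" (default), "k_bins", "k_means", or "none"
        for unsummarized per-cell testing.
    k : number of summary values per score vector (default 15).
    pair_selection : "all_pairs" (default) or "mnn" (mutual nearest
        neighbours on the cluster profile matrix, for many clusters).
    mnn_neighbours : neighbourhood size for MNN pair selection (default 4).
    max_iterations : merge rounds to run (default 1).
    run_to_convergence : iterate until the partition stops changing.
    adjust : BH-adjust all pair p-values jointly before thresholding
        (default True).
    """

    p_cut: float = 0.01
    summarization: str = "k_quantiles"
    k: int = 15
    pair_selection: str = "all_pairs"
    mnn_neighbours: int = 4
    max_iterations: int = 1
    run_to_convergence: bool = False
    adjust: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p_cut < 1):
            raise ValueError("p_cut must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.mnn_neighbours < 1:
            raise ValueError("mnn_neighbours must be >= 1")
        if self.summarization not in _SUMMARIZATIONS:
            raise ValueError(f"summarization must be one of {_SUMMARIZATIONS}")
        if self.pair_selection not in _PAIR_SELECTIONS:
            raise ValueError(f"pair_selection must be one of {_PAIR_SELECTIONS}")


@dataclass
class PairTestResult:
    """Bi-directional test outcome for one unordered cluster pair."""

    cluster_i: str
    cluster_j: str
    p_i: float
    p_j: float
    n_i: int
    n_j: int
    padj_i: float | None = None
    padj_j: float | None = None
    significant: bool | None = None


def pair_table(results: list[PairTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.cluster_i, r.cluster_j, r.p_i, r.p_j, r.padj_i, r.padj_j,
          r.significant, r.n_i, r.n_j) for r in results],
        columns=["cluster_i", "cluster_j", "p_i", "p_j", "padj_i", "padj_j",
                 "significant", "n_i", "n_j"],
    )


@dataclass
class MergeResult:
    """Output of run_cluster_merge."""

    final_partition: ClusterPartition
    iterations: int
    pair_tables: list[list[PairTestResult]]
    final_scores: ScoreMatrix
    final_markers: MarkerGeneSets
    merge_map: dict[str, str]
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Summarization


def summarize_scores(values: np.ndarray, method: str = "k_quantiles",
                     k: int = 15) -> np.ndarray:
    """Summarize a score vector to at most k values.

    k_quantiles : quantiles at probabilities 0, 1/(k-1), ..., 1 (linear
        interpolation; always contains min and max).
    k_bins : means within k equal-probability bins; empty bins are dropped.
    k_means : 1-D k-means centroids, deterministically seeded from the
        k_quantiles summary; if there are fewer than k distinct values those
        are returned as-is.
    none : the input unchanged.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot summarize an empty score vector")
    if method == "none":
        return v.copy()
    if method == "k_quantiles":
        return np.quantile(v, np.linspace(0, 1, k))
    if method == "k_bins":
        edges = np.quantile(v, np.linspace(0, 1, k + 1))
        idx = np.searchsorted(edges[1:-1], v, side="right")
        return np.array([v[idx == b].mean() for b in range(k)
                         if np.any(idx == b)])
    if method == "k_means":
        distinct = np.unique(v)
        if distinct.size <= k:
            return distinct
        from sklearn.cluster import KMeans

        init = np.quantile(v, np.linspace(0, 1, k)).reshape(-1, 1)
        km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300)
        km.fit(v.reshape(-1, 1))
        return np.sort(km.cluster_centers_.ravel())
    raise ValueError(f"unknown summarization method: {method!r}")


# ---------------------------------------------------------------------------
# Pair selection


def cluster_profiles(scores: ScoreMatrix, partition: ClusterPartition
                     ) -> pd.DataFrame:
    """|C| x |C| matrix: entry (i, j) = mean cluster-j score in cluster i."""
    clusters = list(scores.cluster_ids)
    missing = [c for c in partition.clusters if c not in clusters]
    if missing:
        raise ValueError(f"clusters missing from scores: {missing}")
    rows = np.stack([
        scores.values[partition.labels == c].mean(axis=0) for c in clusters
    ])
    return pd.DataFrame(rows, index=clusters, columns=clusters)


def mnn_pairs(profiles: pd.DataFrame, neighbours: int = 4
              ) -> set[tuple[str, str]]:
    """Mutual nearest-neighbour cluster pairs by Euclidean profile distance."""
    clusters = list(profiles.index)
    n = len(clusters)
    if n < 2:
        raise ValueError("need at least 2 clusters")
    if neighbours >= n:
        warnings.warn(f"neighbours={neighbours} >= |C|={n}; clamped to {n - 1}")
        neighbours = n - 1
    dist = cdist(profiles.to_numpy(), profiles.to_numpy())
    np.fill_diagonal(dist, np.inf)
    nearest = [set(np.argsort(dist[i], kind="stable")[:neighbours])
               for i in range(n)]
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            if j in nearest[i] and i in nearest[j]:
                pairs.add((clusters[i], clusters[j]))
    return pairs


def _all_pairs(clusters: list[str]) -> set[tuple[str, str]]:
    return {(clusters[i], clusters[j])
            for i in range(len(clusters)) for j in range(i + 1, len(clusters))}


# ---------------------------------------------------------------------------
# Testing


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch p-value with explicit zero-variance handling."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def test_pair(scores: ScoreMatrix, partition: ClusterPartition, i: str,
              j: str, config: MergeConfig | None = None) -> PairTestResult:
    """Bi-directional Welch test of clusters i and j on summarized scores.

    Raw p-values only; adjusted p-values and the significance call are
    filled in by :func:`call_significance`.
    """
    config = config or MergeConfig()
    if i == j:
        raise ValueError("cannot test a cluster against itself")
    cells_i = partition.labels == i
    cells_j = partition.labels == j
    n_i, n_j = int(cells_i.sum()), int(cells_j.sum())
    if n_i == 0 or n_j == 0:
        raise ValueError(f"empty cluster in pair ({i!r}, {j!r})")

    def summ(cells: np.ndarray, col: str) -> np.ndarray:
        s = summarize_scores(scores.column(col)[cells],
                             config.summarization, config.k)
        if s.size < 2:
            raise ValueError(
                f"summarized scores for cluster pair ({i!r}, {j!r}) on "
                f"column {col!r} have fewer than 2 values"
            )
        return s

    p_i = _welch_p(summ(cells_i, i), summ(cells_j, i))
    p_j = _welch_p(summ(cells_i, j), summ(cells_j, j))
    return PairTestResult(i, j, p_i, p_j, n_i, n_j)


def call_significance(results: list[PairTestResult],
                      config: MergeConfig | None = None
                      ) -> list[PairTestResult]:
    """Fill adjusted p-values and significance calls.

    All 2 x |pairs| raw p-values form one BH family; a pair is significant
    when either adjusted p-value is below p_cut (raw when adjust=False).
    """
    config = config or MergeConfig()
    if not results:
        raise ValueError("no pair results to adjust")
    raw = np.array([[r.p_i, r.p_j] for r in results]).ravel()
    adj = bh_adjust(raw) if config.adjust else raw
    out = []
    for idx, r in enumerate(results):
        padj_i, padj_j = float(adj[2 * idx]), float(adj[2 * idx + 1])
        out.append(replace(r, padj_i=padj_i, padj_j=padj_j,
                           significant=bool(padj_i < config.p_cut
                                            or padj_j < config.p_cut)))
    return out


# ---------------------------------------------------------------------------
# Merging


def _component_label(members: list[str], sizes: dict[str, int]) -> tuple:
    total = sum(sizes[m] for m in members)
    return (-total, min(members))


def merge_step(partition: ClusterPartition,
               results: list[PairTestResult]) -> ClusterPartition:
    """Merge mutually non-significant cluster pairs transitively.

    Non-significant pairs define edges of a graph over clusters; connected
    components become the new clusters, labelled "0", "1", ... by decreasing
    cell count (ties by lexicographically smallest member). When no pair is
    non-significant the partition is returned unchanged, labels intact.
    """
    edges = [(r.cluster_i, r.cluster_j) for r in results
             if r.significant is False]
    if not edges:
        return partition

    parent = {c: c for c in partition.clusters}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    components: dict[str, list[str]] = {}
    for c in partition.clusters:
        components.setdefault(find(c), []).append(c)
    sizes = partition.sizes()
    ordered = sorted(components.values(),
                     key=lambda m: _component_label(m, sizes))
    mapping = {m: str(rank) for rank, members in enumerate(ordered)
               for m in members}
    return partition.relabel(mapping)


def _premerge_singletons(expr: ExpressionMatrix, partition: ClusterPartition,
                         marker_config: MarkerConfig,
                         score_config: ScoreConfig,
                         notes: list[str]) -> ClusterPartition:
    """Absorb size-1 clusters into their nearest cluster by profile distance.

    Marker selection needs >= 2 cells per cluster, so profiles are computed
    over the non-singleton clusters' score columns only.
    """
    sizes = partition.sizes()
    singletons = [c for c, n in sizes.items() if n < 2]
    if not singletons:
        return partition
    keep = [c for c in partition.clusters if c not in singletons]
    if not keep:
        raise ValueError("all clusters are singletons; nothing to test")
    sub = ClusterPartition(
        np.where(np.isin(partition.labels, keep), partition.labels, keep[0]),
        partition.cell_ids,
    )
    markers = select_markers(expr, sub, marker_config)
    scores = score_matrix(expr, sub, markers, score_config)
    profiles = cluster_profiles(scores, sub).to_numpy()
    keep_order = list(scores.cluster_ids)
    mapping = {c: c for c in partition.clusters}
    for s in singletons:
        row = scores.values[partition.labels == s].mean(axis=0)
        nearest = keep_order[int(np.argmin(
            np.linalg.norm(profiles - row, axis=1)))]
        mapping[s] = nearest
        msg = (f"singleton cluster {s!r} pre-merged into nearest cluster "
               f"{nearest!r} by profile distance")
        notes.append(msg)
        warnings.warn(msg)
    return partition.relabel(mapping)


def run_cluster_merge(expr: ExpressionMatrix, partition: ClusterPartition,
                      marker_config: MarkerConfig | None = None,
                      score_config: ScoreConfig | None = None,
                      merge_config: MergeConfig | None = None) -> MergeResult:
    """Iterate marker selection, scoring, pair testing, and merging.

    Stops after ``max_iterations`` rounds (default 1), earlier if the
    partition stops changing, or — with ``run_to_convergence`` — only once a
    fixed point is reached. The output partition is always a coarsening of
    the input; final markers and scores are recomputed on it.
    """
    marker_config = marker_config or MarkerConfig()
    score_config = score_config or ScoreConfig()
    merge_config = merge_config or MergeConfig()
    if len(partition.clusters) < 2:
        raise ValueError("cluster-merge needs at least 2 input clusters")

    notes: list[str] = []
    current = partition
    input_labels = partition.labels.copy()
    tables: list[list[PairTestResult]] = []
    limit = (10 ** 6 if merge_config.run_to_convergence
             else merge_config.max_iterations)
    iterations = 0
    while iterations < limit:
        iterations += 1
        current = _premerge_singletons(expr, current, marker_config,
                                       score_config, notes)
        if len(current.clusters) < 2:
            msg = "partition collapsed to a single cluster; stopping"
            notes.append(msg)
            warnings.warn(msg)
            break
        markers = select_markers(expr, current, marker_config)
        scores = score_matrix(expr, current, markers, score_config)
        if merge_config.pair_selection == "mnn":
            pairs = mnn_pairs(cluster_profiles(scores, current),
                              merge_config.mnn_neighbours)
        else:
            pairs = _all_pairs(current.clusters)
        results = [test_pair(scores, current, a, b, merge_config)
                   for a, b in sorted(pairs)]
        results = call_significance(results, merge_config)
        tables.append(results)
        merged = merge_step(current, results)
        changed = not np.array_equal(merged.labels, current.labels)
        current = merged
        if not changed:
            break
        if len(current.clusters) < 2:
            msg = "partition collapsed to a single cluster; stopping"
            notes.append(msg)
            warnings.warn(msg)
            break

    final_markers = select_markers(expr, current, marker_config) \
        if len(current.clusters) >= 2 else MarkerGeneSets({}, {}, [])
    final_scores = (score_matrix(expr, current, final_markers, score_config)
                    if final_markers.sets else
                    ScoreMatrix(np.zeros((expr.n_cells, 1)), expr.cell_ids,
                                np.asarray(current.clusters, dtype=object),
                                method=score_config.method))
    merge_map = {str(a): str(b) for a, b in zip(input_labels, current.labels)}
    return MergeResult(current, iterations, tables, final_scores,
                       final_markers, merge_map, notes)
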