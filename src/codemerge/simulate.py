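"""Synthetic scRNA-seq counts with combinatorial differential expression.

Groups are *not* demarcated by single marker genes: each group is assigned a
unique random combination of 3-7 genes out of a shared 15-gene pool, and
only the combination identifies the group. Differential expression is
injected by (1) setting a sampled proportion tau ~ N(0.85, 0.05) of a
group's zero counts for each of its DE genes to the gene's median non-zero
count, then (2) multiplying the group's counts for that gene by a factor
phi ~ N(6, 1) (clamped at 1) and rounding.

Base counts come from an explicit hierarchical model — gene means from a
Gamma distribution, per-cell library-size factors log-normal, counts
negative binomial — giving realistic overdispersed, zero-rich count data
with no external estimation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import RAW_COUNTS, ClusterPartition, ExpressionMatrix


@dataclass
class SimulationConfig:
    """Parameters of the count simulator (defaults are the study design)."""

    n_genes: int = 10_000
    n_cells: int = 3_000
    n_groups: int = 8
    de_pool_size: int = 15
    genes_per_group_min: int = 3
    genes_per_group_max: int = 7
    de_mean: float = 6.0        # mu_phi, multiplicative DE factor mean
    de_sd: float = 1.0          # sigma_phi
    zero_fill_mean: float = 0.85  # mu_tau, proportion of zeros filled
    zero_fill_sd: float = 0.05    # sigma_tau
    gene_mean_shape: float = 0.3  # Gamma shape of per-gene mean
    gene_mean_scale: float = 2.0  # Gamma scale of per-gene mean
    dispersion: float = 0.1       # NB dispersion (var = mu + disp * mu^2)
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if not (1 <= self.genes_per_group_min <= self.genes_per_group_max):
            raise ValueError("invalid genes-per-group range")
        if self.de_pool_size < self.genes_per_group_max:
            raise ValueError("DE pool must be at least the max combination size")
        if self.de_pool_size > self.n_genes:
            raise ValueError("DE pool larger than the gene universe")
        if not (0 < self.zero_fill_mean <= 1):
            raise ValueError("zero_fill_mean must be in (0, 1]")


@dataclass
class SimulatedDataset:
    """Counts plus ground truth: group labels, DE combinations, DE pool."""

    counts: ExpressionMatrix
    truth: ClusterPartition
    de_genes: dict[str, list[str]]
    de_pool: list[str]

    def truth_dict(self) -> dict:
        return {
            "groups": list(self.de_genes),
            "combinations": {g: list(c) for g, c in self.de_genes.items()},
            "pool": list(self.de_pool),
        }


def _ids(prefix: str, n: int) -> np.ndarray:
    return np.array([f"{prefix}{i}" for i in range(n)], dtype=object)


def simulate_base_counts(config: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> ExpressionMatrix:
    """Homogeneous Gamma-NB counts: no group structure.

    gene mean ~ Gamma(shape, scale); library factor ~ LogNormal;
    counts ~ NB with mean (library x gene mean) and the configured
    dispersion, drawn as a Gamma-Poisson mixture.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gene_means = rng.gamma(config.gene_mean_shape, config.gene_mean_scale,
                           size=config.n_genes)
    lib = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd,
                        size=config.n_cells)
    r = 1.0 / config.dispersion
    counts = np.empty((config.n_cells, config.n_genes), dtype=np.int32)
    # draw in blocks of cells to bound the temporary float allocations
    step = max(1, min(config.n_cells, 512))
    for start in range(0, config.n_cells, step):
        stop = min(start + step, config.n_cells)
        mu = np.outer(lib[start:stop], gene_means)
        counts[start:stop] = rng.poisson(rng.gamma(r, mu / r))
    return ExpressionMatrix(counts, _ids("cell", config.n_cells),
                            _ids("gene", config.n_genes), RAW_COUNTS)


def _draw_unique_combinations(rng: np.random.Generator, pool: np.ndarray,
                              config: SimulationConfig) -> list[list[str]]:
    combos: list[frozenset] = []
    out: list[list[str]] = []
    for _ in range(config.n_groups):
        while True:
            size = int(rng.integers(config.genes_per_group_min,
                                    config.genes_per_group_max + 1))
            combo = rng.choice(pool, size=size, replace=False)
            key = frozenset(combo)
            if key not in combos:
                combos.append(key)
                out.append(sorted(combo))
                break
    return out


def inject_group_de(counts: ExpressionMatrix, config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> SimulatedDataset:
    """Assign cells to groups and inject combinatorial DE in-place-free."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    t, f = counts.shape
    labels = rng.integers(0, config.n_groups, size=t).astype(str)
    pool = rng.choice(counts.gene_ids, size=config.de_pool_size,
                      replace=False)
    combos = _draw_unique_combinations(rng, pool, config)

    base = counts.dense()
    values = base.copy()
    # per-gene median of non-zero counts, from the unmodified base matrix
    pool_idx = counts.gene_index(pool)
    medians = {}
    for g, gi in zip(pool, pool_idx):
        nz = base[:, gi][base[:, gi] > 0]
        medians[g] = float(np.median(nz)) if nz.size else 1.0

    de_genes: dict[str, list[str]] = {}
    for group in range(config.n_groups):
        gname = str(group)
        cells = np.flatnonzero(labels == gname)
        de_genes[gname] = combos[group]
        for gene in combos[group]:
            gi = int(counts.gene_index([gene])[0])
            col = values[cells, gi]
            zeros = cells[col == 0]
            tau = float(np.clip(rng.normal(config.zero_fill_mean,
                                           config.zero_fill_sd), 0.0, 1.0))
            n_fill = int(round(tau * zeros.size))
            if n_fill > 0:
                fill = rng.choice(zeros, size=n_fill, replace=False)
                values[fill, gi] = medians[gene]
            phi = max(1.0, float(rng.normal(config.de_mean, config.de_sd)))
            values[cells, gi] = np.rint(values[cells, gi] * phi)

    expr = ExpressionMatrix(values.astype(np.int64), counts.cell_ids,
                            counts.gene_ids, RAW_COUNTS)
    truth = ClusterPartition(labels, counts.cell_ids)
    return SimulatedDataset(expr, truth, de_genes, [str(g) for g in pool])


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Base counts + group DE injection from a single seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base = simulate_base_counts(config, rng)
    return inject_group_de(base, config, rng)


def split_artificial_subclusters(partition: ClusterPartition, n_sub: int = 3,
                                 min_size: int = 20, seed: int = 0
                                 ) -> tuple[ClusterPartition,
                                            dict[tuple[str, str], bool]]:
    """Split each cluster with more than ``min_size`` cells into n_sub
    random subgroups of near-equal size; smaller clusters stay intact.

    Returns the sub-clustered partition and ground-truth labels for every
    unordered subgroup pair: True (significantly different) iff the two
    subgroups come from different parent clusters.
    """
    if n_sub < 2:
        raise ValueError("n_sub must be >= 2")
    rng = np.random.default_rng(seed)
    new = np.empty(partition.n_cells, dtype=object)
    parents: dict[str, str] = {}
    for cluster in partition.clusters:
        idx = partition.indices(cluster)
        if idx.size > min_size:
            perm = rng.permutation(idx)
            for s, chunk in enumerate(np.array_split(perm, n_sub)):
                label = f"{cluster}_s{s}"
                new[chunk] = label
                parents[label] = cluster
        else:
            new[idx] = cluster
            parents[cluster] = cluster
    sub = ClusterPartition(new, partition.cell_ids)
    labels = sub.clusters
    truth = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = sorted((labels[i], labels[j]))
            truth[(a, b)] = parents[a] != parents[b]
    return sub, truth


def downsample_per_cluster(expr: ExpressionMatrix,
                           partition: ClusterPartition, max_cells: int = 15,
                           seed: int = 0
                           ) -> tuple[ExpressionMatrix, ClusterPartition]:
    """Keep a uniform random subset of at most max_cells per cluster."""
    if max_cells < 1:
        raise ValueError("max_cells must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cluster in partition.clusters:
        idx = partition.indices(cluster)
        if idx.size > max_cells:
            idx = rng.choice(idx, size=max_cells, replace=False)
        keep.append(np.sort(idx))
    index = np.sort(np.concatenate(keep))
    return expr.subset_cells(index), partition.subset(index)
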