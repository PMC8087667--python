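"""Ground-truth simulator: negative-binomial mixtures with cluster structure.

Cells are assigned to clusters by fixed proportions; counts for cell i and
gene m are NB(mean[cluster_i, m] * libfactor_i, theta_m), where the
per-cell library factor is lognormal.  An optional fraction of entries can
be zeroed out afterwards to emulate excess technical zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import CountMatrix, LabeledCells

__all__ = ["MixtureSpec", "simulate_nb_mixture", "two_cluster_spec"]


@dataclass(frozen=True)
class MixtureSpec:
    n_cells: int
    n_genes: int
    cluster_proportions: tuple[float, ...]
    cluster_means: np.ndarray  # n_clusters x n_genes, positive
    theta: np.ndarray  # per-gene inverse dispersion, positive
    libsize_sigma: float = 0.0  # SD of log library factor (lognormal, mean-log 0)
    extra_zero_fraction: float = 0.0
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)

    def validate(self) -> None:
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.ndim != 1 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("cluster_proportions must be a simplex vector")
        means = np.asarray(self.cluster_means, dtype=float)
        if means.shape != (self.n_clusters, self.n_genes):
            raise ValueError("cluster_means must be n_clusters x n_genes")
        if np.any(means <= 0):
            raise ValueError("cluster means must be positive")
        if np.any(np.asarray(self.theta) <= 0):
            raise ValueError("theta must be positive")
        if not (0.0 <= self.extra_zero_fraction <= 1.0):
            raise ValueError("extra_zero_fraction must lie in [0, 1]")


def simulate_nb_mixture(spec: MixtureSpec) -> tuple[CountMatrix, LabeledCells]:
    """Draw a clustered NB count matrix and its ground-truth labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.n_clusters, size=spec.n_cells, p=spec.cluster_proportions)
    theta = np.asarray(spec.theta, dtype=float)
    mu = np.asarray(spec.cluster_means, dtype=float)[labels]  # n_cells x n_genes
    if spec.libsize_sigma > 0:
        lib = np.exp(rng.normal(0.0, spec.libsize_sigma, size=spec.n_cells))
        mu = mu * lib[:, None]
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    if spec.extra_zero_fraction > 0:
        mask = rng.random(counts.shape) < spec.extra_zero_fraction
        counts = np.where(mask, 0, counts)
    # relabel to contiguous 0..K'-1 in case a cluster drew no cells
    uniq, labels = np.unique(labels, return_inverse=True)
    cell_ids = [f"cell{i}" for i in range(spec.n_cells)]
    gene_ids = [f"gene{m}" for m in range(spec.n_genes)]
    return (
        CountMatrix(counts, cell_ids, gene_ids),
        LabeledCells(cell_ids, labels),
    )


def two_cluster_spec(
    n_cells: int = 2000,
    n_genes: int = 50,
    n_markers: int = 10,
    fold_change: float = 8.0,
    base_mean: float = 2.0,
    theta: float = 2.0,
    proportions: tuple[float, float] = (0.5, 0.5),
    libsize_sigma: float = 0.1,
    seed: int = 0,
) -> MixtureSpec:
    """Two well-separated NB populations.

    The first ``n_markers`` genes are markers: half are up-regulated by
    ``fold_change`` in cluster 0, half in cluster 1; the remaining genes
    share ``base_mean`` in both clusters.
    """
    means = np.full((2, n_genes), base_mean)
    half = n_markers // 2
    means[0, :half] = base_mean * fold_change
    means[1, half:n_markers] = base_mean * fold_change
    return MixtureSpec(
        n_cells=n_cells,
        n_genes=n_genes,
        cluster_proportions=proportions,
        cluster_means=means,
        theta=np.full(n_genes, theta),
        libsize_sigma=libsize_sigma,
        seed=seed,
    )
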