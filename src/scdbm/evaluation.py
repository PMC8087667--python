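"""Synthetic-data quality evaluation against a reference dataset.

The reference workflow mirrors a typical scRNA-seq analysis: library-size
normalization and log1p, PCA, a 2-d UMAP embedding, and Leiden community
detection on the PCA nearest-neighbor graph.  Synthetic cells are projected
into the same embedding and each receives the cluster label of its nearest
reference cell (Euclidean distance).  Quality indices:

* Davies-Bouldin index (DBI) of the transferred labels in embedding space —
  small values mean compact, well-separated clusters.
* Adjusted Rand index (ARI) between the transferred labels and a de-novo
  clustering of the synthetic data by the same provider — measures whether
  the synthetic data, analysed on its own, reproduces the reference
  partition.
* Mean absolute difference in per-cluster cell counts.
* Per-gene mean absolute deviation of descriptive statistics (median, IQR,
  coefficient of variation, zero fraction) between synthetic and reference
  counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import CountMatrix, LabeledCells

__all__ = [
    "ReferenceClusteringConfig",
    "ClusteredEmbedding",
    "EvaluationReport",
    "EmbeddingProjector",
    "reference_clustering",
    "transfer_labels",
    "davies_bouldin",
    "adjusted_rand",
    "cluster_proportion_mad",
    "gene_stat_mad",
    "zero_preservation_check",
    "evaluate_synthetic",
]

GENE_STATISTICS = ("median", "iqr", "cv", "zero_fraction")


@dataclass(frozen=True)
class ReferenceClusteringConfig:
    n_pcs: int = 20
    n_neighbors: int = 15
    resolution: float = 0.1
    seed: int = 0
    embed: str = "umap"  # "umap" or "pca" (first two PCs)


@dataclass(frozen=True)
class ClusteredEmbedding:
    """Low-dimensional coordinates plus cluster labels for a set of cells."""

    coords: np.ndarray
    labels: LabeledCells
    projector: "EmbeddingProjector | None" = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] < 1:
            raise ValueError("coords must be n_cells x d with d >= 1")
        if coords.shape[0] != len(self.labels.cell_ids):
            raise ValueError("coords rows must align with labels")


@dataclass(frozen=True)
class EvaluationReport:
    dbi: float
    ari: float
    cluster_count_mad: float
    gene_stat_mad: dict[str, float]
    n_cells_generated: int

    def __post_init__(self) -> None:
        if self.dbi < 0:
            raise ValueError("DBI must be nonnegative")

    def to_dict(self) -> dict:
        out = {
            "dbi": self.dbi,
            "ari": self.ari,
            "cluster_count_mad": self.cluster_count_mad,
            "n_cells_generated": self.n_cells_generated,
        }
        for k, v in self.gene_stat_mad.items():
            out[f"mad_{k}"] = v
        return out


class EmbeddingProjector:
    """Normalization + PCA + UMAP pipeline fitted on reference counts.

    ``transform`` places new (synthetic) cells into the reference embedding
    space so that nearest-neighbor label transfer is well defined.
    """

    def __init__(self, cfg: ReferenceClusteringConfig):
        self.cfg = cfg
        self._median_lib: float | None = None

    def _normalize(self, counts: np.ndarray) -> np.ndarray:
        lib = counts.sum(axis=1).astype(float)
        lib[lib == 0] = 1.0
        return np.log1p(counts / lib[:, None] * self._median_lib)

    def fit(self, cm: CountMatrix) -> np.ndarray:
        from sklearn.decomposition import PCA

        if cm.n_cells <= self.cfg.n_neighbors:
            raise ValueError(
                f"need more than n_neighbors={self.cfg.n_neighbors} cells, got {cm.n_cells}"
            )
        lib = cm.counts.sum(axis=1).astype(float)
        lib[lib == 0] = 1.0
        self._median_lib = float(np.median(lib))
        logx = self._normalize(cm.counts)
        n_pcs = min(self.cfg.n_pcs, min(logx.shape) - 1)
        self._pca = PCA(n_components=n_pcs, random_state=self.cfg.seed)
        self._pcs = self._pca.fit_transform(logx)
        if self.cfg.embed == "umap":
            import umap

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._umap = umap.UMAP(
                    n_components=2,
                    n_neighbors=self.cfg.n_neighbors,
                    random_state=self.cfg.seed,
                    n_jobs=1,
                )
                self._coords = self._umap.fit_transform(self._pcs)
        else:
            self._umap = None
            self._coords = self._pcs[:, :2]
        return self._coords

    def transform(self, cm: CountMatrix) -> np.ndarray:
        if self._median_lib is None:
            raise RuntimeError("projector is not fitted")
        try:
            pcs = self._pca.transform(self._normalize(cm.counts))
            if self._umap is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return np.asarray(self._umap.transform(pcs))
            return pcs[:, :2]
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"projector failed at embedding stage: {err}") from err

    def pca_coords(self) -> np.ndarray:
        return self._pcs


def _leiden_labels(pcs: np.ndarray, cfg: ReferenceClusteringConfig) -> np.ndarray:
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    knn = NearestNeighbors(n_neighbors=cfg.n_neighbors).fit(pcs)
    _, idx = knn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=pcs.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=cfg.resolution,
        seed=cfg.seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=np.int64)


def reference_clustering(
    cm: CountMatrix,
    cfg: ReferenceClusteringConfig | None = None,
    labels: LabeledCells | None = None,
    coords: np.ndarray | None = None,
) -> ClusteredEmbedding:
    """Cluster and embed a count matrix, or pass user-supplied labels through.

    Default provider: log1p-normalize, PCA, Leiden communities on the PCA
    kNN graph, 2-d UMAP coordinates.  If ``labels`` (and optionally
    ``coords``) are supplied they are returned verbatim, with the embedding
    still fitted so label transfer remains possible.
    """
    if cfg is None:
        cfg = ReferenceClusteringConfig()
    if cm.n_cells == 0:
        raise ValueError("count matrix is empty")
    proj = EmbeddingProjector(cfg)
    fitted_coords = proj.fit(cm)
    if labels is not None:
        if list(labels.cell_ids) != list(cm.cell_ids):
            raise ValueError("supplied labels do not match count matrix cells")
        use_coords = fitted_coords if coords is None else np.asarray(coords, float)
        return ClusteredEmbedding(use_coords, labels, proj)
    membership = _leiden_labels(proj.pca_coords(), cfg)
    return ClusteredEmbedding(fitted_coords, LabeledCells(cm.cell_ids, membership), proj)


def transfer_labels(
    ref: ClusteredEmbedding,
    query_counts: CountMatrix,
    projector: EmbeddingProjector | None = None,
) -> LabeledCells:
    """Assign each query cell the label of its nearest reference cell.

    Distances are Euclidean in the reference embedding space; exact ties go
    to the lowest reference index.
    """
    proj = projector or ref.projector
    if proj is None:
        raise ValueError("no projector available to place query cells")
    qcoords = proj.transform(query_counts)
    labels = np.empty(qcoords.shape[0], dtype=np.int64)
    chunk = 2048
    for s in range(0, qcoords.shape[0], chunk):
        d = cdist(qcoords[s : s + chunk], ref.coords)
        labels[s : s + chunk] = ref.labels.labels[np.argmin(d, axis=1)]
    # transferred labels may miss some reference clusters; keep ids as-is
    return LabeledCells(query_counts.cell_ids, _compact(labels))


def _compact(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def transfer_labels_raw(ref: ClusteredEmbedding, qcoords: np.ndarray) -> np.ndarray:
    """Label transfer from precomputed query coordinates (no re-projection).

    Returns raw reference label ids (not compacted)."""
    d = cdist(np.asarray(qcoords, float), ref.coords)
    return ref.labels.labels[np.argmin(d, axis=1)]


def davies_bouldin(coords: np.ndarray, labels: np.ndarray, variant: str = "classical") -> float:
    """Davies-Bouldin index with p = q = 2.

    DBI = (1/K) sum_i max_{j!=i} R_ij with M_ij the Euclidean centroid
    distance and S_k the root-mean-square distance of cluster members to
    their centroid.  ``variant`` selects the numerator of R_ij:
    ``classical`` uses S_i + S_j; ``as_printed`` uses S_i - S_j.
    """
    if variant not in ("classical", "as_printed"):
        raise ValueError("variant must be 'classical' or 'as_printed'")
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    K = len(uniq)
    if K < 2:
        raise ValueError("need at least 2 clusters")
    cents = np.stack([coords[labels == k].mean(axis=0) for k in uniq])
    S = np.array(
        [
            np.sqrt(np.mean(np.sum((coords[labels == k] - cents[i]) ** 2, axis=1)))
            for i, k in enumerate(uniq)
        ]
    )
    M = cdist(cents, cents)
    if np.any(M[~np.eye(K, dtype=bool)] == 0):
        raise ZeroDivisionError("coincident cluster centroids: M_ij = 0")
    D = np.empty(K)
    for i in range(K):
        R = np.array(
            [
                (S[i] + S[j] if variant == "classical" else S[i] - S[j]) / M[i, j]
                for j in range(K)
                if j != i
            ]
        )
        D[i] = R.max()
    return float(D.mean())


def adjusted_rand(labels_a, labels_b) -> float:
    """Adjusted Rand index from exact integer binomial sums.

    Chance-corrected pair-counting agreement between two partitions of the
    same cells; 1 for identical partitions, ~0 for independent ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must cover the same cells")
    n = a.size
    if n == 0:
        raise ValueError("empty labelings")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_ij = sum(math.comb(int(nij), 2) for nij in table.ravel())
    sum_a = sum(math.comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(math.comb(int(x), 2) for x in table.sum(axis=0))
    n2 = math.comb(n, 2)
    expected = sum_a * sum_b / n2
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # e.g. both partitions trivial
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def cluster_proportion_mad(ref_labels, syn_labels) -> float:
    """Mean absolute difference in per-cluster cell counts.

    Clusters present on only one side contribute their full count; the mean
    runs over the union of cluster ids.
    """
    ref = np.asarray(ref_labels)
    syn = np.asarray(syn_labels)
    if ref.size == 0 or syn.size == 0:
        raise ValueError("empty label vectors")
    ids = np.union1d(np.unique(ref), np.unique(syn))
    diffs = [abs(int((ref == k).sum()) - int((syn == k).sum())) for k in ids]
    return float(np.mean(diffs))


def _gene_stat(counts: np.ndarray, statistic: str):
    counts = counts.astype(float)
    if statistic == "median":
        return np.median(counts, axis=0)
    if statistic == "iqr":
        q75, q25 = np.percentile(counts, [75, 25], axis=0)
        return q75 - q25
    if statistic == "cv":
        mean = counts.mean(axis=0)
        sd = counts.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(mean > 0, sd / mean, np.nan)
    if statistic == "zero_fraction":
        return (counts == 0).mean(axis=0)
    raise ValueError(f"unknown statistic {statistic!r}")


def gene_stat_mad(orig: CountMatrix, syn: CountMatrix, statistic: str) -> float:
    """Mean over genes of |stat(orig gene) - stat(syn gene)| on raw counts.

    For ``cv``, genes with zero mean in either dataset are excluded.
    """
    if orig.gene_ids != syn.gene_ids:
        raise ValueError("gene sets differ between original and synthetic data")
    so = _gene_stat(orig.counts, statistic)
    ss = _gene_stat(syn.counts, statistic)
    diff = np.abs(so - ss)
    if statistic == "cv":
        keep = ~(np.isnan(so) | np.isnan(ss))
        n_excluded = int((~keep).sum())
        if n_excluded:
            warnings.warn(
                f"cv: excluded {n_excluded} genes with zero mean", RuntimeWarning, stacklevel=2
            )
        diff = diff[keep]
        if diff.size == 0:
            raise ValueError("no genes with positive mean in both datasets")
    return float(diff.mean())


@dataclass(frozen=True)
class ZeroPreservationReport:
    mean_abs_gap: float
    flagged_genes: list[str]
    per_gene_gap: np.ndarray  # generated zero fraction minus corrupted one


def zero_preservation_check(
    orig: CountMatrix,
    corrupted: CountMatrix,
    generated: CountMatrix,
    margin: float = 0.1,
) -> ZeroPreservationReport:
    """Check that a generator does not silently impute artificial zeros.

    Compares per-gene zero fractions of the generated data against the
    corrupted training input; genes where the generated zero fraction falls
    below the corrupted one by more than ``margin`` are flagged as evidence
    of imputation.
    """
    if not (orig.gene_ids == corrupted.gene_ids == generated.gene_ids):
        raise ValueError("gene sets must match across all three matrices")
    zc = (corrupted.counts == 0).mean(axis=0)
    zg = (generated.counts == 0).mean(axis=0)
    gap = zg - zc
    flagged = [g for g, d in zip(orig.gene_ids, gap) if d < -margin]
    return ZeroPreservationReport(float(np.abs(gap).mean()), flagged, gap)


def evaluate_synthetic(
    ref: ClusteredEmbedding,
    original: CountMatrix,
    synthetic: CountMatrix,
    cfg: ReferenceClusteringConfig | None = None,
) -> EvaluationReport:
    """Full quality report for one synthetic dataset against the reference.

    DBI is computed on the synthetic cells' embedding coordinates with their
    transferred labels; ARI compares the transferred labels with a de-novo
    clustering of the synthetic data by the same provider.
    """
    if cfg is None:
        cfg = ReferenceClusteringConfig()
    proj = ref.projector
    if proj is None:
        raise ValueError("reference embedding carries no projector")
    qcoords = proj.transform(synthetic)
    raw = transfer_labels_raw(ref, qcoords)
    if len(np.unique(raw)) >= 2:
        dbi = davies_bouldin(qcoords, raw, variant="classical")
    else:
        dbi = float("nan")  # degenerate: all cells transferred to one cluster
    denovo = reference_clustering(synthetic, cfg)
    ari = adjusted_rand(raw, denovo.labels.labels)
    count_mad = cluster_proportion_mad(ref.labels.labels, raw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mads = {s: gene_stat_mad(original, synthetic, s) for s in GENE_STATISTICS}
    return EvaluationReport(
        dbi=dbi,
        ari=ari,
        cluster_count_mad=count_mad,
        gene_stat_mad=mads,
        n_cells_generated=synthetic.n_cells,
    )
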