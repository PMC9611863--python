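"""Transcription-consistency analysis across samples.

Gene pairs are scored with Spearman's rank correlation across samples; the
distance between genes is ``1 - |rho|``, which is deliberately sign-blind —
strongly anti-correlated genes sit as close as strongly correlated ones,
since either indicates coordinated regulation.  Genes are then clustered by
complete-linkage agglomeration, the tree is checked against the original
distances by the cophenetic correlation, and the number of clusters is
chosen by mean silhouette width on the precomputed distance.

The agglomeration itself is implemented here with a deterministic
smallest-index tie-break so dendrograms are reproducible across platforms;
merges are stored in scipy linkage-matrix layout so scipy's dendrogram
utilities apply directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_score

logger = logging.getLogger("tissuescreen")


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho matrix with unit diagonal over labelled genes."""

    gene_labels: list[str]
    rho: np.ndarray
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.gene_labels)
        if self.rho.shape != (n, n):
            raise ValueError(f"rho shape {self.rho.shape} != ({n}, {n})")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12, rtol=0):
            raise ValueError("rho is not symmetric")
        if not np.all(np.diag(self.rho) == 1.0):
            raise ValueError("rho diagonal must be exactly 1")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValueError("|rho| exceeds 1")


@dataclass
class DistanceMatrix:
    """Symmetric 1 - |rho| distance matrix: zero diagonal, entries in [0, 1]."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12, rtol=0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: (node_a, node_b, height) per merge.

    Leaves are numbered 0..n-1 in label order; merge i creates node n+i.
    ``linkage_matrix`` is the scipy-compatible (n-1) x 4 form.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    @property
    def linkage_matrix(self) -> np.ndarray:
        n = len(self.labels)
        z = np.zeros((n - 1, 4))
        sizes = {i: 1 for i in range(n)}
        for i, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + i] = size
            z[i] = [a, b, h, size]
        return z


# ---------------------------------------------------------------------------
# Correlation and distance
# ---------------------------------------------------------------------------


def spearman_matrix(
    sample_matrix: np.ndarray | pd.DataFrame,
    gene_labels: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Midrank Spearman correlation between all gene pairs (genes x samples).

    A constant gene has no rank variation, so its correlations are
    undefined; they are recorded as 0 and the gene is flagged, keeping the
    matrix complete for clustering.
    """
    if isinstance(sample_matrix, pd.DataFrame):
        if gene_labels is None:
            gene_labels = [str(g) for g in sample_matrix.index]
        sample_matrix = sample_matrix.to_numpy(dtype=float)
    x = np.asarray(sample_matrix, dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 3:
        raise ValueError("Spearman correlation requires at least 3 samples")
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    labels = list(gene_labels) if gene_labels is not None else [f"g{i}" for i in range(n_genes)]

    ranks = np.apply_along_axis(rankdata, 1, x)
    sd = ranks.std(axis=1)
    constant = sd == 0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * np.sqrt(n_samples))
    rho = (centered @ centered.T) / np.outer(denom, denom)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    flagged = [labels[i] for i in np.nonzero(constant)[0]]
    if flagged:
        logger.warning("constant gene(s) with undefined correlation set to 0: %s", flagged)
    return CorrelationMatrix(labels, rho, flagged)


def correlation_distance(corr: CorrelationMatrix) -> DistanceMatrix:
    """d_ij = 1 - |rho_ij|: perfect (anti-)correlation gives distance 0."""
    d = 1.0 - np.abs(corr.rho)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(corr.gene_labels), np.clip(d, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


def hcluster(dist: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering; inter-cluster distance is the pairwise max
    (complete linkage) or min (single linkage).

    Ties are broken by the smallest (then second-smallest) cluster index, so
    the merge sequence is fully deterministic.
    """
    if linkage not in ("complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    reduce = max if linkage == "complete" else min
    n = len(dist.labels)
    if n < 2:
        raise ValueError("clustering requires at least 2 items")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    d = dist.d
    while len(members) > 1:
        best: tuple[float, int, int] | None = None
        ids = sorted(members)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dd = reduce(d[i, j] for i in members[a] for j in members[b])
                if best is None or dd < best[0]:
                    best = (dd, a, b)
        dd, a, b = best  # ties resolved by the sorted-id scan order
        merges.append((a, b, float(dd)))
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return Dendrogram(list(dist.labels), merges)


def cophenetic_correlation(
    dist: DistanceMatrix, dendrogram: Dendrogram
) -> tuple[float, bool]:
    """Pearson correlation between original and cophenetic distances.

    Returns ``(coefficient, degenerate)``; when either distance set is
    constant the correlation is undefined and reported as 0 with the
    degenerate flag set.
    """
    if dendrogram.labels != dist.labels:
        raise ValueError("dendrogram labels do not match the distance matrix")
    original = dist.condensed()
    coph = cophenet(dendrogram.linkage_matrix)
    if np.ptp(original) == 0 or np.ptp(coph) == 0:
        logger.warning("cophenetic correlation degenerate: constant distances")
        return 0.0, True
    c = float(np.corrcoef(original, coph)[0, 1])
    return c, False


def cut(dendrogram: Dendrogram, k: int) -> list[int]:
    """Cut the merge sequence into exactly k clusters.

    Labels are integers 0..k-1 ordered by each cluster's smallest leaf.
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i, (a, b, _) in enumerate(dendrogram.merges[: n - k]):
        members[n + i] = members.pop(a) + members.pop(b)
    clusters = sorted((min(m), m) for m in members.values())
    labels = [0] * n
    for idx, (_, m) in enumerate(clusters):
        for leaf in m:
            labels[leaf] = idx
    return labels


def select_k(
    dist: DistanceMatrix,
    dendrogram: Dendrogram,
    k_range: Sequence[int] = range(2, 11),
) -> tuple[int, dict[int, float]]:
    """Cluster count maximizing mean silhouette width on the distances.

    Ties break to the smallest k.  Returns the chosen k and the silhouette
    score per candidate k (candidates outside [2, n-1] are dropped).
    """
    n = len(dist.labels)
    candidates = [k for k in k_range if 2 <= k <= n - 1]
    if not candidates:
        raise ValueError(f"no valid k in range for n={n}")
    scores: dict[int, float] = {}
    for k in candidates:
        labels = cut(dendrogram, k)
        scores[k] = float(silhouette_score(dist.d, labels, metric="precomputed"))
    best = max(sorted(scores), key=lambda k: scores[k])  # stable: first max wins
    return best, scores


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths = parent height - child height."""
    n = len(dendrogram.labels)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: dendrogram.labels[i] for i in range(n)}
    for i, (a, b, h) in enumerate(dendrogram.merges):
        la = h - height[a]
        lb = h - height[b]
        node[n + i] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
        height[n + i] = h
    return node[n + len(dendrogram.merges) - 1] + ";"


def matrix_to_tsv(labels: Sequence[str], m: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(m, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def write_clusters_tsv(labels: Sequence[str], clusters: Sequence[int], path: str | Path) -> None:
    pd.DataFrame({"gene": list(labels), "cluster": list(clusters)}).to_csv(
        path, sep="\t", index=False
    )
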