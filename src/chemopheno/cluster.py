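"""Similarity analysis of the abundance matrix.

Euclidean distances between species (or compound) profiles, Ward.D2
agglomerative clustering via the Lance-Williams recurrence on squared
distances, principal components with cos2 quality-of-representation, and
leaf-ordered heatmap export.

Ward.D2 merges the pair minimizing the increase in within-cluster
variance; after merging clusters i and j, the distance to any other
cluster k is updated as

    d(i+j, k) = sqrt[ ((n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2)
                      / (n_i + n_j + n_k) ]

Equal merge costs are broken toward the lexicographically smallest label
pair, making dendrograms platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "PCAResult",
    "euclidean_distances",
    "ward_d2_cluster",
    "cut_tree",
    "pca",
    "heatmap_export",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal and row labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("distance matrix must be square and match labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("distances must be non-negative with zero diagonal")
        self.matrix = m

    def min_pair(self) -> tuple[str, str, float]:
        """Labels and value of the smallest off-diagonal distance."""
        m = self.matrix.copy()
        np.fill_diagonal(m, np.inf)
        i, j = np.unravel_index(np.argmin(m), m.shape)
        a, b = sorted((self.labels[i], self.labels[j]))
        return a, b, float(m[i, j])


@dataclass
class Dendrogram:
    """Merge table of an agglomerative clustering.

    ``merges`` lists (node_a, node_b, height, size) in merge order; leaves
    are numbered 0..n-1 and the i-th merge creates node n+i, as in the
    scipy linkage convention.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a dendrogram over n leaves needs n-1 merges")

    def to_linkage(self) -> np.ndarray:
        """Scipy-format linkage array (for plotting/leaf ordering)."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf indices of the tree."""
        n = len(self.labels)

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b, _h, _s = self.merges[node - n]
            return walk(a) + walk(b)

        return walk(2 * n - 2) if n > 1 else list(range(n))


def euclidean_distances(matrix: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean distances between the rows of ``matrix``."""
    if isinstance(matrix, pd.DataFrame):
        labels = [str(x) for x in matrix.index]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(values.shape[0])]
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need >=2 rows of equal length")
    return DistanceMatrix(labels=labels, matrix=squareform(pdist(values)))


def ward_d2_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative Ward.D2 clustering of a precomputed distance matrix."""
    n = len(dist.labels)
    d2 = dist.matrix.astype(float) ** 2  # Lance-Williams operates on squares
    size = {i: 1 for i in range(n)}
    # lexicographic tie-break key: smallest member label of each cluster
    key = {i: dist.labels[i] for i in range(n)}
    active = list(range(n))
    node_of = {i: i for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_node = n

    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                cost = d2[i, j]
                pair_key = tuple(sorted((key[i], key[j])))
                cand = (cost, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        cost, _pk, i, j = best
        height = float(np.sqrt(cost))
        ni, nj = size[i], size[j]
        a, b = sorted((node_of[i], node_of[j]))
        merges.append((a, b, height, ni + nj))

        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            d2[i, k] = d2[k, i] = (
                (ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * d2[i, j]
            ) / (ni + nj + nk)
        size[i] = ni + nj
        key[i] = min(key[i], key[j])
        node_of[i] = next_node
        next_node += 1
        active.remove(j)

    return Dendrogram(labels=list(dist.labels), merges=merges)


def cut_tree(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition the leaves into ``k`` clusters by removing the k-1 highest merges.

    Returns label -> cluster id (1-based, ordered by first leaf appearance).
    """
    n = len(dend.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # merges are in non-decreasing height order; apply all but the last k-1
    for idx, (a, b, _h, _s) in enumerate(dend.merges):
        if idx >= n - k:
            break
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node

    assignment: dict[str, int] = {}
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen) + 1
        assignment[dend.labels[leaf]] = seen[root]
    return assignment


@dataclass
class PCAResult:
    """Principal component scores, loadings and per-observation cos2."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    cos2: pd.DataFrame


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA of observations (rows) by singular value decomposition.

    ``scale`` divides each column by its standard deviation (error on
    zero-variance columns). cos2 of observation i on component m is
    score_im^2 / sum_m score_im^2 -- the share of the observation's
    squared distance to the centroid captured by that axis. All
    min(n_obs - 1, n_var) components are retained, so cos2 rows sum to 1.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [str(c) for c, s in zip(matrix.columns, sd) if s == 0]
            raise ValueError(f"zero-variance columns cannot be scaled: {bad}")
        X = X / sd
    if center:
        X = X - X.mean(axis=0)

    n_comp = min(X.shape[0] - 1 if center else X.shape[0], X.shape[1])
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    # deterministic sign: largest-magnitude loading positive per component
    for m in range(n_comp):
        pivot = np.argmax(np.abs(Vt[m]))
        if Vt[m][pivot] < 0:
            Vt[m] *= -1
            U[:, m] *= -1
    scores = U * s
    total_ss = (X**2).sum()
    evr = s**2 / total_ss if total_ss > 0 else np.zeros(n_comp)
    comp_names = [f"PC{m + 1}" for m in range(n_comp)]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=comp_names)
    sq = scores**2
    total = sq.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    cos2 = pd.DataFrame(sq / total, index=matrix.index, columns=comp_names)
    return PCAResult(
        scores=scores_df,
        loadings=loadings,
        explained_variance_ratio=evr,
        cos2=cos2,
    )


def heatmap_export(
    matrix: pd.DataFrame,
    row_dend: Dendrogram,
    col_dend: Dendrogram,
    path_prefix: str | Path,
) -> pd.DataFrame:
    """Write the leaf-ordered matrix TSV and a dendrogram-annotated heatmap.

    Returns the reordered matrix; files are ``<prefix>.tsv`` and
    ``<prefix>.png``.
    """
    if list(map(str, matrix.index)) != row_dend.labels or list(
        map(str, matrix.columns)
    ) != col_dend.labels:
        raise ValueError("dendrogram labels must match matrix row/column labels")
    ordered = matrix.iloc[row_dend.leaf_order(), col_dend.leaf_order()]
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ordered.to_csv(prefix.with_suffix(".tsv"), sep="\t")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as _scipy_dend

    fig = plt.figure(figsize=(10, 4.5))
    gs = fig.add_gridspec(2, 2, width_ratios=[1, 6], height_ratios=[1, 3],
                          hspace=0.02, wspace=0.02)
    ax_col = fig.add_subplot(gs[0, 1])
    _scipy_dend(col_dend.to_linkage(), ax=ax_col, no_labels=True,
                color_threshold=0, link_color_func=lambda _k: "k")
    ax_col.axis("off")
    ax_row = fig.add_subplot(gs[1, 0])
    _scipy_dend(row_dend.to_linkage(), ax=ax_row, orientation="left",
                no_labels=True, color_threshold=0, link_color_func=lambda _k: "k")
    ax_row.axis("off")
    ax = fig.add_subplot(gs[1, 1])
    # scipy's left-orientation dendrogram lists leaves bottom-to-top
    ax.imshow(ordered.to_numpy()[::-1], aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(ordered.index)))
    ax.set_yticklabels(ordered.index[::-1], fontsize=7)
    ax.yaxis.tick_right()
    ax.set_xticks([])
    fig.savefig(prefix.with_suffix(".png"), dpi=120, bbox_inches="tight")
    plt.close(fig)
    return ordered
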