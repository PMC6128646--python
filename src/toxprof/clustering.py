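"""Hierarchical clustering of toxicogenomic profiles.

Mutant-by-toxin GI-score matrices are clustered in two dimensions with the
classic gene-expression recipe: uncentered correlation (cosine similarity
without mean-centering) as the similarity, distance d = 1 - r, and
unweighted pair-wise average linkage (UPGMA). Uncentered correlation is the
right similarity for fitness profiles because the zero point is meaningful —
GI = 0 is "unaffected" — so profiles should cluster by direction from the
origin, not after per-profile recentering.

Missing cells are handled by pairwise deletion: a pair of profiles is
compared over the positions finite in both, subject to a minimum-overlap
requirement. Outputs include tab-delimited CDT/GTR/ATR files that standard
dendrogram viewers open, and Newick strings per axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "uncentered_corr",
    "similarity_matrix",
    "average_linkage",
    "cluster_bidimensional",
    "Dendrogram",
    "BiclusterResult",
    "to_newick",
    "write_cluster3",
]


def uncentered_corr(x, y, min_overlap: int = 2) -> float:
    """Cosine similarity without mean-centering, in [-1, 1].

    r = sum(x_i y_i) / sqrt(sum(x_i^2) * sum(y_i^2)). Positions where
    either vector is non-finite are dropped before computing (pairwise
    deletion); at least ``min_overlap`` shared finite entries are required,
    and a zero-norm vector after deletion has no defined direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be 1-d vectors of equal, positive length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < min_overlap:
        raise ValueError(
            f"only {int(mask.sum())} shared finite entries; need >= {min_overlap}"
        )
    xv, yv = x[mask], y[mask]
    nx = np.sqrt(np.dot(xv, xv))
    ny = np.sqrt(np.dot(yv, yv))
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm vector after missing-data removal")
    return float(np.clip(np.dot(xv, yv) / (nx * ny), -1.0, 1.0))


def similarity_matrix(data: np.ndarray, min_overlap: int = 2) -> np.ndarray:
    """Pairwise uncentered correlation between the rows of ``data``."""
    n = data.shape[0]
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = uncentered_corr(data[i], data[j], min_overlap)
    return S


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    Leaves are numbered 0..n-1; the cluster created at merge step k gets id
    n + k. ``merges`` holds (left_id, right_id, distance) per step, with
    left_id < right_id; distances are the 1 - r cluster distances at which
    the merge happened and are non-decreasing across steps (UPGMA admits no
    inversions).
    """

    n_leaves: int
    merges: list
    labels: list

    def __post_init__(self):
        if len(self.merges) not in (0, self.n_leaves - 1):
            raise ValueError("a binary tree on n leaves has n-1 internal nodes")
        d = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(d, d[1:])):
            raise AssertionError("merge distances must be non-decreasing")

    def children(self) -> dict:
        return {
            self.n_leaves + k: (left, right)
            for k, (left, right, _) in enumerate(self.merges)
        }

    def heights(self) -> dict:
        h = {i: 0.0 for i in range(self.n_leaves)}
        for k, (_, _, d) in enumerate(self.merges):
            h[self.n_leaves + k] = d
        return h

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1 if self.merges else 0

    def leaf_order(self) -> list:
        """Left-first depth-first leaf sequence."""
        kids = self.children()
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = kids[node]
                stack.extend([right, left])
        return order


def average_linkage(
    data, axis: str = "rows", min_overlap: int = 2
) -> Dendrogram:
    """UPGMA on d = 1 - uncentered correlation.

    Agglomerates with the unweighted-average (Lance–Williams) update: the
    distance between merged cluster (a u b) and any c is the size-weighted
    mean of d(a,c) and d(b,c), i.e. the mean over all original leaf pairs.
    Ties in the minimum distance are broken toward the lexicographically
    smallest (cluster id, cluster id) pair, so the tree is deterministic.
    """
    if isinstance(data, pd.DataFrame):
        labels = list(data.index if axis == "rows" else data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        labels = None
    if axis == "cols":
        X = X.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    n = X.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if n < 1:
        raise ValueError("nothing to cluster")
    if n == 1:
        return Dendrogram(n_leaves=1, merges=[], labels=labels)

    # the overlap floor guards missing-data pairs; it cannot exceed the
    # profile length (a 1-column matrix still clusters its rows)
    D = 1.0 - similarity_matrix(X, min(min_overlap, X.shape[1]))
    # dist maps frozen pair (i, j), i < j over *cluster ids*, to distance
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    for step in range(n - 1):
        (a, b) = min(dist, key=lambda p: (dist[p], p))
        d_ab = dist[(a, b)]
        new = n + step
        for c in active - {a, b}:
            d_ac = dist[(min(a, c), max(a, c))]
            d_bc = dist[(min(b, c), max(b, c))]
            dist[(c, new)] = (size[a] * d_ac + size[b] * d_bc) / (size[a] + size[b])
        for c in list(active):
            dist.pop((min(a, c), max(a, c)), None)
            dist.pop((min(b, c), max(b, c)), None)
        active -= {a, b}
        active.add(new)
        size[new] = size[a] + size[b]
        merges.append((a, b, d_ab))
    return Dendrogram(n_leaves=n, merges=merges, labels=labels)


@dataclass
class BiclusterResult:
    """Row- and column-clustered matrix with both trees."""

    data: pd.DataFrame  # reordered by leaf order on both axes
    row_tree: Dendrogram
    col_tree: Dendrogram


def cluster_bidimensional(matrix: pd.DataFrame, min_overlap: int = 2) -> BiclusterResult:
    """Cluster rows and columns independently; reorder both axes.

    Requires at least 2 rows; a single column is allowed (its tree is a
    lone leaf) so one-screen matrices still get row clustering.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    row_tree = average_linkage(matrix, axis="rows", min_overlap=min_overlap)
    col_tree = average_linkage(matrix, axis="cols", min_overlap=min_overlap)
    ordered = matrix.iloc[row_tree.leaf_order(), col_tree.leaf_order()]
    return BiclusterResult(data=ordered, row_tree=row_tree, col_tree=col_tree)


# ---------------------------------------------------------------------------
# exports


def to_newick(tree: Dendrogram) -> str:
    """Newick string with branch lengths from merge heights (d = 1 - r)."""
    kids = tree.children()
    heights = tree.heights()

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if node < tree.n_leaves:
            return f"{tree.labels[node]}:{bl:.6g}"
        left, right = kids[node]
        h = heights[node]
        return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

    root = tree.root
    if root < tree.n_leaves:
        return f"{tree.labels[root]};"
    left, right = kids[root]
    h = heights[root]
    return f"({render(left, h)},{render(right, h)});"


def _tree_lines(tree: Dendrogram, leaf_fmt: str, node_fmt: str) -> list:
    lines = []
    for k, (left, right, d) in enumerate(tree.merges):
        def name(i):
            return leaf_fmt.format(i) if i < tree.n_leaves else node_fmt.format(i - tree.n_leaves)
        lines.append(f"{node_fmt.format(k)}\t{name(left)}\t{name(right)}\t{1.0 - d:.6f}")
    return lines


def write_cluster3(result: BiclusterResult, prefix: str | Path) -> dict:
    """Emit CDT/GTR/ATR files (tab-delimited, NODE/GENE/ARRY ids).

    The GTR/ATR record merge *similarities* (1 - d), largest first, as the
    classic clustering tools do; the CDT holds the matrix reordered by leaf
    order with GID/AID identifiers linking cells to the trees. Returns the
    paths written.
    """
    prefix = Path(prefix)
    paths = {}
    gtr = prefix.with_suffix(".gtr")
    with open(gtr, "w") as fh:
        fh.write("\n".join(_tree_lines(result.row_tree, "GENE{}X", "NODE{}X")) + "\n")
    paths["gtr"] = gtr
    has_atr = result.col_tree.n_leaves > 1
    if has_atr:
        atr = prefix.with_suffix(".atr")
        with open(atr, "w") as fh:
            fh.write("\n".join(_tree_lines(result.col_tree, "ARRY{}X", "NODE{}X")) + "\n")
        paths["atr"] = atr

    df = result.data
    row_order = result.row_tree.leaf_order()
    col_order = result.col_tree.leaf_order()
    cdt = prefix.with_suffix(".cdt")
    with open(cdt, "w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(map(str, df.columns)) + "\n")
        if has_atr:
            fh.write("AID\t\t\t\t" + "\t".join(f"ARRY{j}X" for j in col_order) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1" for _ in df.columns) + "\n")
        for i, (label, row) in zip(row_order, df.iterrows()):
            vals = "\t".join("" if not np.isfinite(v) else f"{v:.6g}" for v in row)
            fh.write(f"GENE{i}X\t{label}\t{label}\t1\t{vals}\n")
    paths["cdt"] = cdt
    return paths
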