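"""Genetic similarity, neighbor-joining dendrogram with bootstrap
support, and principal component analysis over the binary marker matrix.

The NJ agglomeration is implemented here (Saitou–Nei, deterministic
tie-breaking) rather than delegated, so that replicate-level behaviour
(bootstrap column resampling, support mapping onto the fixed topology)
is fully specified.  Trees are :class:`skbio.TreeNode` objects with an
optional ``support`` attribute (percentage, 0–100) on internal nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .matrix import MarkerMatrix

__all__ = ["SimilarityMatrix", "PCAResult", "jaccard", "nj_tree", "root_at",
           "bootstrap_support", "tree_splits", "pca", "tree_from_matrix"]


# ---------------------------------------------------------------------------
# Jaccard similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Symmetric clone × clone Jaccard similarity in [0, 1], unit diagonal."""

    df: pd.DataFrame

    @property
    def clone_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def to_distance(self) -> pd.DataFrame:
        """Dissimilarity 1 − S, the bridging convention feeding NJ."""
        d = 1.0 - self.df
        np.fill_diagonal(d.values, 0.0)
        return d


def jaccard(m: MarkerMatrix | np.ndarray, clone_ids: list[str] | None = None
            ) -> SimilarityMatrix:
    """Pairwise Jaccard similarity |A∩B| / |A∪B| of present-marker sets.

    Pairs of all-absent profiles have an empty union; they are defined
    as similarity 1 (identical profiles) with a warning.
    """
    if isinstance(m, MarkerMatrix):
        x = m.df.to_numpy(dtype=float)
        ids = m.clone_ids
    else:
        x = np.asarray(m, dtype=float)
        ids = clone_ids if clone_ids is not None else [str(i) for i in range(len(x))]
    if x.shape[0] < 2:
        raise ValueError("need at least two clones")
    empty = x.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            "clone(s) with all-zero marker profile: "
            + ", ".join(np.asarray(ids)[empty]), stacklevel=2)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(pd.DataFrame(s, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _clamp(x: float) -> float:
    return x if x > 0.0 else 0.0


def nj_tree(d: pd.DataFrame | np.ndarray, ids: list[str] | None = None) -> TreeNode:
    """Saitou–Nei neighbor joining on a symmetric zero-diagonal distance
    matrix; returns an unrooted tree (trifurcating root) over ``ids``.

    Q-matrix ties are broken by the lowest (row, col) index pair in the
    current matrix, and negative branch lengths are clamped to zero, so
    the result is reproducible bit-for-bit.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        dm = d.to_numpy(dtype=float).copy()
    else:
        dm = np.array(d, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(len(dm))]
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm).any():
        raise ValueError("NaN in distance matrix")
    if dm.shape != (n, n) or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(set(ids)) != n:
        raise ValueError("duplicate taxon ids")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]

    while len(nodes) > 3:
        m = dm.shape[0]
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) pair among minima — deterministic tie-break
        flat = np.argmin(q)  # row-major argmin returns the first minimum
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = dm[i, j]
        li = _clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = _clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))))
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        new_row = 0.5 * (dm[i, :] + dm[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        dm = np.vstack([dm[keep][:, keep],
                        new_row[keep][None, :]])
        dm = np.hstack([dm, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three lineages around an unrooted trifurcation
    (a, b, c) = nodes
    la = _clamp(0.5 * (dm[0, 1] + dm[0, 2] - dm[1, 2]))
    lb = _clamp(0.5 * (dm[0, 1] + dm[1, 2] - dm[0, 2]))
    lc = _clamp(0.5 * (dm[0, 2] + dm[1, 2] - dm[0, 1]))
    a.length, b.length, c.length = la, lb, lc
    return TreeNode(children=[a, b, c])


def root_at(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root the tree on the midpoint of the outgroup's pendant edge."""
    try:
        tip = tree.find(outgroup)
    except Exception as exc:  # skbio raises MissingNodeError
        raise ValueError(f"outgroup {outgroup!r} not in tree") from exc
    if not tip.is_tip():
        raise ValueError(f"outgroup {outgroup!r} is not a leaf")
    rooted = tree.root_at(tip, above=True, branch_attrs=["support"])
    return rooted


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, each canonicalised
    as the side *not* containing the lexicographically smallest tip."""
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    full = frozenset(tips)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(tips) - 2:
            splits.add(side)
    return splits


def bootstrap_support(m: MarkerMatrix, n_reps: int = 1000,
                      seed: int = 0) -> TreeNode:
    """NJ tree of the full matrix with internal edges annotated by the
    percentage of column-resampled replicates containing the same
    bipartition.

    Columns (markers) are resampled with replacement; each replicate is
    re-scored through Jaccard + NJ.  Supports live on the ``support``
    attribute of internal nodes and annotate the *original* topology.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(jaccard(m).to_distance())
    tips = sorted(m.clone_ids)
    anchor, full = tips[0], frozenset(tips)

    node_splits: list[tuple[TreeNode, frozenset[str]]] = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(tips) - 2:
            node_splits.append((node, side))

    counts = {id(node): 0 for node, _ in node_splits}
    rng = np.random.default_rng(seed)
    x = m.df.to_numpy()
    ids = m.clone_ids
    n_cols = x.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = jaccard(x[:, cols], clone_ids=ids)
        rep_splits = tree_splits(nj_tree(rep.to_distance()))
        for node, side in node_splits:
            if side in rep_splits:
                counts[id(node)] += 1
    for node, _ in node_splits:
        node.support = 100.0 * counts[id(node)] / n_reps
    return tree


def tree_from_matrix(m: MarkerMatrix) -> TreeNode:
    """Convenience: Jaccard distance + NJ in one step."""
    return nj_tree(jaccard(m).to_distance())


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Component scores, eigenvalues and per-component variance shares."""

    scores: pd.DataFrame          # clones × PC1..PCk
    eigenvalues: np.ndarray       # covariance eigenvalues for reported PCs
    proportions: np.ndarray       # fraction of total variance per reported PC

    def cumulative_proportion(self, k: int | None = None) -> float:
        k = len(self.proportions) if k is None else k
        return float(self.proportions[:k].sum())


def pca(m: MarkerMatrix, k: int = 3) -> PCAResult:
    """PCA of the column-centered 0/1 marker matrix.

    Scores come from the SVD of the centered matrix (equivalent to the
    eigendecomposition of its covariance); each component's sign is
    fixed by making the largest-magnitude loading entry positive.
    """
    x = m.df.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two clones")
    if k > min(n - 1, x.shape[1]):
        raise ValueError(f"k={k} exceeds min(n-1, markers)="
                         f"{min(n - 1, x.shape[1])}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for j in range(k):
        imax = int(np.argmax(np.abs(vt[j])))
        if vt[j, imax] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    eigvals = s ** 2 / (n - 1)
    total = float((s ** 2).sum())
    props = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.clone_ids,
                            columns=[f"PC{j + 1}" for j in range(k)]),
        eigenvalues=eigvals[:k],
        proportions=props,
    )
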