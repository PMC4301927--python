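"""Module detection: clustering, tree cutting, eigengenes, merging."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score


@dataclass
class Dendrogram:
    """Agglomerative dendrogram wrapping a SciPy linkage matrix."""

    linkage: np.ndarray  # (n-1, 4) merge table
    n_leaves: int
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class EigengeneSet:
    """First-principal-component summaries per module.

    ``eigengenes`` is a modules x samples frame of unit-norm vectors;
    the sign of each is fixed so the mean correlation with member genes
    is non-negative. ``explained_variance`` is the fraction of module
    variance captured.
    """

    eigengenes: pd.DataFrame
    explained_variance: pd.Series


def hierarchical_cluster(
    dissim: np.ndarray, method: str = "complete", euclidean_rows: bool = False
) -> Dendrogram:
    """Cluster a precomputed dissimilarity matrix.

    By default the supplied matrix is used directly as pairwise
    distances. With ``euclidean_rows=True`` the Euclidean distances
    between the matrix rows are clustered instead (the literal
    "Euclidean distance on the similarity matrix" reading).
    """
    dissim = np.asarray(dissim, dtype=float)
    if dissim.ndim != 2 or dissim.shape[0] != dissim.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(dissim, dissim.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(dissim), 0, atol=1e-10):
        raise ValueError("dissimilarity must have a zero diagonal")
    if euclidean_rows:
        condensed = pdist(dissim, metric="euclidean")
    else:
        condensed = squareform((dissim + dissim.T) / 2.0, checks=False)
    z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(linkage=z, n_leaves=dissim.shape[0], method=method)


def _subtree_leaves(z: np.ndarray, n: int) -> list[np.ndarray]:
    """Leaf index sets for every internal node (merge order)."""
    leaves: list[np.ndarray] = []
    for a, b in z[:, :2].astype(int):
        la = np.array([a]) if a < n else leaves[a - n]
        lb = np.array([b]) if b < n else leaves[b - n]
        leaves.append(np.concatenate([la, lb]))
    return leaves


def dynamic_tree_cut(
    dend: Dendrogram,
    min_size: int = 30,
    cut_height: float | None = None,
    gap_fraction: float = 0.0,
) -> np.ndarray:
    """Cut the dendrogram into modules (label 0 = unassigned).

    A static cut at ``cut_height`` (default 0.99 x max merge height)
    yields candidate branches; branches of at least ``min_size`` leaves
    become modules. Each branch is then recursively split where the gap
    between a node's merge height and its taller child exceeds
    ``gap_fraction`` of the branch's internal height range and both
    sub-branches reach ``min_size``. Modules are numbered from 1 by
    decreasing size, ties by smallest member index.
    """
    n = dend.n_leaves
    z = dend.linkage
    if min_size > n:
        warnings.warn("min_size exceeds leaf count; all genes unassigned")
        return np.zeros(n, dtype=int)
    max_h = z[:, 2].max() if len(z) else 0.0
    if cut_height is None:
        cut_height = 0.99 * max_h

    flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    node_leaves = _subtree_leaves(z, n)
    node_height = {n + i: z[i, 2] for i in range(len(z))}
    children = {n + i: (int(z[i, 0]), int(z[i, 1])) for i in range(len(z))}

    def leaves_of(node: int) -> np.ndarray:
        return np.array([node]) if node < n else node_leaves[node - n]

    def height_of(node: int) -> float:
        return 0.0 if node < n else node_height[node]

    # map each flat branch to the subtree node spanning exactly its leaves
    branch_root: dict[int, int] = {}
    sizes = {c: int((flat == c).sum()) for c in np.unique(flat)}
    for node in range(2 * n - 1):
        lv = leaves_of(node)
        c = flat[lv[0]]
        if len(lv) == sizes[c] and (flat[lv] == c).all():
            # largest such node wins (later nodes span more leaves)
            prev = branch_root.get(c, -1)
            if prev < 0 or len(lv) > len(leaves_of(prev)):
                branch_root[c] = node

    def internal_heights(node: int) -> list[float]:
        out, stack = [], [node]
        while stack:
            cur = stack.pop()
            if cur >= n:
                out.append(height_of(cur))
                stack.extend(children[cur])
        return out

    def split(node: int) -> list[np.ndarray]:
        """Return leaf groups of the subtree after recursive gap splits."""
        if node < n:
            return [leaves_of(node)]
        left, right = children[node]
        if len(leaves_of(left)) < min_size or len(leaves_of(right)) < min_size:
            return [leaves_of(node)]
        hs = internal_heights(node)
        span = height_of(node) - min(hs)
        gap = height_of(node) - max(height_of(left), height_of(right))
        if span <= 0 or gap <= gap_fraction * span:
            return [leaves_of(node)]
        return split(left) + split(right)

    groups: list[np.ndarray] = []
    for c, root in branch_root.items():
        if sizes[c] < min_size:
            continue
        groups.extend(g for g in split(root) if len(g) >= min_size)

    labels = np.zeros(n, dtype=int)
    groups.sort(key=lambda g: (-len(g), int(g.min())))
    for i, g in enumerate(groups, start=1):
        labels[g] = i
    return labels


def stability_check(
    detect: "callable",
    n_genes: int,
    n_repeats: int = 5,
    seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Re-run a detection procedure under permuted gene input order.

    ``detect`` maps a gene-index permutation to labels in the original
    gene order. Returns the pairwise adjusted Rand indices between
    repeats; a deterministic pipeline reports ARI = 1 throughout.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    runs = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_genes)
        runs.append(np.asarray(detect(perm)))
    rows = []
    for i in range(n_repeats):
        for j in range(i + 1, n_repeats):
            rows.append(
                {
                    "seed_a": seeds[i],
                    "seed_b": seeds[j],
                    "ari": adjusted_rand_score(runs[i], runs[j]),
                }
            )
    return pd.DataFrame(rows)


def _standardize(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return centered / sd


def compute_eigengenes(expr: pd.DataFrame, labels: np.ndarray) -> EigengeneSet:
    """First principal component of each module's standardized expression."""
    labels = np.asarray(labels)
    modules = sorted(set(labels) - {0})
    if not modules:
        raise ValueError("no modules to summarize")
    values = _standardize(expr.to_numpy(dtype=float))
    rows, ev = {}, {}
    for q in modules:
        block = values[labels == q]  # genes x samples
        u, s, vt = np.linalg.svd(block, full_matrices=False)
        e = vt[0]
        e = e / np.linalg.norm(e)
        member_cor = np.array([np.corrcoef(g, e)[0, 1] for g in block])
        if np.nanmean(member_cor) < 0:
            e = -e
        rows[q] = e
        ev[q] = float(s[0] ** 2 / (s**2).sum())
    eg = pd.DataFrame(rows, index=expr.columns).T
    return EigengeneSet(eigengenes=eg, explained_variance=pd.Series(ev))


def merge_modules(
    expr: pd.DataFrame,
    labels: np.ndarray,
    eigengenes: EigengeneSet | None = None,
    similarity_threshold: float = 0.65,
    max_iter: int = 10,
) -> tuple[np.ndarray, EigengeneSet, list[int]]:
    """Iteratively merge modules whose eigengenes correlate above threshold.

    Each pass clusters the eigengenes with average linkage on
    ``1 - correlation``, cuts at ``1 - similarity_threshold``, relabels
    genes and recomputes eigengenes, until stable or ``max_iter`` passes.
    Returns the merged labels, final eigengenes, and the module count
    after each pass.
    """
    labels = np.asarray(labels).copy()
    if eigengenes is None:
        eigengenes = compute_eigengenes(expr, labels)
    counts: list[int] = []
    for _ in range(max_iter):
        modules = list(eigengenes.eigengenes.index)
        if len(modules) <= 1:
            counts.append(len(modules))
            break
        e = eigengenes.eigengenes.to_numpy()
        cor = np.clip(np.corrcoef(e), -1.0, 1.0)
        d = np.clip(1.0 - cor, 0.0, None)
        np.fill_diagonal(d, 0.0)
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        groups = hierarchy.fcluster(z, t=1.0 - similarity_threshold, criterion="distance")
        if len(set(groups)) == len(modules):
            counts.append(len(modules))
            break
        mapping = dict(zip(modules, groups))
        new = np.zeros_like(labels)
        for g in range(len(labels)):
            if labels[g] != 0:
                new[g] = mapping[labels[g]]
        labels = _relabel_by_size(new)
        eigengenes = compute_eigengenes(expr, labels)
        counts.append(len(eigengenes.eigengenes))
    else:
        warnings.warn("module merging did not converge within max_iter passes")
    return labels, eigengenes, counts


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber non-zero labels by decreasing size, ties by first member."""
    out = np.zeros_like(labels)
    info = []
    for q in set(labels) - {0}:
        members = np.where(labels == q)[0]
        info.append((-len(members), int(members.min()), q))
    for new, (_, _, q) in enumerate(sorted(info), start=1):
        out[labels == q] = new
    return out


def detect_modules(
    dissim: np.ndarray,
    expr: pd.DataFrame,
    min_size: int = 30,
    merge_threshold: float = 0.65,
    cut_height: float | None = None,
    gap_fraction: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, EigengeneSet]:
    """Cluster -> cut -> merge convenience wrapper.

    Returns (pre-merge labels, merged labels, merged eigengenes).
    """
    dend = hierarchical_cluster(dissim)
    pre = dynamic_tree_cut(
        dend, min_size=min_size, cut_height=cut_height, gap_fraction=gap_fraction
    )
    if not (pre > 0).any():
        return pre, pre, EigengeneSet(pd.DataFrame(), pd.Series(dtype=float))
    merged, eigengenes, _ = merge_modules(
        expr, pre, similarity_threshold=merge_threshold
    )
    return pre, merged, eigengenes
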