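"""Weighted network construction: adjacency, soft threshold, TOM.

The adjacency is a correlation-power similarity, ``a_ij = |cor|^beta``
in the default unsigned mode, and the topological overlap measure (TOM)
rescales it by shared-neighbour weight. Soft-threshold selection uses
the scale-free topology fit of the connectivity distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODES = ("unsigned", "signed-magnitude")


@dataclass
class Adjacency:
    """Symmetric gene-gene adjacency with unit diagonal.

    ``connectivity`` (k_i) sums each row excluding the diagonal.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    beta: int
    mode: str = "unsigned"

    @property
    def connectivity(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - np.diag(self.matrix)

    def __post_init__(self) -> None:
        a = self.matrix
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")


@dataclass
class TOM:
    """Topological overlap matrix; dissimilarity is ``1 - matrix``."""

    matrix: np.ndarray
    gene_ids: list[str]

    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.matrix
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ScaleFreeFit:
    r_squared: float
    slope: float
    ok: bool = True


def compute_adjacency(
    expr: pd.DataFrame, beta: int, mode: str = "unsigned"
) -> Adjacency:
    """Raise the gene-gene Pearson correlation to the soft power ``beta``.

    Unsigned mode uses ``|cor|^beta``; signed-magnitude uses
    ``((1 + cor) / 2)^beta``. Zero-variance genes are dropped with a
    warning before computing correlations.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate profiles")

    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        dropped = list(expr.index[sd == 0])
        warnings.warn(f"dropping zero-variance genes: {dropped}")
        expr = expr.loc[sd > 0]
        values = expr.to_numpy(dtype=float)

    cor = np.corrcoef(values)
    cor = np.clip(cor, -1.0, 1.0)
    if mode == "unsigned":
        a = np.abs(cor) ** beta
    else:
        a = ((1.0 + cor) / 2.0) ** beta
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return Adjacency(matrix=a, gene_ids=list(expr.index), beta=beta, mode=mode)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """Fit log10(frequency) ~ log10(mean connectivity) over k bins.

    Connectivities are binned into ``n_bins`` equal-width bins; the
    regression runs over non-empty bins with positive mean. The returned
    R^2 carries the sign of ``-slope`` so that a positive value
    indicates the decreasing relationship expected of scale-free
    topology. Degenerate inputs (all k equal, or fewer than three
    usable bins) return ``ok=False``.
    """
    k = np.asarray(k, dtype=float)
    if k.size == 0 or np.ptp(k) == 0:
        return ScaleFreeFit(np.nan, np.nan, ok=False)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_freq.append(np.log10(mask.sum() / k.size))
        log_k.append(np.log10(mean_k))
    if len(log_k) < 3 or np.ptp(log_k) == 0:
        return ScaleFreeFit(np.nan, np.nan, ok=False)
    fit = stats.linregress(log_k, log_freq)
    r2 = fit.rvalue**2 * np.sign(-fit.slope)
    return ScaleFreeFit(float(r2), float(fit.slope))


def soft_threshold_scan(
    expr: pd.DataFrame,
    powers: list[int] | range = range(1, 21),
    mode: str = "unsigned",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free fit and connectivity summary per candidate power."""
    rows = []
    for beta in powers:
        adj = compute_adjacency(expr, beta=beta, mode=mode)
        k = adj.connectivity
        fit = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": beta,
                "r_squared": fit.r_squared,
                "slope": fit.slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    return pd.DataFrame(rows)


def select_soft_threshold(scan: pd.DataFrame, target: float = 0.90) -> int:
    """Pick the last candidate power before the fit curve reaches target.

    If the very first candidate already reaches the target, it is
    returned; if no candidate reaches it, the argmax-R^2 power is
    returned with a warning.
    """
    if scan.empty:
        raise ValueError("empty soft-threshold scan")
    scan = scan.sort_values("power").reset_index(drop=True)
    reached = scan.index[scan["r_squared"] >= target]
    if len(reached) == 0:
        best = int(scan.loc[scan["r_squared"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached R^2 target {target}; "
            f"returning argmax power {best}"
        )
        return best
    first = reached[0]
    if first == 0:
        return int(scan.loc[0, "power"])
    return int(scan.loc[first - 1, "power"])


def compute_tom(adj: Adjacency) -> TOM:
    """Topological overlap of an adjacency matrix.

    ``w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and unit diagonal.
    """
    a = adj.matrix
    k = adj.connectivity
    # with unit diagonal, (A @ A)_ij = l_ij + 2 a_ij off-diagonal
    l = a @ a - 2.0 * a
    denom = np.minimum.outer(k, k) + 1.0 - a
    denom = np.where(denom <= 0, np.nan, denom)
    w = (l + a) / denom
    w = np.nan_to_num(w, nan=0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return TOM(matrix=w, gene_ids=adj.gene_ids)


def tom_dissimilarity(tom: TOM) -> np.ndarray:
    """``d = 1 - w`` with a zero diagonal."""
    return tom.dissimilarity()
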