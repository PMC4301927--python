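"""Eigengene-trait correlation, module membership, TF rank testing."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nitronet.modules import EigengeneSet


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the Student-t transform.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of
    freedom. Values of |r| = 1 return the smallest positive float to
    keep p in (0, 1].
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return float(np.finfo(float).tiny)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return max(2.0 * stats.t.sf(abs(t), df=n - 2), float(np.finfo(float).tiny))


def module_trait_correlation(
    eigengenes: EigengeneSet, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and t-transform p for every (module, trait) pair.

    Constant traits are skipped with a warning. Output is a long table
    with columns ``module, trait, r, p, n``, ready for heatmap pivots.
    """
    eg = eigengenes.eigengenes
    shared = [s for s in eg.columns if s in traits.index]
    if len(shared) < 3:
        raise ValueError("eigengenes and traits share fewer than 3 samples")
    rows = []
    for trait in traits.columns:
        y = traits.loc[shared, trait].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"skipping constant trait '{trait}'")
            continue
        for module in eg.index:
            x = eg.loc[module, shared].to_numpy(dtype=float)
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {
                    "module": module,
                    "trait": trait,
                    "r": r,
                    "p": correlation_pvalue(r, len(shared)),
                    "n": len(shared),
                }
            )
    return pd.DataFrame(rows)


def module_membership(
    expr: pd.DataFrame, labels: np.ndarray, eigengenes: EigengeneSet
) -> pd.DataFrame:
    """Correlation of each gene with its own module's eigengene.

    Returns a table with columns ``gene, module, mm, rank``; ranks run
    from 1 (highest membership) within each module, ties broken by gene
    id for determinism. Zero-variance genes get ``mm = NaN`` and are
    ranked last.
    """
    labels = np.asarray(labels)
    eg = eigengenes.eigengenes
    rows = []
    values = expr.to_numpy(dtype=float)
    for q in eg.index:
        e = eg.loc[q].to_numpy(dtype=float)
        members = np.where(labels == q)[0]
        for i in members:
            x = values[i]
            if x.std() == 0:
                mm = np.nan
            else:
                mm = float(np.corrcoef(x, e)[0, 1])
            rows.append({"gene": expr.index[i], "module": q, "mm": mm})
    table = pd.DataFrame(rows)
    ranked = []
    for q, grp in table.groupby("module"):
        order = grp.sort_values(["mm", "gene"], ascending=[False, True], na_position="last")
        r = pd.Series(np.arange(1, len(order) + 1), index=order.index)
        ranked.append(r)
    table["rank"] = pd.concat(ranked).reindex(table.index).astype(int)
    return table


def rank_top_tf(mm_table: pd.DataFrame, tf_set: set[str]) -> pd.DataFrame:
    """Highest-membership TF-annotated gene per module.

    Modules without any TF member are reported with ``gene = None`` and
    ``r_obs = NaN`` (excluded from significance testing).
    """
    rows = []
    for q, grp in mm_table.groupby("module"):
        tfs = grp[grp["gene"].isin(tf_set)]
        if tfs.empty:
            rows.append(
                {"module": q, "gene": None, "r_obs": np.nan, "n": len(grp), "m": 0}
            )
        else:
            best = tfs.loc[tfs["rank"].idxmin()]
            rows.append(
                {
                    "module": q,
                    "gene": best["gene"],
                    "r_obs": int(best["rank"]),
                    "n": len(grp),
                    "m": int(len(tfs)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TFRankResult:
    """Observed best-TF rank against the random-ranking null."""

    n: int
    m: int
    r_obs: int
    mc_p: float
    analytic_p: float
    signed_rank_p: float
    n_permutations: int
    seed: int | None
    null_mean_rank: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "r_obs": self.r_obs,
            "mc_p": self.mc_p,
            "analytic_p": self.analytic_p,
            "signed_rank_p": self.signed_rank_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "null_mean_rank": self.null_mean_rank,
        }


def best_rank_tail_probability(n: int, m: int, r: int) -> float:
    """P(best of m random distinct ranks out of n is <= r), exactly.

    ``1 - C(n - r, m) / C(n, m)`` computed with exact integer
    arithmetic.
    """
    if not (1 <= m <= n and 1 <= r <= n):
        raise ValueError("need 1 <= m <= n and 1 <= r <= n")
    if n - r < m:
        return 1.0
    return 1.0 - math.comb(n - r, m) / math.comb(n, m)


def _sample_best_ranks(
    n: int, m: int, n_perm: int, rng: np.random.Generator, chunk: int = 4096
) -> np.ndarray:
    """Best (smallest) rank among m randomly placed entities, per draw.

    Each draw is a uniform m-subset of ranks 1..n. Sparse subsets
    (m << n) are drawn with replacement and duplicate rows rejected;
    otherwise random keys are partially sorted, chunked to bound memory
    at ``chunk * n`` floats.
    """
    if m == 1:
        return rng.integers(1, n + 1, size=n_perm)
    if m <= max(n // 20, 2) and n > 64:
        def has_dup(rows: np.ndarray) -> np.ndarray:
            return (np.diff(np.sort(rows, axis=1), axis=1) == 0).any(axis=1)

        draws = rng.integers(1, n + 1, size=(n_perm, m))
        bad = has_dup(draws)
        while bad.any():
            draws[bad] = rng.integers(1, n + 1, size=(int(bad.sum()), m))
            bad[bad] = has_dup(draws[bad])
        return draws.min(axis=1)
    out = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        keys = rng.random((size, n))
        subset = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[done : done + size] = subset.min(axis=1) + 1
        done += size
    return out


def tf_rank_permutation_test(
    n: int,
    m: int,
    r_obs: int,
    n_perm: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TFRankResult:
    """Permutation test of the observed best-TF rank within a module.

    Draws ``n_perm`` uniform random orderings of the module's ``n``
    entities and records the best rank among the ``m`` TF-annotated
    ones. Reports:

    * ``mc_p`` — the add-one Monte-Carlo tail probability
      ``(#{R* <= r_obs} + 1) / (n_perm + 1)``;
    * ``analytic_p`` — the closed-form tail ``1 - C(n-r,m)/C(n,m)``;
    * ``signed_rank_p`` — a one-sample Wilcoxon signed-rank test of the
      null ranks against ``r_obs`` (a location comparison, reported for
      completeness; the tail probabilities are the primary measure).
    """
    if m == 0:
        raise ValueError("module has no TF-annotated entity to test")
    if not (1 <= m <= n and 1 <= r_obs <= n):
        raise ValueError("need 1 <= m <= n and 1 <= r_obs <= n")
    if rng is None:
        rng = np.random.default_rng(seed)
    best = _sample_best_ranks(n, m, n_perm, rng)
    mc_p = (int((best <= r_obs).sum()) + 1) / (n_perm + 1)
    diffs = best - r_obs
    if np.all(diffs == 0):
        signed_rank_p = 1.0
    else:
        signed_rank_p = float(stats.wilcoxon(diffs[diffs != 0]).pvalue)
    return TFRankResult(
        n=n,
        m=m,
        r_obs=r_obs,
        mc_p=float(mc_p),
        analytic_p=best_rank_tail_probability(n, m, r_obs),
        signed_rank_p=signed_rank_p,
        n_permutations=n_perm,
        seed=seed,
        null_mean_rank=float(best.mean()),
    )


def plot_module_trait_heatmap(table: pd.DataFrame, path: str) -> None:
    """Render the module-trait correlation table as an annotated heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = table.pivot(index="module", columns="trait", values="r")
    p = table.pivot(index="module", columns="trait", values="p")
    fig, ax = plt.subplots(
        figsize=(1.2 * len(r.columns) + 2, 0.5 * len(r.index) + 2)
    )
    im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r.index)), [f"M{q}" for q in r.index])
    for i in range(len(r.index)):
        for j in range(len(r.columns)):
            ax.text(
                j,
                i,
                f"{r.iat[i, j]:.2f}\n({p.iat[i, j]:.1g})",
                ha="center",
                va="center",
                fontsize=7,
            )
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
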