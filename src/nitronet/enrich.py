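"""Flat-annotation term enrichment (one-sided Fisher + BH FDR)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def read_annotation(
    path: str | Path, term_table: str | Path | None = None
) -> tuple[dict[str, set[str]], pd.DataFrame | None]:
    """Read a two-column (gene, term) TSV into a gene -> terms map.

    An optional term table (term, name, ontology) is returned alongside.
    """
    pairs = pd.read_csv(path, sep="\t", header=0, dtype=str)
    gene_col, term_col = pairs.columns[:2]
    annotation: dict[str, set[str]] = {}
    for gene, term in zip(pairs[gene_col], pairs[term_col]):
        annotation.setdefault(gene, set()).add(term)
    terms = None
    if term_table is not None:
        terms = pd.read_csv(term_table, sep="\t", dtype=str).set_index("term")
    return annotation, terms


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    Order-invariant: q-values are returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def fisher_enrichment(
    module_genes,
    annotation: dict[str, set[str]],
    universe,
    alpha: float = 0.05,
    min_count: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a gene list.

    For a term annotated to K of the N universe genes, of which k fall
    in the n-gene module, the one-sided p is the upper hypergeometric
    tail P(X >= k). Terms with fewer than ``min_count`` module genes are
    untested. BH q-values are computed across the tested terms and the
    significant flag requires ``q <= alpha``.
    """
    universe = set(universe)
    module = set(module_genes)
    if not universe:
        raise ValueError("empty universe")
    if not module:
        raise ValueError("empty module gene list")
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")

    term_universe: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotation.get(gene, ()):
            term_universe.setdefault(term, set()).add(gene)

    n, big_n = len(module), len(universe)
    rows = []
    for term, genes in sorted(term_universe.items()):
        k = len(genes & module)
        if k < min_count:
            continue
        big_k = len(genes)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {"term": term, "k": k, "n": n, "K": big_k, "N": big_n, "p": min(p, 1.0)}
        )
    table = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["q"] <= alpha
        table = table.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
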