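"""Metabolite statistics: imputation, Welch contrasts, response patterns.

Abundance tables are compounds x samples DataFrames with NaN for
missing cells; the metabolite design maps each sample to a tissue and a
treatment group in {LN, HN, LN->HN, HN->LN}. Tests run on natural-log
transformed values after per-compound minimum imputation; fold changes
are ratios of arithmetic group means on the original scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from nitronet.enrich import bh_fdr

GROUPS = ("LN", "HN", "LN->HN", "HN->LN")

#: contrast name -> (numerator group, denominator group)
CONTRASTS: dict[str, tuple[str, str]] = {
    "HN_vs_LN": ("HN", "LN"),
    "induction_vs_LN": ("LN->HN", "LN"),
    "reduction_vs_HN": ("HN->LN", "HN"),
}

PATTERNS = (
    "proportional-HN",
    "LN-accumulating",
    "non-proportional-reduction",
    "unchanged",
    "other",
)


def impute_minimum(mat: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with the compound's observed minimum.

    Compounds with no observed value at all are dropped with a warning.
    """
    observed = mat.notna().any(axis=1)
    if (~observed).any():
        warnings.warn(
            f"dropping entirely-missing compounds: {list(mat.index[~observed])}"
        )
        mat = mat.loc[observed]
    return mat.apply(lambda row: row.fillna(row.min()), axis=1)


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-statistic, Satterthwaite df and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return (0.0, float(len(x) + len(y) - 2), 1.0) if x.mean() == y.mean() else (
            np.inf if x.mean() > y.mean() else -np.inf,
            float(len(x) + len(y) - 2),
            0.0,
        )
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(df), float(p)


def welch_contrast(
    mat: pd.DataFrame,
    design: pd.DataFrame,
    contrast: str,
    tissue: str | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-compound Welch test for one treatment contrast.

    The test statistic is computed on ln-transformed abundances (the
    default); the reported ``ratio`` is numerator-group mean over
    denominator-group mean on the original scale. ``tissue`` restricts
    the samples when the design spans several tissues.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast '{contrast}'; use one of {list(CONTRASTS)}")
    num_group, den_group = CONTRASTS[contrast]
    sel = design
    if tissue is not None:
        sel = sel[sel["tissue"] == tissue]
    num_samples = sel.index[sel["group"] == num_group]
    den_samples = sel.index[sel["group"] == den_group]
    if len(num_samples) < 2 or len(den_samples) < 2:
        raise ValueError(f"contrast '{contrast}' needs >= 2 samples per group")

    rows = []
    for compound in mat.index:
        a = mat.loc[compound, num_samples].to_numpy(dtype=float)
        b = mat.loc[compound, den_samples].to_numpy(dtype=float)
        ratio = float(a.mean() / b.mean())
        if log_transform:
            a, b = np.log(a), np.log(b)
        t, df, p = welch_test(a, b)
        rows.append(
            {
                "compound": compound,
                "contrast": contrast,
                "ratio": ratio,
                "t": t,
                "df": df,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table


def compare_all(
    mat: pd.DataFrame,
    design: pd.DataFrame,
    tissue: str | None = None,
    alpha: float = 0.05,
    q_cut: float = 0.10,
) -> pd.DataFrame:
    """All three study contrasts with the dual p/q significance flag.

    ``significant`` requires both ``p <= alpha`` and ``q <= q_cut``; q
    is computed per contrast (within tissue) by Benjamini-Hochberg.
    """
    mat = impute_minimum(mat)
    parts = [
        welch_contrast(mat, design, contrast, tissue=tissue)
        for contrast in CONTRASTS
    ]
    table = pd.concat(parts, ignore_index=True)
    table["significant"] = (table["p"] <= alpha) & (table["q"] <= q_cut)
    return table


def classify_calls(
    hn_ln_ratio: float,
    hn_ln_sig: bool,
    induction_ratio: float,
    induction_sig: bool,
    reduction_ratio: float,
    reduction_sig: bool,
) -> str:
    """Response-pattern label from the three oriented ratio calls.

    * ``non-proportional-reduction`` — the reduction shift ratio
      (HN->LN over HN) is significantly above 1 while the adapted
      HN/LN ratio is at or above 1 or not significant: the compound is
      low (or flat) under adapted low N yet spikes on the shift.
    * ``proportional-HN`` — HN/LN significantly above 1, without a
      significant reduction spike.
    * ``LN-accumulating`` — HN/LN significantly below 1.
    * ``unchanged`` — nothing significant in any contrast.
    * ``other`` — any remaining combination.
    """
    if reduction_sig and reduction_ratio > 1 and (hn_ln_ratio >= 1 or not hn_ln_sig):
        return "non-proportional-reduction"
    if hn_ln_sig and hn_ln_ratio > 1 and not (reduction_sig and reduction_ratio > 1):
        return "proportional-HN"
    if hn_ln_sig and hn_ln_ratio < 1:
        return "LN-accumulating"
    if not (hn_ln_sig or induction_sig or reduction_sig):
        return "unchanged"
    return "other"


def classify_response(cmp: pd.DataFrame) -> pd.Series:
    """Pattern label per compound from a full three-contrast table.

    ``cmp`` must hold all three contrasts for every compound (as built
    by :func:`compare_all` for one tissue).
    """
    wide_r = cmp.pivot(index="compound", columns="contrast", values="ratio")
    wide_s = cmp.pivot(index="compound", columns="contrast", values="significant")
    missing = [c for c in CONTRASTS if c not in wide_r.columns]
    if missing or wide_r.isna().any().any():
        raise ValueError(f"missing contrasts for classification: {missing or 'some compounds'}")
    labels = {}
    for compound in wide_r.index:
        labels[compound] = classify_calls(
            wide_r.at[compound, "HN_vs_LN"],
            bool(wide_s.at[compound, "HN_vs_LN"]),
            wide_r.at[compound, "induction_vs_LN"],
            bool(wide_s.at[compound, "induction_vs_LN"]),
            wide_r.at[compound, "reduction_vs_HN"],
            bool(wide_s.at[compound, "reduction_vs_HN"]),
        )
    return pd.Series(labels, name="pattern")


def pattern_summary(
    cmp: pd.DataFrame, patterns: pd.Series, pathways: pd.Series | None = None
) -> pd.DataFrame:
    """Wide ratio table with significance stars and the pattern call."""
    wide_r = cmp.pivot(index="compound", columns="contrast", values="ratio")
    wide_s = cmp.pivot(index="compound", columns="contrast", values="significant")
    out = pd.DataFrame(index=wide_r.index)
    if pathways is not None:
        out["pathway"] = pathways.reindex(out.index)
    for contrast in CONTRASTS:
        starred = [
            f"{r:.2f}*" if s else f"{r:.2f}"
            for r, s in zip(wide_r[contrast], wide_s[contrast])
        ]
        out[contrast] = starred
    out["pattern"] = patterns.reindex(out.index)
    return out
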