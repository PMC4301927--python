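"""Expression matrix preparation.

Reads tab-delimited expression and sample-design tables, filters
features, collapses replicate groups to medians, and builds the binary
trait indicators used for eigengene-trait correlation.

Conventions
-----------
* An expression matrix is a :class:`pandas.DataFrame` with feature ids
  as the index and sample ids as columns; values are finite floats
  (assumed already normalised/log-scale upstream).
* A sample design is a :class:`pandas.DataFrame` indexed by sample id
  with columns ``tissue``, ``condition`` and ``replicate``.
* Replicate groups are defined by ``(tissue, condition)``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("tissue", "condition", "replicate")


def read_expression(
    path: str | Path, design_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an expression TSV and its sample design, cross-checking ids.

    Parameters
    ----------
    path
        TSV with a header row; first column holds feature ids, the
        remaining columns one sample each.
    design_path
        TSV with columns ``sample``, ``tissue``, ``condition``,
        ``replicate``.

    Returns
    -------
    (expression, design)
        Expression as features x samples DataFrame; design indexed by
        sample id, columns re-ordered to match the expression columns.

    Raises
    ------
    ValueError
        On duplicate feature ids, non-finite values, or a mismatch
        between expression columns and design samples.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    dup = expr.index[expr.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate feature ids: {', '.join(map(str, dup))}")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    expr = expr.astype(float)

    design = read_design(design_path)
    missing = set(expr.columns) - set(design.index)
    extra = set(design.index) - set(expr.columns)
    if missing or extra:
        raise ValueError(
            "sample mismatch between expression and design; "
            f"not in design: {sorted(missing)}; not in expression: {sorted(extra)}"
        )
    return expr, design.loc[list(expr.columns)]


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    if "sample" not in design.columns:
        raise ValueError("design table must have a 'sample' column")
    for col in DESIGN_COLUMNS:
        if col not in design.columns:
            raise ValueError(f"design table missing column '{col}'")
    if design["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in design table")
    return design.set_index("sample")


def write_expression(expr: pd.DataFrame, path: str | Path, id_label: str = "feature") -> None:
    expr.to_csv(path, sep="\t", index_label=id_label, float_format="%.12g")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def filter_features(
    expr: pd.DataFrame,
    exclude_ids: set[str] | frozenset[str] = frozenset(),
    detection_floor: float | None = None,
    design: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop excluded features and, optionally, undetected ones.

    A feature passes the detection floor if at least one replicate group
    has all of its replicate values at or above ``detection_floor``.
    Filtering is skipped for the floor when no design is given.

    Returns the filtered matrix and a removal report with columns
    ``feature`` and ``reason``.
    """
    removed: list[tuple[str, str]] = []
    keep = []
    exclude_ids = set(exclude_ids)
    if detection_floor is not None and design is None:
        raise ValueError("detection_floor requires a sample design")

    for fid in expr.index:
        if fid in exclude_ids:
            removed.append((fid, "excluded"))
            continue
        if detection_floor is not None:
            row = expr.loc[fid]
            groups = design.loc[list(expr.columns)].groupby(
                ["tissue", "condition"], sort=False
            )
            detected = any(
                (row[g.index] >= detection_floor).all() for _, g in groups
            )
            if not detected:
                removed.append((fid, "below_detection_floor"))
                continue
        keep.append(fid)

    if not keep:
        raise ValueError("all features removed by filtering")
    report = pd.DataFrame(removed, columns=["feature", "reason"])
    return expr.loc[keep], report


def collapse_replicates_median(
    expr: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicate columns to the per-group median.

    One output column per observed ``(tissue, condition)`` group, named
    ``{tissue}_{condition}``, in order of first appearance. Collapsing
    an already-collapsed matrix is the identity.
    """
    cols: dict[str, pd.Series] = {}
    rows = []
    seen: list[tuple[str, str]] = []
    for sample in expr.columns:
        key = (design.at[sample, "tissue"], design.at[sample, "condition"])
        if key not in seen:
            seen.append(key)
    for tissue, condition in seen:
        members = [
            s
            for s in expr.columns
            if design.at[s, "tissue"] == tissue
            and design.at[s, "condition"] == condition
        ]
        name = f"{tissue}_{condition}"
        cols[name] = expr[members].median(axis=1)
        rows.append({"sample": name, "tissue": tissue, "condition": condition, "replicate": 1})
    collapsed = pd.DataFrame(cols, index=expr.index)
    collapsed_design = pd.DataFrame(rows).set_index("sample")
    return collapsed, collapsed_design


def build_trait_indicators(design: pd.DataFrame) -> pd.DataFrame:
    """Build binary trait indicators over the (collapsed) samples.

    Emits one column per observed ``(condition, tissue)`` combination
    (named ``{condition}_{tissue}``) and one per condition across
    tissues (named ``{condition}``). When both groupings coincide the
    condition-only column is kept once. Constant indicators are kept in
    the output but flagged with a warning; correlation code skips them.
    """
    traits = pd.DataFrame(index=design.index)
    combos = list(
        dict.fromkeys(zip(design["condition"], design["tissue"]))
    )
    for condition, tissue in combos:
        name = f"{condition}_{tissue}"
        traits[name] = (
            (design["condition"] == condition) & (design["tissue"] == tissue)
        ).astype(int)
    for condition in dict.fromkeys(design["condition"]):
        name = str(condition)
        col = (design["condition"] == condition).astype(int)
        # single-tissue designs: condition-only duplicates the combo
        if not any(col.equals(traits[c]) for c in traits.columns):
            traits[name] = col
    for name in traits.columns:
        if traits[name].nunique() < 2:
            warnings.warn(
                f"trait indicator '{name}' is constant and unusable for correlation"
            )
    return traits
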