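"""End-to-end orchestration: prep -> network -> modules -> association
-> enrichment (-> metabolites), driven by a single config with one seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import nitronet
from nitronet import associate, enrich, metabolites, modules, network, prep


@dataclass
class PipelineConfig:
    expression: str
    design: str
    out_dir: str
    exclude: str | None = None
    tf_list: str | None = None
    annotation: str | None = None
    metabolites: str | None = None
    metabolite_design: str | None = None
    beta: int | str = "auto"  # "auto" selects by scale-free fit
    r2_target: float = 0.90
    mode: str = "unsigned"
    min_module_size: int = 30
    merge_threshold: float = 0.65
    gap_fraction: float = 0.0
    n_perm: int = 100_000
    alpha: float = 0.05
    q_cut: float = 0.10
    collapse: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.r2_target <= 1:
            raise ValueError("r2_target must lie in (0, 1]")
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1 or not 0 < self.q_cut <= 1:
            raise ValueError("alpha and q_cut must lie in (0, 1)")
        if self.n_perm < 1 or self.min_module_size < 1:
            raise ValueError("n_perm and min_module_size must be positive")
        for name in ("expression", "design", "exclude", "tf_list", "annotation",
                     "metabolites", "metabolite_design"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage, writing artifacts and a report.

    Returns the run report (also written to ``report.json``); the
    report body is deterministic for a fixed config and seed, with
    timestamps kept in a separate field.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": nitronet.__version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "skipped": [],
    }
    timestamps = {"start": time.time()}

    stage = "prep"
    try:
        expr, design = prep.read_expression(config.expression, config.design)
        n_in = len(expr)
        exclude = set()
        if config.exclude:
            exclude = {
                line.strip()
                for line in Path(config.exclude).read_text().splitlines()
                if line.strip()
            }
        expr, removal = prep.filter_features(expr, exclude_ids=exclude)
        removal.to_csv(out / "removed_features.tsv", sep="\t", index=False)
        if config.collapse:
            expr, design = prep.collapse_replicates_median(expr, design)
        traits = prep.build_trait_indicators(design)
        prep.write_expression(expr, out / "expression_prepped.tsv")
        prep.write_design(design, out / "design_prepped.tsv")
        traits.to_csv(out / "traits.tsv", sep="\t", index_label="sample")
        report["stages"][stage] = {
            "features_in": n_in,
            "features_out": len(expr),
            "samples_out": expr.shape[1],
            "traits": len(traits.columns),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "network"
    try:
        if config.beta == "auto":
            scan = network.soft_threshold_scan(expr, mode=config.mode)
            scan.to_csv(out / "soft_threshold_scan.tsv", sep="\t", index=False)
            beta = network.select_soft_threshold(scan, target=config.r2_target)
        else:
            beta = int(config.beta)
        adj = network.compute_adjacency(expr, beta=beta, mode=config.mode)
        tom = network.compute_tom(adj)
        np.save(out / "tom.npy", tom.matrix)
        (out / "tom.json").write_text(
            json.dumps({"gene_ids": tom.gene_ids, "beta": beta, "mode": config.mode})
        )
        report["stages"][stage] = {
            "beta": beta,
            "n_genes": len(tom.gene_ids),
            "mean_connectivity": float(adj.connectivity.mean()),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "modules"
    try:
        expr_net = expr.loc[tom.gene_ids]
        pre, merged, eigengenes = modules.detect_modules(
            tom.dissimilarity(),
            expr_net,
            min_size=config.min_module_size,
            merge_threshold=config.merge_threshold,
            gap_fraction=config.gap_fraction,
        )
        partition = pd.DataFrame(
            {"gene": expr_net.index, "pre_merge": pre, "merged": merged}
        )
        partition.to_csv(out / "partition.tsv", sep="\t", index=False)
        if len(eigengenes.eigengenes):
            eigengenes.eigengenes.to_csv(
                out / "eigengenes.tsv", sep="\t", index_label="module"
            )
        report["stages"][stage] = {
            "modules_pre_merge": int(len(set(pre) - {0})),
            "modules_merged": int(len(set(merged) - {0})),
            "unassigned_genes": int((merged == 0).sum()),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "association"
    try:
        if not len(eigengenes.eigengenes):
            report["skipped"].append("association: no modules detected")
            mm = None
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trait_table = associate.module_trait_correlation(
                    eigengenes, traits.astype(float)
                )
            trait_table.to_csv(out / "module_trait.tsv", sep="\t", index=False)
            associate.plot_module_trait_heatmap(
                trait_table, str(out / "module_trait_heatmap.png")
            )
            mm = associate.module_membership(expr_net, merged, eigengenes)
            mm.to_csv(out / "module_membership.tsv", sep="\t", index=False)
            n_sig = int((trait_table["p"] < config.alpha).sum())
            report["stages"][stage] = {
                "module_trait_pairs": len(trait_table),
                "significant_pairs": n_sig,
            }
            if config.tf_list:
                tf_set = {
                    line.strip()
                    for line in Path(config.tf_list).read_text().splitlines()
                    if line.strip()
                }
                top = associate.rank_top_tf(mm, tf_set)
                results = {}
                for _, row in top.iterrows():
                    if row["m"] == 0:
                        results[str(row["module"])] = {"status": "no TF in module"}
                        continue
                    res = associate.tf_rank_permutation_test(
                        n=int(row["n"]),
                        m=int(row["m"]),
                        r_obs=int(row["r_obs"]),
                        n_perm=config.n_perm,
                        seed=config.seed,
                    )
                    results[str(row["module"])] = {
                        "gene": row["gene"],
                        **res.as_dict(),
                    }
                (out / "tf_rank.json").write_text(json.dumps(results, indent=2))
                report["stages"][stage]["tf_modules_tested"] = sum(
                    1 for v in results.values() if "mc_p" in v
                )
            else:
                report["skipped"].append("association: TF rank test (no TF list)")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "enrichment"
    if config.annotation and mm is not None:
        try:
            annotation, _ = enrich.read_annotation(config.annotation)
            universe = [g for g in expr_net.index if g in annotation]
            per_module = {}
            tables = []
            for q in sorted(set(merged) - {0}):
                genes = [
                    g
                    for g, lab in zip(expr_net.index, merged)
                    if lab == q and g in annotation
                ]
                if not genes:
                    per_module[int(q)] = 0
                    continue
                table = enrich.fisher_enrichment(
                    genes, annotation, universe, alpha=config.alpha
                )
                table.insert(0, "module", q)
                tables.append(table)
                per_module[int(q)] = int(table["significant"].sum())
            if tables:
                pd.concat(tables, ignore_index=True).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False
                )
            report["stages"][stage] = {"significant_terms_per_module": per_module}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        report["skipped"].append("enrichment: no annotation provided")

    stage = "metabolites"
    if config.metabolites and config.metabolite_design:
        try:
            mat = pd.read_csv(config.metabolites, sep="\t", index_col=0)
            mdesign = pd.read_csv(config.metabolite_design, sep="\t", index_col=0)
            per_tissue = {}
            tables = []
            for tissue in dict.fromkeys(mdesign["tissue"]):
                cmp = metabolites.compare_all(
                    mat,
                    mdesign,
                    tissue=tissue,
                    alpha=config.alpha,
                    q_cut=config.q_cut,
                )
                patterns = metabolites.classify_response(cmp)
                summary = metabolites.pattern_summary(cmp, patterns)
                summary.insert(0, "tissue", tissue)
                tables.append(summary)
                per_tissue[tissue] = {
                    "significant": int(cmp["significant"].sum()),
                    "patterns": patterns.value_counts().to_dict(),
                }
            pd.concat(tables).to_csv(
                out / "metabolite_patterns.tsv", sep="\t", index_label="compound"
            )
            report["stages"][stage] = per_tissue
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        report["skipped"].append("metabolites: no metabolite table provided")

    timestamps["end"] = time.time()
    report_with_time = {**report, "timestamps": timestamps}
    (out / "report.json").write_text(json.dumps(report_with_time, indent=2))
    return report_with_time
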