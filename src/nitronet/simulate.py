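"""Synthetic data with planted ground truth for every pipeline stage.

Expression matrices are built from per-module latent signals: each
planted module's genes are a shared unit-variance signal times a loading
plus Gaussian noise, with the loading chosen so the expected
gene-signal correlation equals ``within_module_cor``. Trait-linked
signals embed a standardized binary design indicator at an exact target
correlation. Metabolite tables are log-normal with group-mean offsets
chosen so expected group ratios equal the planted ratios, and
missingness is left-censored (lowest values masked) to match
minimum-imputation downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_TISSUES = ("leaf", "root")
DEFAULT_CONDITIONS = ("LN", "HN", "induced", "reduced")


def default_design(
    tissues=DEFAULT_TISSUES, conditions=DEFAULT_CONDITIONS, n_replicates: int = 3
) -> list[tuple[str, str, int]]:
    """The study layout: 2 tissues x 4 conditions x 3 replicates."""
    return [
        (t, c, r + 1)
        for t in tissues
        for c in conditions
        for r in range(n_replicates)
    ]


@dataclass
class SyntheticSpec:
    """Parameters of a planted-module expression dataset."""

    n_genes: int
    module_sizes: list[int]
    sample_design: list[tuple[str, str, int]] = field(default_factory=default_design)
    trait_links: dict[int, tuple[str, float]] = field(default_factory=dict)
    within_module_cor: float = 0.9
    noise_sd: float = 1.0
    tf_fraction: float = 0.05
    planted_hub_tf: tuple[int, float] | None = None
    seed: int = 0

    @property
    def n_background_genes(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    def trait_names(self) -> list[str]:
        names = []
        for tissue, condition, _ in self.sample_design:
            combo = f"{condition}_{tissue}"
            if combo not in names:
                names.append(combo)
            if condition not in names:
                names.append(condition)
        return names

    def design_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": f"{t}_{c}_r{r}",
                "tissue": t,
                "condition": c,
                "replicate": r,
            }
            for t, c, r in self.sample_design
        ]
        return pd.DataFrame(rows).set_index("sample")

    def validate(self) -> None:
        if self.n_genes <= 0 or any(s <= 0 for s in self.module_sizes):
            raise ValueError("gene and module counts must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} "
                f"> n_genes = {self.n_genes}"
            )
        if not 0 < self.within_module_cor <= 1:
            raise ValueError("within_module_cor must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.tf_fraction <= 1:
            raise ValueError("tf_fraction must lie in [0, 1]")
        valid_traits = set(self.trait_names())
        for idx, (trait, r) in self.trait_links.items():
            if not 0 <= idx < len(self.module_sizes):
                raise ValueError(f"trait link references unknown module {idx}")
            if trait not in valid_traits:
                raise ValueError(
                    f"trait '{trait}' not derivable from the sample design"
                )
            if not 0 <= r <= 1:
                raise ValueError("target trait correlation must lie in [0, 1]")
        if self.planted_hub_tf is not None:
            idx, rho = self.planted_hub_tf
            if not 0 <= idx < len(self.module_sizes):
                raise ValueError(f"hub TF references unknown module {idx}")
            if not 0 < rho <= 1:
                raise ValueError("hub TF correlation must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside generated data."""

    module_labels: pd.Series | None = None  # gene -> int, 0 = background
    signals: pd.DataFrame | None = None  # module index -> vector over samples
    tf_genes: list[str] = field(default_factory=list)
    hub_gene: str | None = None
    metabolite_ratios: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_labels": None
            if self.module_labels is None
            else self.module_labels.to_dict(),
            "signals": None
            if self.signals is None
            else {str(k): list(v) for k, v in self.signals.iterrows()},
            "tf_genes": self.tf_genes,
            "hub_gene": self.hub_gene,
            "metabolite_ratios": self.metabolite_ratios,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def _trait_indicator(spec: SyntheticSpec, trait: str) -> np.ndarray:
    values = []
    for tissue, condition, _ in spec.sample_design:
        combo = f"{condition}_{tissue}"
        values.append(1.0 if trait in (combo, condition) else 0.0)
    return np.array(values)


def _project_out(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        v = v - (v @ b) / (b @ b) * b
    return v


def _latent_signal(
    spec: SyntheticSpec,
    module_idx: int,
    rng: np.random.Generator,
    n_samples: int,
    previous: list[np.ndarray],
) -> np.ndarray:
    """Unit-variance latent signal, trait-embedded when linked.

    The stochastic part is orthogonalized against earlier module
    signals (while degrees of freedom allow) so distinct planted
    modules stay distinct and are not merged by chance.
    """
    noise = rng.standard_normal(n_samples)
    link = spec.trait_links.get(module_idx)
    basis = list(previous) if len(previous) < n_samples - 2 else []
    if link is None:
        resid = _project_out(noise, basis)
        if resid.std() == 0:
            resid = noise
        return _standardize(resid)
    trait, r = link
    z = _standardize(_trait_indicator(spec, trait))
    e = _project_out(noise, [z] + basis)
    if e.std() == 0:
        e = noise - (noise @ z) / (z @ z) * z
    e = _standardize(e)
    return r * z + np.sqrt(1.0 - r * r) * e  # exactly unit variance, cor r


def generate_expression(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Expression matrix with planted modules; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    design = spec.design_frame()
    samples = list(design.index)
    n_samples = len(samples)
    rho, sigma = spec.within_module_cor, spec.noise_sd

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    labels = np.zeros(spec.n_genes, dtype=int)
    values = np.empty((spec.n_genes, n_samples))
    signals = {}

    def loading(target_cor: float) -> float:
        if sigma == 0 or target_cor >= 1:
            return 1.0
        return sigma * target_cor / np.sqrt(1.0 - target_cor**2)

    pos = 0
    hub_gene = None
    drawn: list[np.ndarray] = []
    for q, size in enumerate(spec.module_sizes):
        signal = _latent_signal(spec, q, rng, n_samples, drawn)
        drawn.append(signal)
        signals[q] = signal
        members = range(pos, pos + size)
        for i in members:
            labels[i] = q + 1
            target = rho
            if spec.planted_hub_tf is not None and spec.planted_hub_tf[0] == q and i == pos:
                target = spec.planted_hub_tf[1]
                hub_gene = gene_ids[i]
            c = loading(target)
            noise = 0.0 if (sigma == 0 or target >= 1) else sigma * rng.standard_normal(n_samples)
            values[i] = c * signal + noise
        pos += size
    for i in range(pos, spec.n_genes):
        values[i] = rng.standard_normal(n_samples)

    n_tf = int(round(spec.tf_fraction * spec.n_genes))
    tf_idx = set(rng.choice(spec.n_genes, size=n_tf, replace=False).tolist())
    if hub_gene is not None:
        tf_idx.add(gene_ids.index(hub_gene))
    tf_genes = sorted(gene_ids[i] for i in tf_idx)

    expr = pd.DataFrame(values, index=gene_ids, columns=samples)
    truth = SyntheticTruth(
        module_labels=pd.Series(labels, index=gene_ids),
        signals=pd.DataFrame(signals, index=samples).T,
        tf_genes=tf_genes,
        hub_gene=hub_gene,
    )
    return expr, truth


def generate_metabolites(
    n_compounds: int,
    group_sizes: dict[str, int],
    planted_ratios: dict | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    sigma: float = 0.2,
    base_mean: float = 1000.0,
    tissue: str = "leaf",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Log-normal abundance table with planted group ratios.

    ``planted_ratios`` maps a compound id (or integer index) to a
    ``{group: ratio}`` map of expected-mean multipliers relative to the
    unlisted baseline groups. Missing cells are left-censored: for each
    compound a binomial number of the lowest values is masked.
    """
    if any(s < 2 for s in group_sizes.values()):
        raise ValueError("every group needs at least 2 samples")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    compounds = [f"c{i:04d}" for i in range(n_compounds)]
    ratios: dict[str, dict[str, float]] = {c: {} for c in compounds}
    for key, val in (planted_ratios or {}).items():
        cid = compounds[key] if isinstance(key, int) else key
        ratios[cid] = dict(val)

    samples, rows = [], []
    for group, size in group_sizes.items():
        for i in range(size):
            sid = f"{tissue}_{group.replace('->', 'to')}_{i + 1}"
            samples.append((sid, group))
            rows.append({"sample": sid, "tissue": tissue, "group": group})
    design = pd.DataFrame(rows).set_index("sample")

    # E[exp(mu + sigma Z)] = exp(mu + sigma^2/2); group-mean offsets of
    # ln(ratio) therefore yield the planted expected-mean ratios exactly
    mu0 = np.log(base_mean) - sigma**2 / 2.0
    values = np.empty((n_compounds, len(samples)))
    for ci, cid in enumerate(compounds):
        for si, (sid, group) in enumerate(samples):
            mu = mu0 + np.log(ratios[cid].get(group, 1.0))
            values[ci, si] = np.exp(mu + sigma * rng.standard_normal())

    mat = pd.DataFrame(values, index=compounds, columns=[s for s, _ in samples])
    if missing_rate > 0:
        n_samples = len(samples)
        for cid in compounds:
            n_miss = min(rng.binomial(n_samples, missing_rate), n_samples - 1)
            if n_miss:
                lowest = mat.loc[cid].nsmallest(n_miss).index
                mat.loc[cid, lowest] = np.nan

    truth = SyntheticTruth(metabolite_ratios=ratios)
    return mat, design, truth


def write_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path,
    metabolite_args: dict | None = None,
) -> dict[str, Path]:
    """Generate and write a full synthetic dataset as TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, truth = generate_expression(spec)
    paths = {
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
        "tf_list": out / "tf_list.txt",
        "truth": out / "truth.json",
    }
    expr.to_csv(paths["expression"], sep="\t", index_label="feature", float_format="%.12g")
    spec.design_frame().to_csv(paths["design"], sep="\t", index_label="sample")
    paths["tf_list"].write_text("\n".join(truth.tf_genes) + "\n")
    if metabolite_args:
        mat, mdesign, mtruth = generate_metabolites(
            seed=spec.seed, **metabolite_args
        )
        paths["metabolites"] = out / "metabolites.tsv"
        paths["metabolite_design"] = out / "metabolite_design.tsv"
        mat.to_csv(paths["metabolites"], sep="\t", index_label="compound", float_format="%.12g")
        mdesign.to_csv(paths["metabolite_design"], sep="\t", index_label="sample")
        truth.metabolite_ratios = mtruth.metabolite_ratios
    truth.to_json(paths["truth"])
    return paths
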