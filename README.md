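# nitronet

Weighted gene co-expression network and metabolite response analysis for
multi-condition (nitrogen limitation / shift) expression experiments, with a
synthetic-data generator that plants recoverable ground truth in every stage.

The pipeline:

1. **prep** — read tab-delimited expression + design tables, filter features,
   collapse replicate groups to medians, build binary condition/tissue trait
   indicators.
2. **network** — correlation-power adjacency `|cor|^β` (signed-magnitude mode
   available), soft-threshold selection by the scale-free topology fit rule
   (last power below the R² target), topological overlap matrix (TOM) and its
   dissimilarity.
3. **modules** — complete-linkage clustering of 1 − TOM, dynamic tree cutting
   with a minimum module size, first-principal-component eigengenes, and
   iterative merging of modules whose eigengenes correlate above a threshold
   (default 0.65).
4. **associate** — eigengene–trait Pearson correlations with Student-t
   p-values, module membership (kME) scores and ranks, and a permutation test
   of the best transcription-factor rank per module (Monte-Carlo, closed-form
   and Wilcoxon signed-rank readings all reported).
5. **enrich** — flat-annotation hypergeometric term enrichment per module with
   Benjamini–Hochberg FDR.
6. **metabolites** — per-compound minimum imputation, Welch two-sample tests
   on natural-log abundances across the HN vs LN / induction / reduction
   contrasts, ratio-of-means fold changes, dual p ≤ 0.05 & q ≤ 0.10
   significance, and response-pattern classification (proportional-HN,
   LN-accumulating, non-proportional-reduction, unchanged, other).

## CLI

Every stage is a subcommand of `nitronet`; `nitronet run` executes them all
from one YAML config with a single seed:

```bash
# generate a synthetic dataset with planted modules, trait link and hub TF
nitronet simulate --config examples/sim.yaml --out data/

# full pipeline
nitronet run --config examples/run.yaml

# or stage by stage
nitronet prep --expr data/expression.tsv --design data/design.tsv --out prep/
nitronet network --expr prep/expression_prepped.tsv --beta auto --out net/
nitronet modules --tom net/tom.npy --expr prep/expression_prepped.tsv --out mod/
nitronet associate --expr prep/expression_prepped.tsv --partition mod/partition.tsv \
    --eigengenes mod/eigengenes.tsv --traits prep/traits.tsv --tf-list data/tf_list.txt --out assoc/
nitronet enrich --partition mod/partition.tsv --annotation go.tsv --out enr/
nitronet metabolites --table data/metabolites.tsv --design data/metabolite_design.tsv --out met/
```

A minimal run config:

```yaml
expression: data/expression.tsv
design: data/design.tsv
tf_list: data/tf_list.txt
out_dir: results/run
beta: auto          # or an integer power
r2_target: 0.90
min_module_size: 30
merge_threshold: 0.65
n_perm: 100000
seed: 1
```

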