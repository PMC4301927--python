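# synthetic dataset: 3 planted modules, one trait-linked, one hub TF
n_genes: 400
module_sizes: [60, 60, 50]
trait_links:
  0: [reduced_leaf, 0.9]
planted_hub_tf: [0, 0.995]
tf_fraction: 0.05
within_module_cor: 0.9
noise_sd: 1.0
seed: 1
metabolites:
  n_compounds: 50
  group_sizes: {LN: 6, HN: 6, LN->HN: 6, HN->LN: 6}
  planted_ratios:
    0: {HN->LN: 8.0}
  missing_rate: 0.1
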