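expression: data/expression.tsv
design: data/design.tsv
tf_list: data/tf_list.txt
metabolites: data/metabolites.tsv
metabolite_design: data/metabolite_design.tsv
out_dir: results/run
beta: 4          # "auto" selects by the scale-free fit rule
r2_target: 0.90
min_module_size: 30
merge_threshold: 0.65
n_perm: 100000
alpha: 0.05
q_cut: 0.10
seed: 1
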