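# Synthetic demonstration run shaped like the curated breast-cancer
# benchmark: 186 samples (176 tumor / 10 normal) x 500 genes with 6
# planted informative genes. Optimizer budgets are reduced from the
# full defaults (20 agents x 100 iterations) so the whole pipeline
# finishes in a couple of minutes; the candidate pool left after the
# t-test screen is small, so the search still converges.
synthetic:
  n_tumor: 176
  n_normal: 10
  n_genes: 500
  n_informative: 6
variance_threshold: 0.01
smote_k: 5
test_fraction: 0.2
mrmr_k: 20
alpha: 0.05
n_agents: 10
max_iter: 15
folds: 10
seed: 0
outdir: genefs_demo_run
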