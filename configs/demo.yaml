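# Small end-to-end demonstration run: synthetic census of 40 species at
# 300 points with a positive specialization effect, 8 perturbed trees.
outdir: results/demo
seed: 7
density_mode: presence
delta_cut: 2.0
stability_trees: 8
sim:
  n_points: 300
  n_species: 40
  n_trees: 8
  ssi_effect: 0.3
  branch_jitter_sd: 0.1
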