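# End-to-end demo: simulate a 3-batch dataset, integrate it, score it.
out_dir: runs/demo
seed: 0
simulate:
  n_cells: 600
  n_genes: 150
  n_batches: 3
  n_cell_types: 4
preprocess:
  n_top: 150
train:
  mode: unsupervised
  epochs: 200
  latent_dim: 10
evaluate:
  baseline_pca: true
  with_kbet: false
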