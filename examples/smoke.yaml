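# End-to-end demonstration settings: a 150 x 20 synthetic panel with a
# planted rank-5 response, and pipeline settings scaled to it (bottlenecked
# autoencoder, pooled Boruta with a lighter forest, single CV repeat).
# Unset keys keep the published defaults (k=20, alpha=0.5, beta=0.1,
# lambda_c=lambda_d=0.5, similarity weights 2/2/2/5/2, threshold=0.4, r=1).
seed: 0
hidden_units: 8
ae_epochs: 400
boruta_mode: pooled
boruta_trees: 100
boruta_max_iter: 15
hmm_restarts: 2
hmm_max_iter: 60
n_signatures: 3
n_folds: 10
n_repeats: 1
synthetic:
  n_cell_lines: 150
  n_drugs: 20
  latent_dim: 5
  noise_sd: 0.3
  n_genes: 100
  n_signal_genes: 30
  n_cnv_features: 60
  n_cnv_signal: 15
  tissues: 4
  missing_frac: 0.1
  n_signatures: 3
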