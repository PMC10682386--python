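# scdreamer-kit

Batch-effect-aware integration of multi-batch single-cell RNA-seq data with
an adversarial variational autoencoder, a semi-supervised extension that
transfers cell-type labels, a ZINB synthetic-data generator with known
ground truth, and the full integration-benchmarking metric suite
(NMI/ARI/ASW, batch ASW, PCR, graph connectivity, kBET, LISI,
isolated-label and composite scores).

It is written for computational biologists who need to merge scRNA-seq
batches from different donors, labs or protocols into one embedding in
which shared cell types mix across batches while distinct cell types stay
separated — and who want every step testable at desk scale on a CPU.

## The model

For cell `i` with raw UMI counts `x_i` and batch `s_i`, the generative
model is

    z_i ~ N(0, I),   l_i ~ LogNormal (per-batch empirical),
    x_ig ~ ZINB( exp(l_i) · softmax(D(z_i, s_i))_g ,  θ_g ,  π_ig )

trained by maximising the evidence lower bound

    ELBO = E_q[log p(x|z,l,s)] − β·KL(q(z|x,s)‖p(z)) − β·KL(q(l|x,s)‖p(l))

Two adversaries shape the embedding: a **discriminator** that separates
real from reconstructed profiles, played against the autoencoder through
the Bhattacharyya distance `−log Σ_i √(P(x_i)·P(x̄_i))` of the two
minibatch probability profiles; and a **batch classifier** on `z` whose
cross-entropy the encoder maximises (the classifier minimises it),
stripping batch information from the embedding.  A consistency penalty
`Σ_j (z_j − ẑ_j)²` ties each cell's embedding to that of the same cell
down-sampled to 80% of its UMIs.

The semi-supervised variant replaces the `N(0, I)` prior on `z` with a
cell-type-conditioned hierarchical prior `p(z|y,c)` learned by a second
autoencoder (`y ~ N(0, I)` captures within-type variability) and adds a
classifier that learns `c` from `z` on the labeled cells; unlabeled cells
receive its predictions.  See `docs/methods.md` for the full account.

All networks run on a small numpy reverse-mode autodiff core included in
the package; training is deterministic given the seed and needs no GPU.

## Worked example

```bash
scdreamer-kit run --config examples/demo.yaml
```

simulates a 600-cell, 150-gene, 3-batch dataset with 4 cell types and a
strong gene-wise batch distortion, trains the integration model for 200
epochs (about half a minute on one CPU core), scores the embedding against
a raw-PCA baseline, and writes `runs/demo/evaluation.json`:

```
model         raw: {'nmi': 1.0, 'ari': 1.0, 'asw_cell_type': 0.79, 'asw_batch': 0.992,
                    'pcr_batch': 0.996, 'graph_connectivity': 1.0, ...}
pca_baseline  raw: {'nmi': 0.718, 'ari': 0.432, 'asw_cell_type': 0.657, 'asw_batch': 0.491,
                    'pcr_batch': 0.624, 'graph_connectivity': 0.39, ...}
```

Reading: Louvain clusters of the integrated embedding match the true cell
types perfectly (NMI = ARI = 1.0) and batches are near-indistinguishable
within each type (batch ASW 0.99, PCR 0.996 means almost no
principal-component variance is explained by batch), whereas raw PCA still
clusters partly by batch (ARI 0.43, batch ASW 0.49).  The run directory
also contains the embedding TSV, a reloadable checkpoint, per-epoch
component losses and a reproducibility manifest; re-running the same
config gives a bit-identical embedding.

Other entry points: `simulate`, `preprocess`, `train` (with
`--ablation {full,woDis,woBC}`), `train-sup`, `predict-labels`,
`evaluate` — see `--help` for options; the YAML schema is documented in
the `run_pipeline` docstring.

Library use mirrors the CLI:

```python
from scdreamer_kit import make_spec, simulate, NetworkConfig, train_unsupervised, encode

ds, truth = simulate(make_spec(seed=0))           # 2000 × 500, 3 batches, 5 types
state = train_unsupervised(ds, NetworkConfig(n_epochs=120, seed=0))
emb = encode(ds, state)                           # posterior means, cells × 10
```

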