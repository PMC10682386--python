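# Methods

## The generative model

Each cell `i` carries raw UMI counts `x_i` over the selected
highly-variable genes and a known batch label `s_i`.  The model assumes a
low-dimensional cell state `z_i ~ N(0, I)` and a log library-size factor
`l_i` with a log-normal prior, and explains the counts through a decoder
conditioned on the batch:

    x_ig ~ ZINB( mu_ig, theta_g, pi_ig ),
    mu_i  = exp(l_i) * softmax( D(z_i, s_i) )

so gene-level proportions come from the decoder, scaled to the cell's
sequencing depth.  The negative binomial is parameterised by mean `mu` and
inverse dispersion `theta` (variance `mu + mu^2/theta`); `theta_g` is a
free per-gene parameter shared across cells (softplus-positive), and the
dropout probability `pi_ig` is a per-gene sigmoid head of the decoder.
`likelihood: nb` drops the zero-inflation component.

The encoder `E(x, s)` returns diagonal-Gaussian posteriors `q(z|x,s)` and
`q(l|x,s)`; internally it sees `log1p(x)` (the likelihood always sees raw
counts — the log transform only conditions the network's input scale).
Training maximises the evidence lower bound

    ELBO = E_q[ log p(x|z,l,s) ] - beta*KL(q(z)||p(z)) - beta*KL(q(l)||p(l))

with a single reparameterised sample per cell per step.  `beta` scales both
KL terms and is warmed up linearly over the first 25% of epochs (a standard
measure against posterior collapse at small data scale; both choices are
configurable).  The library prior `p(l)` is a per-batch empirical
log-normal: mean and variance of log total counts within each batch.

## Adversarial components

Two auxiliary networks push the embedding toward batch-mixed, biologically
faithful solutions:

* **Discriminator.**  A dense network scores `log1p` of real profiles and
  of decoder means.  Its per-cell "real" probabilities for the two
  minibatch profiles, each renormalised to sum to one over the minibatch,
  are compared by the Bhattacharyya distance
  `-log sum_i sqrt(P(x_i) P(xbar_i))`; the discriminator maximises this
  separation while the autoencoder minimises it.  Discriminator logits are
  clamped to [-8, 8] before the sigmoid so a saturated discriminator cannot
  produce an exactly-zero overlap (the loss is additionally capped at
  `-log(1e-12)` for disjoint profiles).
* **Batch classifier.**  A softmax head on `z` trained to predict the
  batch with cross-entropy; the encoder receives the *negated* loss, i.e.
  it maximises the classifier's cross-entropy, removing linearly decodable
  batch signal from the embedding.

Updates alternate per minibatch — (i) encoder/decoder (+ prior networks
and classifier in the supervised variant), (ii) discriminator, (iii) batch
classifier on detached embeddings — each group with its own ADAM optimiser
(lr 1e-3, batch size 128).  The alternating-optimiser formulation is
equivalent to a gradient-reversal layer but easier to test component-wise.
A consistency penalty `sum_j (z_j - zhat_j)^2` ties each cell's posterior
mean to that of the same cell after multinomial down-sampling to 80% of its
UMIs (drawn from the multivariate hypergeometric so the retained total is
exact).  The relative weights of the Bhattacharyya, adversarial and
penalty terms (`lambda_disc`, `lambda_adv`, `lambda_penalty`) default to
1.0 and are exposed in `NetworkConfig`.  Ablations: `woDis` removes the
discriminator game, `woBC` the batch-classifier game.

## Semi-supervised variant

With (possibly partial) cell-type labels `c_i`, the prior on `z` becomes
hierarchical: a latent `y_i ~ N(0, I)` captures within-type variability and
`p(z|y,c) = N(f'_mu(y,c), f'_sigma(y,c))` is produced by a decoder `D_y`,
with `q(y|z,c)` from an encoder `E_y`.  The per-cell bound is

    E_q[log p(x|z,l,s)] - KL(q(z|x,s) || p(z|y,c))      (one y-sample)
    - E_q[KL(q(y|z,c) || N(0,I))] - KL(q(l|x,s) || p(l))

A classifier on `z` is trained with cross-entropy on labeled cells only;
its gradient flows into the encoder by default (`classifier_into_encoder`,
switchable).  Unlabeled cells receive the classifier's current prediction
as `c` — hard argmax refreshed every epoch by default, or a
probability-weighted marginal (`impute: marginal`).  `y` has the same
dimension as `z` unless configured otherwise.  Pinning `E_y`/`D_y` to
`(0, I)` with a single cell type collapses the bound to the flat one; the
test suite verifies this reduction numerically.

## Networks and numerics

All seven networks are dense relu stacks on a small in-package
reverse-mode autodiff engine over numpy (`scdreamer_kit.autodiff`), every
primitive of which is finite-difference gradient-checked in the test
suite.  Defaults: encoder [128, 64] with four linear heads (`mu_z`,
`log sigma_z^2`, `mu_l`, `log sigma_l^2`), decoder [64, 128], discriminator
[64, 32], batch classifier [32], prior networks [32], cell-type classifier
[32]; latent dimension 10.  Log-variances are clamped to [-10, 10], decoder
proportion logits to [-30, 30], dropout logits to [-10, 10] (then scaled by
0.999 to keep `pi < 1`).  A non-finite loss aborts training with the name
of the offending component.  One seed in `NetworkConfig` drives weight
initialisation, minibatch order, UMI thinning and all reparameterisation
draws; reruns are bit-identical, and checkpoints reload to a bit-identical
forward pass.

## Preprocessing

Genes are first restricted to those with a nonzero total count in every
batch.  For ranking only, counts are depth-normalised to the median
per-cell total and log1p-transformed; genes are then scored by
seurat-flavour normalised dispersion (scanpy's implementation: 20
equal-width mean bins, dispersion z-scored within bin) and the top 2000
kept.  Ties are broken by gene id so the selection is invariant to gene
order up to relabeling.  The models always consume raw counts of the
selected genes, as the count likelihood requires.  An optional
`max_mito_fraction` flag drops high-mitochondrial cells; it is off by
default since no universal cutoff exists.

## Synthetic data

The generator draws, per cell: a batch (uniform or per-spec composition),
a type from the batch's composition row, and a log-normal library factor
`l_i` (default log-mean log 3, log-sd 0.3).  The mean factorises as
`mu_ig = l_i * type_means[c,g] * batch_scale[b,g]`: type programs share a
gamma baseline with 10% of genes upregulated 8-fold per type; batch
distortions are gene-wise log-normal factors with log-sd 0.8 — strong
enough that raw PCA separates batches, which is the regime an integration
method must handle.  Counts are gamma-Poisson (NB, default theta 2) with
independent Bernoulli dropout (default 5%) — exactly the observation model
the networks assume.  Type labels are hidden uniformly at random at the
configured rate; the ground truth keeps them.  The benchmark suite covers
a balanced 3-batch fixture, a skewed-composition fixture (one type absent
from one batch), a 20-batch fixture, and a 50%-hidden-labels fixture, all
at 2000 cells x 500 genes / 5 types — sized to train in about two minutes
each on one CPU.

What the generator does *not* emulate: gene-gene correlation within a
type, continuous trajectories, ambient RNA, doublets, or batch effects
that change cell states rather than gene-wise scales.  Passing the
recovery tests therefore shows the estimator works under its own model
assumptions at realistic effect sizes, not that it matches its behaviour
on real tissue atlases.

## Evaluation metrics

Bio-conservation: NMI and ARI against Louvain clusters at the
NMI-maximising resolution (grid 0.1-2.0, step 0.1, kNN graph with k=15; the
same clustering is reused for ARI), and cell-type ASW rescaled by
(ASW+1)/2.  Batch correction: batch ASW (per cell type, `1 - |ASW|` over
batches, unweighted mean over types spanning more than one batch);
principal-component regression (variance-weighted mean over the top 50 PCs
of the R^2 from one-hot-batch regression; reported as the batch-variance
fraction, with a pre/post comparison helper); graph connectivity (mean
largest-connected-component fraction of per-type kNN subgraphs); and kBET
(k=50, per cell type and per connected component, 50 subsamples of 10% of
cells, Pearson chi-squared at alpha=0.05 against the *cell-type-level*
batch proportions, reported as 1 - rejection rate).  Per-cell diagnostics:
iLISI/cLISI (inverse Simpson's index with Gaussian neighbourhood weights
tuned to perplexity 30; Dijkstra distances for graph inputs) and
positive / true-positive percentages (k=20).  Composites min-max scale
each metric across the competing methods and average: bio over
{NMI, ASW, ARI}, batch over {batch ASW, PCR, connectivity, kBET} with kBET
dropped (divisor 3) when unavailable, combined as their mean.  NMI uses
arithmetic-mean entropy normalisation; two trivial single-cluster
partitions define NMI = 1.  Isolated-label scores evaluate every type tied
for fewest batches and average.

Numerical conventions worth noting: the kBET expected frequencies are the
cell-type-level proportions (so a spatially pure component rejects rather
than trivially passing), and the chi-squared approximation is conservative
when k is a sizable fraction of the group (finite-population effect); the
calibration test therefore runs at n=1500 with k=50.

## Known limitations

* Training is CPU-bound numpy; fine at 10^3-10^4 cells, not at atlas scale.
* The Bhattacharyya reading of the discriminator loss (per-cell real
  probabilities renormalised over the minibatch) is one of several
  possible formulations of an adversarial reconstruction critic; it is the
  bounded, trainable one, and the one the loss's printed form implies.
* Exact kNN only (no approximate-neighbour backend); metrics are intended
  for desk-scale embeddings.
* The encoder's adversarial objective maximises the true-class
  cross-entropy, which in principle rewards confidently-wrong batch
  predictions rather than uniform ones; at the default weight this is
  well-behaved, but `lambda_adv` is exposed should it destabilise.
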