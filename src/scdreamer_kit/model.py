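"""Adversarial variational autoencoder for multi-batch integration.

Four networks are trained jointly on raw UMI counts of the highly-variable
genes:

* encoder ``E``: (log1p counts, one-hot batch) -> posterior mean/variance of
  the cell embedding ``z`` and of the log library-size factor ``l``;
* decoder ``D``: (z, batch) -> ZINB parameters of the reconstruction, with
  gene proportions through a softmax scaled by exp(l) and a per-gene
  dispersion shared across cells;
* discriminator: sees log1p of real and reconstructed profiles and is
  trained to separate them; the autoencoder minimises (and the
  discriminator maximises) the Bhattacharyya distance between the two
  minibatch probability profiles, pushing reconstructions toward the data
  distribution;
* batch classifier: predicts the batch from ``z``; it minimises
  cross-entropy while the encoder maximises it, removing batch information
  from the embedding.

A consistency penalty ties the embedding of each cell to the embedding of
the same cell after multinomial down-sampling to 80% of its UMIs.  Updates
alternate per minibatch (autoencoder / discriminator / batch classifier),
each group with its own ADAM optimiser; the KL terms are scaled by ``beta``
with a linear warm-up.  Ablations: ``woDis`` drops the discriminator game,
``woBC`` drops the batch-classifier game.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, relu, sigmoid, softmax, softplus, value
from .data import ExpressionDataset
from .losses import (
    GaussianPosterior,
    ZINBParams,
    batch_cross_entropy,
    bhattacharyya_loss,
    downsample_penalty,
    elbo_unsup,
    multinomial_thin,
)
from .nn import MLP, Adam

logger = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    """Hyperparameters of the integration model (defaults are CPU-scale)."""

    latent_dim: int = 10
    hidden_encoder: tuple = (128, 64)
    hidden_decoder: tuple = (64, 128)
    hidden_disc: tuple = (64, 32)
    hidden_batch: tuple = (32,)
    hidden_prior: tuple = (32,)       # E_y / D_y (supervised variant)
    hidden_classifier: tuple = (32,)  # cell-type classifier
    lr: float = 1e-3
    lr_disc: float = 1e-3
    lr_batch: float = 1e-3
    beta: float = 1.0
    kl_warmup_fraction: float = 0.25
    batch_size: int = 128
    n_epochs: int = 120
    seed: int = 0
    likelihood: str = "zinb"          # "zinb" or "nb"
    ablation: str = "full"            # "full", "woDis", "woBC"
    lambda_adv: float = 1.0           # encoder's batch-adversarial weight
    lambda_disc: float = 1.0          # Bhattacharyya weight in autoencoder loss
    lambda_penalty: float = 1.0       # down-sampling consistency weight
    downsample_rate: float = 0.8
    y_dim: int | None = None          # supervised variant; None -> latent_dim
    lambda_classifier: float = 1.0
    impute: str = "hard"              # unlabeled-cell handling: "hard" or "marginal"
    classifier_into_encoder: bool = True

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if min(self.lr, self.lr_disc, self.lr_batch) <= 0:
            raise ValueError("learning rates must be positive")
        if self.likelihood not in ("zinb", "nb"):
            raise ValueError("likelihood must be 'zinb' or 'nb'")
        if self.ablation not in ("full", "woDis", "woBC"):
            raise ValueError("ablation must be 'full', 'woDis' or 'woBC'")


@dataclass
class LatentEmbedding:
    """Per-cell latent coordinates and posterior parameters."""

    z: np.ndarray
    z_mean: np.ndarray
    z_var: np.ndarray
    l_mean: np.ndarray
    l_var: np.ndarray
    cell_ids: list[str]


def _clip(t: Tensor, lo: float, hi: float) -> Tensor:
    """Differentiable clamp (gradient 1 inside the interval, 0 outside)."""
    return relu(t - lo) - relu(t - hi) + lo


def _one_hot(labels: np.ndarray, categories: list) -> np.ndarray:
    index = {c: j for j, c in enumerate(categories)}
    out = np.zeros((len(labels), len(categories)))
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out


class ModelState:
    """Trained (or initialising) parameter sets plus training history."""

    def __init__(self, cfg: NetworkConfig, n_genes: int, batches: list, gene_ids: list[str],
                 lib_prior: dict):
        self.cfg = cfg
        self.n_genes = n_genes
        self.batches = list(batches)
        self.gene_ids = list(gene_ids)
        self.lib_prior = lib_prior  # batch label -> (mean, var) of log total counts
        self.epoch = 0
        self.loss_history: list[dict] = []
        rng = np.random.default_rng(cfg.seed)
        n_b = len(self.batches)
        d_in = n_genes + n_b
        self.E = MLP(d_in, cfg.hidden_encoder,
                     {"mu_z": cfg.latent_dim, "logvar_z": cfg.latent_dim, "mu_l": 1, "logvar_l": 1},
                     rng, name="E")
        dec_heads = {"rho_logits": n_genes}
        if cfg.likelihood == "zinb":
            dec_heads["pi_logits"] = n_genes
        self.D = MLP(cfg.latent_dim + n_b, cfg.hidden_decoder, dec_heads, rng, name="D")
        self.log_theta = Tensor(np.zeros(n_genes), requires_grad=True)
        self.Disc = MLP(n_genes, cfg.hidden_disc, {"logit": 1}, rng, name="Disc")
        self.B = MLP(cfg.latent_dim, cfg.hidden_batch, {"logits": n_b}, rng, name="B")
        self.rng = rng  # minibatch order, thinning, reparameterisation

    # -- forward pieces ------------------------------------------------
    def encoder_posteriors(self, x_log, s_onehot):
        out = self.E(Tensor._lift(x_log), Tensor._lift(s_onehot))
        q_z = GaussianPosterior(out["mu_z"], ad.exp(_clip(out["logvar_z"], -10.0, 10.0)))
        q_l = GaussianPosterior(out["mu_l"], ad.exp(_clip(out["logvar_l"], -10.0, 10.0)))
        return q_z, q_l

    def decoder_params(self, z, s_onehot, log_l) -> ZINBParams:
        out = self.D(Tensor._lift(z), Tensor._lift(s_onehot))
        rho = softmax(_clip(out["rho_logits"], -30.0, 30.0), axis=-1)
        mu = rho * ad.exp(_clip(Tensor._lift(log_l), -2.0, 15.0)) + 1e-8
        theta = softplus(self.log_theta) + 1e-4
        if self.cfg.likelihood == "zinb":
            pi = sigmoid(_clip(out["pi_logits"], -10.0, 10.0)) * 0.999
        else:
            pi = 0.0
        return ZINBParams(mu=mu, theta=theta, pi=pi)

    def lib_prior_arrays(self, batch_labels: np.ndarray):
        means = np.array([[self.lib_prior[b][0]] for b in batch_labels])
        vars_ = np.array([[self.lib_prior[b][1]] for b in batch_labels])
        return means, vars_

    # -- persistence ---------------------------------------------------
    def _named_arrays(self) -> dict:
        out = {}
        for net in (self.E, self.D, self.Disc, self.B):
            out.update(net.named_parameters())
        out["log_theta"] = self.log_theta.data
        return out

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.cfg),
            "n_genes": self.n_genes,
            "batches": self.batches,
            "gene_ids": self.gene_ids,
            "lib_prior": {str(k): list(v) for k, v in self.lib_prior.items()},
            "epoch": self.epoch,
            "loss_history": self.loss_history,
            "kind": "unsupervised",
        }
        np.savez(path, __meta__=json.dumps(meta), **self._named_arrays())

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(str(path), allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            arrays = {k: f[k] for k in f.files if k != "__meta__"}
        cfg = NetworkConfig(**meta["config"])
        state = cls(cfg, meta["n_genes"], meta["batches"], meta["gene_ids"],
                    {k: tuple(v) for k, v in meta["lib_prior"].items()})
        state.epoch = meta["epoch"]
        state.loss_history = meta["loss_history"]
        for net in (state.E, state.D, state.Disc, state.B):
            net.load_named_parameters(arrays)
        state.log_theta.data = np.asarray(arrays["log_theta"], dtype=np.float64)
        return state


def _library_log_prior(ds: ExpressionDataset) -> dict:
    """Per-batch empirical mean/variance of log total UMI counts."""
    prior = {}
    logtot = np.log(np.maximum(ds.counts.sum(axis=1), 1).astype(np.float64))
    for b in ds.batches:
        vals = logtot[ds.batch == b]
        prior[b] = (float(vals.mean()), float(max(vals.var(), 1e-4)))
    return prior


def _check_finite(loss_val: float, component: str) -> None:
    if not np.isfinite(loss_val):
        raise RuntimeError(f"non-finite loss in {component}; aborting training")


def train_unsupervised(ds: ExpressionDataset, cfg: NetworkConfig) -> ModelState:
    """Train the adversarial VAE on ``ds`` (raw HVG counts).

    Alternates, per minibatch: (i) autoencoder update on
    -ELBO (+ beta-scaled KL inside) + down-sampling penalty
    + Bhattacharyya generator term - lambda_adv * batch cross-entropy;
    (ii) discriminator update maximising the Bhattacharyya separation;
    (iii) batch-classifier update on detached embeddings.  Deterministic
    given ``cfg.seed``.
    """
    state = ModelState(cfg, ds.n_genes, ds.batches, ds.gene_ids, _library_log_prior(ds))
    _run_training(state, ds, cfg)
    return state


def _run_training(state: ModelState, ds: ExpressionDataset, cfg: NetworkConfig,
                  sup_hooks=None) -> None:
    rng = state.rng
    n = ds.n_cells
    x_all = ds.counts
    xlog_all = np.log1p(x_all.astype(np.float64))
    s_all = _one_hot(ds.batch, state.batches)
    prior_m, prior_v = state.lib_prior_arrays(ds.batch)
    n_b = len(state.batches)

    ae_params = state.E.parameters() + state.D.parameters() + [state.log_theta]
    if sup_hooks is not None:
        ae_params = ae_params + sup_hooks.extra_ae_params()
    opt_ae = Adam(ae_params, lr=cfg.lr)
    opt_disc = Adam(state.Disc.parameters(), lr=cfg.lr_disc)
    opt_b = Adam(state.B.parameters(), lr=cfg.lr_batch)

    use_disc = cfg.ablation != "woDis"
    use_bc = cfg.ablation != "woBC" and n_b > 1
    warmup = max(1, int(np.ceil(cfg.kl_warmup_fraction * cfg.n_epochs)))

    for epoch in range(cfg.n_epochs):
        beta_t = cfg.beta * min(1.0, (epoch + 1) / warmup)
        if sup_hooks is not None:
            sup_hooks.refresh_imputation(state, xlog_all, s_all)
        order = rng.permutation(n)
        ep_losses: dict[str, float] = {}
        n_steps = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue
            x, xlog, s = x_all[idx], xlog_all[idx], s_all[idx]
            priors = {"z": (0.0, np.ones(cfg.latent_dim)),
                      "l": (prior_m[idx], prior_v[idx])}

            # ---- (i) autoencoder update -------------------------------
            q_z, q_l = state.encoder_posteriors(xlog, s)
            eps_z = rng.standard_normal(value(q_z.mean).shape)
            eps_l = rng.standard_normal(value(q_l.mean).shape)
            z = q_z.mean + ad.sqrt(q_z.var) * eps_z
            log_l = q_l.mean + ad.sqrt(q_l.var) * eps_l
            dec = state.decoder_params(z, s, log_l)
            if sup_hooks is not None:
                loss_ae, comps = sup_hooks.autoencoder_loss(
                    state, x, s, idx, q_z, q_l, z, dec, priors, beta_t, rng)
            else:
                elbo = elbo_unsup(x, s, {"z": q_z, "l": q_l}, dec, priors, beta=beta_t)
                loss_ae = -elbo
                comps = {"elbo": elbo.item()}

            x_thin = multinomial_thin(x, cfg.downsample_rate, rng)
            q_z_thin, _ = state.encoder_posteriors(np.log1p(x_thin.astype(np.float64)), s)
            pen = downsample_penalty(q_z.mean, q_z_thin.mean)
            loss_ae = loss_ae + cfg.lambda_penalty * pen
            comps["penalty"] = pen.item()

            if use_disc:
                p_real = sigmoid(_clip(state.Disc(Tensor(xlog))["logit"], -8.0, 8.0))
                p_fake = sigmoid(_clip(state.Disc(ad.log(dec.mu + 1.0))["logit"], -8.0, 8.0))
                lb_gen = bhattacharyya_loss(p_real, p_fake)
                loss_ae = loss_ae + cfg.lambda_disc * lb_gen
                comps["bhattacharyya"] = lb_gen.item()
            if use_bc:
                r = softmax(state.B(z)["logits"])
                ce_enc = batch_cross_entropy(s, r)
                loss_ae = loss_ae - cfg.lambda_adv * ce_enc

            _check_finite(loss_ae.item(), "autoencoder")
            opt_ae.zero_grad()
            opt_disc.zero_grad()
            opt_b.zero_grad()
            loss_ae.backward()
            opt_ae.step()

            # ---- (ii) discriminator update ---------------------------
            if use_disc:
                x_bar = value(dec.mu)
                p_real = sigmoid(_clip(state.Disc(Tensor(xlog))["logit"], -8.0, 8.0))
                p_fake = sigmoid(_clip(state.Disc(Tensor(np.log1p(x_bar)))["logit"], -8.0, 8.0))
                loss_d = -bhattacharyya_loss(p_real, p_fake)
                _check_finite(loss_d.item(), "discriminator")
                opt_disc.zero_grad()
                loss_d.backward()
                opt_disc.step()
                comps["disc"] = -loss_d.item()

            # ---- (iii) batch-classifier update -----------------------
            if use_bc:
                r = softmax(state.B(Tensor(value(z)))["logits"])
                loss_b = batch_cross_entropy(s, r)
                _check_finite(loss_b.item(), "batch classifier")
                opt_b.zero_grad()
                loss_b.backward()
                opt_b.step()
                comps["batch_ce"] = loss_b.item()

            if sup_hooks is not None:
                sup_hooks.post_step(state, value(z), idx, rng, comps)

            for k, v in comps.items():
                ep_losses[k] = ep_losses.get(k, 0.0) + v
            n_steps += 1

        state.epoch = epoch + 1
        state.loss_history.append(
            {"epoch": epoch + 1, "beta": beta_t,
             **{k: v / max(n_steps, 1) for k, v in ep_losses.items()}})
        if (epoch + 1) % max(1, cfg.n_epochs // 10) == 0:
            logger.info("epoch %d/%d: %s", epoch + 1, cfg.n_epochs, state.loss_history[-1])


def encode(ds: ExpressionDataset, state: ModelState, chunk: int = 1024) -> LatentEmbedding:
    """Posterior parameters for every cell; deterministic given the state."""
    missing = [g for g in state.gene_ids if g not in set(ds.gene_ids)]
    if ds.gene_ids != state.gene_ids:
        raise ValueError(
            f"gene set does not match training genes (missing or reordered: {missing[:5]}...)")
    xlog = np.log1p(ds.counts.astype(np.float64))
    s = _one_hot(ds.batch, state.batches)
    zm, zv, lm, lv = [], [], [], []
    for start in range(0, ds.n_cells, chunk):
        q_z, q_l = state.encoder_posteriors(xlog[start:start + chunk], s[start:start + chunk])
        zm.append(value(q_z.mean)); zv.append(value(q_z.var))
        lm.append(value(q_l.mean)); lv.append(value(q_l.var))
    z_mean = np.vstack(zm)
    return LatentEmbedding(z=z_mean, z_mean=z_mean, z_var=np.vstack(zv),
                           l_mean=np.vstack(lm), l_var=np.vstack(lv), cell_ids=list(ds.cell_ids))


def decode(z: np.ndarray, s_onehot: np.ndarray, log_l: np.ndarray, state: ModelState) -> ZINBParams:
    """ZINB parameters for given latent coordinates (numpy in, numpy out)."""
    params = state.decoder_params(Tensor(z), Tensor(s_onehot), Tensor(log_l))
    return ZINBParams(mu=value(params.mu), theta=value(params.theta),
                      pi=value(params.pi) if state.cfg.likelihood == "zinb" else 0.0)


def corrected_expression(ds: ExpressionDataset, state: ModelState, reference_batch=None) -> np.ndarray:
    """Decoder means with every cell mapped to one reference batch.

    The batch covariate is set to ``reference_batch`` for all cells and the
    library factor to each cell's posterior mean, yielding batch-corrected
    expression on the raw-count scale.
    """
    if reference_batch is None:
        reference_batch = state.batches[0]
    if reference_batch not in state.batches:
        raise ValueError(f"unknown reference batch '{reference_batch}' (have {state.batches})")
    emb = encode(ds, state)
    s_ref = _one_hot(np.asarray([reference_batch] * ds.n_cells, dtype=object), state.batches)
    out = decode(emb.z_mean, s_ref, emb.l_mean, state)
    return np.asarray(out.mu)
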