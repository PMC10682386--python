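"""Semi-supervised variant: hierarchical prior on z plus a label classifier.

On top of the unsupervised adversarial VAE, the embedding prior becomes
cell-type conditioned: a second autoencoder learns a latent ``y`` capturing
within-type variability (encoder ``E_y``: (z, c) -> q(y|z,c); decoder
``D_y``: (y, c) -> Normal prior parameters for z), and a classifier learns
the type from ``z``, trained with cross-entropy on the cells whose
annotation is observed.  The per-cell evidence lower bound becomes

    E_q[log p(x|z,l,s)] - KL(q(z|x,s) || p(z|y,c))        (y ~ q(y|z,c))
    - E_q[ KL(q(y|z,c) || N(0,I)) ] - KL(q(l|x,s) || p(l))

with the middle expectation estimated by a single reparameterised y-sample.
Cells without an annotation get the classifier's current prediction as
``c`` (hard argmax, refreshed every epoch, or a probability-weighted
marginal).  Discriminator and batch classifier are trained exactly as in
the unsupervised model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, softmax, value
from .data import UNLABELED, ExpressionDataset
from .losses import GaussianPosterior, batch_cross_entropy, kl_diag_gaussian, zinb_log_pmf
from .model import (
    ModelState,
    NetworkConfig,
    _clip,
    _library_log_prior,
    _run_training,
    encode,
)
from .nn import MLP, Adam
from .autodiff import tmean, tsum


@dataclass
class LabelPrediction:
    """Per-cell predicted type, softmax probabilities and observation mask."""

    predicted: np.ndarray
    probabilities: np.ndarray
    was_observed: np.ndarray
    classes: list


class SupState(ModelState):
    """Unsupervised state plus E_y, D_y, the classifier and the label set."""

    def __init__(self, cfg: NetworkConfig, n_genes: int, batches: list, gene_ids: list[str],
                 lib_prior: dict, classes: list):
        super().__init__(cfg, n_genes, batches, gene_ids, lib_prior)
        self.classes = list(classes)
        n_c = len(self.classes)
        y_dim = cfg.y_dim or cfg.latent_dim
        rng = np.random.default_rng(cfg.seed + 1)  # extra nets get their own stream
        self.Ey = MLP(cfg.latent_dim + n_c, cfg.hidden_prior,
                      {"mu_y": y_dim, "logvar_y": y_dim}, rng, name="Ey")
        self.Dy = MLP(y_dim + n_c, cfg.hidden_prior,
                      {"mu_z": cfg.latent_dim, "logvar_z": cfg.latent_dim}, rng, name="Dy")
        self.C = MLP(cfg.latent_dim, cfg.hidden_classifier, {"logits": n_c}, rng, name="C")

    def prior_posterior_y(self, z, c_onehot) -> GaussianPosterior:
        out = self.Ey(Tensor._lift(z), Tensor._lift(c_onehot))
        return GaussianPosterior(out["mu_y"], ad.exp(_clip(out["logvar_y"], -10.0, 10.0)))

    def prior_z_given_yc(self, y, c_onehot):
        out = self.Dy(Tensor._lift(y), Tensor._lift(c_onehot))
        return out["mu_z"], ad.exp(_clip(out["logvar_z"], -10.0, 10.0))

    def classify(self, z) -> np.ndarray:
        return value(softmax(self.C(Tensor._lift(z))["logits"]))

    def _named_arrays(self) -> dict:
        out = super()._named_arrays()
        for net in (self.Ey, self.Dy, self.C):
            out.update(net.named_parameters())
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
            "classes": self.classes,
            "kind": "supervised",
        }
        np.savez(path, __meta__=json.dumps(meta), **self._named_arrays())

    @classmethod
    def load(cls, path) -> "SupState":
        with np.load(str(path), allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            arrays = {k: f[k] for k in f.files if k != "__meta__"}
        cfg = NetworkConfig(**meta["config"])
        state = cls(cfg, meta["n_genes"], meta["batches"], meta["gene_ids"],
                    {k: tuple(v) for k, v in meta["lib_prior"].items()}, meta["classes"])
        state.epoch = meta["epoch"]
        state.loss_history = meta["loss_history"]
        for net in (state.E, state.D, state.Disc, state.B, state.Ey, state.Dy, state.C):
            net.load_named_parameters(arrays)
        state.log_theta.data = np.asarray(arrays["log_theta"], dtype=np.float64)
        return state


def elbo_sup(x, s_onehot, c_onehot, networks: dict, rng: np.random.Generator, beta: float = 1.0):
    """Single-sample estimate of the hierarchical-prior evidence lower bound.

    ``networks`` supplies callables: ``encoder(x, s) -> (q_z, q_l)``,
    ``decoder(z, s, log_l) -> ZINBParams``, ``prior_encoder(z, c) -> q_y``,
    ``prior_decoder(y, c) -> (mean, var)``, and ``lib_prior(row_indices) ->
    (mean, var)`` for the log-library prior.  Returns the minibatch-mean
    ELBO (a Tensor when the networks are differentiable).
    """
    q_z, q_l = networks["encoder"](x, s_onehot)
    eps_z = rng.standard_normal(value(q_z.mean).shape)
    eps_l = rng.standard_normal(value(q_l.mean).shape)
    z = q_z.mean + ad.sqrt(q_z.var) * eps_z
    log_l = q_l.mean + ad.sqrt(q_l.var) * eps_l
    dec = networks["decoder"](z, s_onehot, log_l)
    recon = tsum(zinb_log_pmf(x, dec), axis=-1)

    q_y = networks["prior_encoder"](z, c_onehot)
    eps_y = rng.standard_normal(value(q_y.mean).shape)
    y = q_y.mean + ad.sqrt(q_y.var) * eps_y
    pz_mean, pz_var = networks["prior_decoder"](y, c_onehot)
    kl_z = kl_diag_gaussian(q_z, pz_mean, pz_var)
    y_dim = value(q_y.mean).shape[-1]
    kl_y = kl_diag_gaussian(q_y, 0.0, np.ones(y_dim))
    lp_mean, lp_var = networks["lib_prior"]()
    kl_l = kl_diag_gaussian(q_l, lp_mean, lp_var)
    return tmean(recon - beta * (kl_z + kl_y + kl_l))


class _SupHooks:
    """Plugs the hierarchical prior and classifier into the shared loop."""

    def __init__(self, state: SupState, ds: ExpressionDataset):
        self.state = state
        self.labeled = ds.labeled_mask()
        self.observed_idx = np.array(
            [state.classes.index(c) if c != UNLABELED else -1 for c in ds.cell_type])
        self.c_onehot = np.zeros((ds.n_cells, len(state.classes)))
        obs = self.observed_idx >= 0
        self.c_onehot[np.flatnonzero(obs), self.observed_idx[obs]] = 1.0
        self.opt_c = None if state.cfg.classifier_into_encoder else Adam(
            state.C.parameters(), lr=state.cfg.lr)

    def extra_ae_params(self):
        ps = self.state.Ey.parameters() + self.state.Dy.parameters()
        if self.state.cfg.classifier_into_encoder:
            ps = ps + self.state.C.parameters()
        return ps

    def refresh_imputation(self, state, xlog_all, s_all):
        """Fill unlabeled cells' c with the classifier's current prediction."""
        unl = np.flatnonzero(~self.labeled)
        if unl.size == 0:
            return
        q_z, _ = state.encoder_posteriors(xlog_all[unl], s_all[unl])
        probs = state.classify(value(q_z.mean))
        if state.cfg.impute == "hard":
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(unl)), probs.argmax(axis=1)] = 1.0
            self.c_onehot[unl] = onehot
        else:  # marginal: probability-weighted mixture over classes
            self.c_onehot[unl] = probs

    def autoencoder_loss(self, state, x, s, idx, q_z, q_l, z, dec, priors, beta_t, rng):
        c = self.c_onehot[idx]
        recon = tsum(zinb_log_pmf(x, dec), axis=-1)
        q_y = state.prior_posterior_y(z, c)
        eps_y = rng.standard_normal(value(q_y.mean).shape)
        y = q_y.mean + ad.sqrt(q_y.var) * eps_y
        pz_mean, pz_var = state.prior_z_given_yc(y, c)
        kl_z = kl_diag_gaussian(q_z, pz_mean, pz_var)
        kl_y = kl_diag_gaussian(q_y, 0.0, np.ones(value(q_y.mean).shape[-1]))
        kl_l = kl_diag_gaussian(q_l, *priors["l"])
        elbo = tmean(recon - beta_t * (kl_z + kl_y + kl_l))
        loss = -elbo
        comps = {"elbo": elbo.item()}

        lab = self.labeled[idx]
        if lab.any() and state.cfg.classifier_into_encoder:
            r = softmax(state.C(z)["logits"])
            ce = batch_cross_entropy(c[lab], r[np.flatnonzero(lab)])
            comps["classifier_ce"] = ce.item()
            loss = loss + state.cfg.lambda_classifier * ce
        return loss, comps

    def post_step(self, state, z_val, idx, rng, comps):
        if self.opt_c is None:
            return
        lab = self.labeled[idx]
        if not lab.any():
            return
        r = softmax(state.C(Tensor(z_val[lab]))["logits"])
        ce = batch_cross_entropy(self.c_onehot[idx][lab], r)
        self.opt_c.zero_grad()
        ce.backward()
        self.opt_c.step()
        comps["classifier_ce"] = ce.item()


def train_supervised(ds: ExpressionDataset, cfg: NetworkConfig) -> SupState:
    """Train the semi-supervised model; deterministic given ``cfg.seed``."""
    if ds.cell_type is None or not ds.labeled_mask().any():
        raise ValueError(
            "no labeled cells: the semi-supervised model needs at least some annotations; "
            "use the unsupervised model instead")
    classes = sorted({c for c in ds.cell_type if c != UNLABELED})
    state = SupState(cfg, ds.n_genes, ds.batches, ds.gene_ids, _library_log_prior(ds), classes)
    hooks = _SupHooks(state, ds)
    _run_training(state, ds, cfg, sup_hooks=hooks)
    return state


def predict_labels(ds: ExpressionDataset, state: SupState) -> LabelPrediction:
    """Classifier applied to posterior-mean embeddings; argmax labels."""
    emb = encode(ds, state)
    probs = state.classify(emb.z_mean)
    predicted = np.asarray([state.classes[j] for j in probs.argmax(axis=1)], dtype=object)
    was_observed = ds.labeled_mask()
    return LabelPrediction(predicted=predicted, probabilities=probs,
                           was_observed=was_observed, classes=list(state.classes))
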