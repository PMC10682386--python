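"""Probabilistic building blocks for the integration models.

Closed-form pieces of the training objectives: negative-binomial and
zero-inflated negative-binomial log-pmfs, diagonal-Gaussian KL divergence,
the evidence lower bound of the unsupervised model, the Bhattacharyya
adversarial loss, batch-classifier cross-entropy, and the UMI down-sampling
consistency penalty.

Every function accepts either plain numpy arrays (returning numbers) or
:class:`~scdreamer_kit.autodiff.Tensor` (returning a differentiable node),
so the values asserted in unit tests are computed by the very same code
that the training loop differentiates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, gammaln, log, relu, softplus, sqrt, tmean, tsum, value

logger = logging.getLogger(__name__)

#: guard for -log(0) when discriminator profiles have disjoint support
BHATTACHARYYA_CAP_EPS = 1e-12


@dataclass
class ZINBParams:
    """Per-gene mean, inverse-dispersion and dropout probability.

    ``mu`` and ``theta`` are strictly positive; ``pi`` lies in [0, 1).  The
    NB variance is mu + mu^2/theta, so small theta means strong
    overdispersion; ``pi`` is the extra point mass at zero.
    """

    mu: object
    theta: object
    pi: object = 0.0

    def __post_init__(self):
        mu, theta, pi = value(self.mu), value(self.theta), value(self.pi)
        if np.any(mu <= 0):
            raise ValueError("ZINB mean mu must be strictly positive")
        if np.any(theta <= 0):
            raise ValueError("ZINB dispersion theta must be strictly positive")
        if np.any(pi < 0) or np.any(pi >= 1):
            raise ValueError("ZINB dropout pi must lie in [0, 1)")


@dataclass
class GaussianPosterior:
    """Diagonal-Gaussian posterior parameters (mean and variance)."""

    mean: object
    var: object

    def __post_init__(self):
        if np.any(value(self.var) <= 0):
            raise ValueError("posterior variance must be strictly positive")


def _check_counts(x) -> np.ndarray:
    xv = np.asarray(value(x), dtype=np.float64)
    if np.any(xv < 0):
        raise ValueError("counts must be non-negative")
    if np.any(xv != np.round(xv)):
        raise ValueError("counts must be integral")
    return xv


def nb_log_pmf(x, mu, theta):
    """Log-pmf of the negative binomial with mean ``mu``, dispersion ``theta``.

    log NB(x) = lgamma(x+theta) - lgamma(x+1) - lgamma(theta)
                + theta*log(theta/(theta+mu)) + x*log(mu/(theta+mu)),
    evaluated entirely in log space.
    """
    xv = _check_counts(x)
    log_theta_mu = log(theta + mu)
    return (
        gammaln(xv + theta)
        - gammaln(xv + 1.0)
        - gammaln(theta)
        + theta * (log(theta) - log_theta_mu)
        + xv * (log(mu) - log_theta_mu)
    )


def zinb_log_pmf(x, params: ZINBParams):
    """Log-pmf of the zero-inflated negative binomial.

    log[ pi * 1{x=0} + (1-pi) * NB(x; mu, theta) ], with the x = 0 branch
    computed as a stable log-add-exp; reduces exactly to :func:`nb_log_pmf`
    when pi = 0.
    """
    mu, theta, pi = params.mu, params.theta, params.pi
    if np.any(value(pi) >= 1):
        raise ValueError("pi = 1 is degenerate (all mass at zero)")
    xv = _check_counts(x)
    nb = nb_log_pmf(xv, mu, theta)
    if np.all(value(pi) == 0):
        return nb
    iszero = (xv == 0).astype(np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # log(0) -> -inf is intended
        log_pi = log(pi) if isinstance(pi, Tensor) else np.log(value(pi))
    log_1mpi = log(1.0 - pi)
    nonzero_case = log_1mpi + nb
    # logaddexp(log_pi, nonzero_case) written with softplus so it
    # differentiates through both branches
    zero_case = nonzero_case + softplus(log_pi - nonzero_case)
    return iszero * zero_case + (1.0 - iszero) * nonzero_case


def kl_diag_gaussian(q: GaussianPosterior, p_mean, p_var):
    """KL( N(q.mean, q.var) || N(p_mean, p_var) ) for diagonal Gaussians.

    Summed over the trailing dimension; for 2-D inputs returns one value
    per row (per cell).  Always >= 0, zero iff the distributions coincide.
    """
    q_mean, q_var = q.mean, q.var
    if np.any(value(p_var) <= 0):
        raise ValueError("prior variance must be strictly positive")
    term = 0.5 * (log(p_var) - log(q_var) + (q_var + (q_mean - p_mean) ** 2) / p_var - 1.0)
    return tsum(term, axis=-1)


def elbo_unsup(x, s, encoder_out: dict, decoder_out: ZINBParams, priors: dict, beta: float = 1.0):
    """Evidence lower bound of the unsupervised model, averaged over cells.

    ELBO = E_q[log p(x|z,s,l)] - beta*KL(q(z|x,s)||p(z)) - beta*KL(q(l|x,s)||p(l))

    ``encoder_out`` carries GaussianPosterior entries "z" and "l";
    ``priors`` carries (mean, var) pairs under the same keys.  The
    expectation is the single-reparameterised-sample estimate: the ZINB
    parameters in ``decoder_out`` were produced from one (z, l) draw.
    ``beta`` scales both KL terms.
    """
    recon = tsum(zinb_log_pmf(x, decoder_out), axis=-1)
    kl_z = kl_diag_gaussian(encoder_out["z"], *priors["z"])
    kl_l = kl_diag_gaussian(encoder_out["l"], *priors["l"])
    return tmean(recon - beta * kl_z - beta * kl_l)


def bhattacharyya_loss(p_real, p_fake):
    """Bhattacharyya distance between two minibatch probability profiles.

    Inputs are the discriminator's per-cell "real" probabilities for the
    original and the reconstructed profiles; each is renormalised to sum to
    one over the minibatch, and the loss is -log sum_i sqrt(P_i * Pbar_i).
    Zero iff the normalised profiles coincide; disjoint supports are capped
    at -log(eps) with a warning instead of +inf.
    """
    sr, sf = tsum(p_real), tsum(p_fake)
    if value(sr) <= 0 or value(sf) <= 0:
        raise ValueError("discriminator probability profiles must have positive sums")
    bc = tsum(sqrt((p_real / sr) * (p_fake / sf)))
    if value(bc) <= BHATTACHARYYA_CAP_EPS:
        logger.warning("Bhattacharyya coefficient ~0 (disjoint profiles); capping loss")
    eps = BHATTACHARYYA_CAP_EPS
    return -log(relu(bc - eps) + eps)  # max(bc, eps), exact for bc >= eps


def batch_cross_entropy(s_onehot, r):
    """Cross-entropy -sum_j s_j log r_j of a softmax prediction ``r``.

    ``r`` rows sum to one; probabilities are clamped at 1e-8 before the log
    (a zero at the true class is logged).  2-D inputs return the minibatch
    mean.
    """
    eps = 1e-8
    if np.any((value(r) < eps) & (value(s_onehot) > 0)):
        logger.debug("prediction assigns ~0 probability to a true class; clamping at %g", eps)
    r_safe = relu(r - eps) + eps
    ce = -tsum(s_onehot * log(r_safe), axis=-1)
    return tmean(ce) if value(ce).ndim > 0 else ce


def downsample_penalty(z, z_hat):
    """Squared-distance consistency penalty sum_j (z_j - zhat_j)^2.

    ``z_hat`` is the embedding of the same cell after multinomial thinning
    of its UMI counts; 2-D inputs return the minibatch mean.
    """
    if value(z).shape != value(z_hat).shape:
        raise ValueError("embedding dimensions must match")
    pen = tsum((z - z_hat) ** 2, axis=-1)
    return tmean(pen) if value(pen).ndim > 0 else pen


def multinomial_thin(x: np.ndarray, rate: float = 0.8, rng: np.random.Generator | None = None) -> np.ndarray:
    """Down-sample each cell's UMIs, retaining round(rate * total) counts.

    Draws from the multivariate hypergeometric distribution so the retained
    total is exact (a 100-UMI cell keeps exactly 80 at rate 0.8).
    """
    rng = rng or np.random.default_rng()
    xi = np.asarray(_check_counts(x), dtype=np.int64)
    single = xi.ndim == 1
    xi = np.atleast_2d(xi)
    out = np.empty_like(xi)
    for i, row in enumerate(xi):
        total = int(row.sum())
        keep = int(round(rate * total))
        out[i] = rng.multivariate_hypergeometric(row, keep) if total else row
    return out[0] if single else out
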