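"""Integration-quality metrics: bio-conservation, batch mixing, composites.

Bio-conservation: NMI and ARI against Louvain clusters at the
NMI-maximising resolution, and cell-type average silhouette width (ASW).
Batch correction: batch ASW within cell types, principal-component
regression of batch, graph connectivity of per-type kNN subgraphs, and the
kBET neighbourhood chi-squared test.  Per-cell diagnostics: iLISI/cLISI
(inverse Simpson's index in a perplexity-weighted neighbourhood) and the
positive / true-positive cell proportions.  Composite scores are means of
min-max scaled metrics across competing methods.

Combinatorial primitives (mutual information, adjusted Rand, silhouette,
F1) delegate to scikit-learn; Louvain community detection to igraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import numpy as np
from scipy import sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.stats import chi2
from sklearn.metrics import (
    adjusted_rand_score,
    f1_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

BIO_METRICS = ("nmi", "ari", "asw_cell_type")
BATCH_METRICS = ("asw_batch", "pcr_batch", "graph_connectivity", "kbet")


@dataclass
class EvaluationReport:
    """Raw metric values, min-max scaled values, and composite scores."""

    raw: dict = field(default_factory=dict)
    scaled: dict = field(default_factory=dict)
    composites: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# clustering helpers
# ----------------------------------------------------------------------

def knn_graph(emb: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Symmetric unweighted kNN adjacency (exact Euclidean neighbours)."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(emb))).fit(emb)
    adj = nn.kneighbors_graph(emb, mode="connectivity")
    adj = adj.tolil()
    adj.setdiag(0)
    adj = adj.tocsr()
    adj.eliminate_zeros()
    return ((adj + adj.T) > 0).astype(np.int8)


def _louvain(adj: sp.csr_matrix, resolution: float, seed: int = 0) -> np.ndarray:
    src, dst = adj.nonzero()
    keep = src < dst
    g = igraph.Graph(n=adj.shape[0], edges=list(zip(src[keep], dst[keep])))
    import random as _random

    igraph.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    return np.asarray(part.membership)


def louvain_optimal_nmi(emb: np.ndarray, cell_type: np.ndarray, *, k: int = 15,
                        resolutions: np.ndarray | None = None, seed: int = 0) -> np.ndarray:
    """Louvain labels at the resolution (0.1..2.0 grid) maximising NMI."""
    if len(emb) < 2:
        raise ValueError("need at least 2 cells to cluster")
    if resolutions is None:
        resolutions = np.round(np.arange(0.1, 2.01, 0.1), 2)
    adj = knn_graph(emb, k=k)
    best, best_nmi = None, -1.0
    for res in resolutions:
        labels = _louvain(adj, float(res), seed=seed)
        score = nmi(cell_type, labels)
        if score > best_nmi:
            best, best_nmi = labels, score
    if len(np.unique(best)) == 1:
        logger.warning("Louvain produced a single cluster at every resolution")
    return best


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalised by the arithmetic mean of entropies."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    if len(set(labels_a)) == 1 and len(set(labels_b)) == 1:
        logger.info("both labelings are single-cluster; NMI defined as 1.0")
        return 1.0
    return float(normalized_mutual_info_score(labels_a, labels_b, average_method="arithmetic"))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    return float(adjusted_rand_score(np.asarray(labels_a), np.asarray(labels_b)))


def macro_f1(true_labels, predicted_labels) -> float:
    """Unweighted mean per-class F1 over classes present in the truth."""
    true_labels = np.asarray(true_labels).astype(str)
    classes = sorted(set(true_labels))
    return float(f1_score(true_labels, np.asarray(predicted_labels).astype(str),
                          labels=classes, average="macro", zero_division=0))


# ----------------------------------------------------------------------
# silhouette-based metrics
# ----------------------------------------------------------------------

def asw_cell_type(emb: np.ndarray, cell_type) -> float:
    """Cell-type average silhouette width rescaled to [0, 1] via (ASW+1)/2."""
    cell_type = np.asarray(cell_type)
    if len(set(cell_type)) < 2:
        raise ValueError("need at least 2 cell types for silhouette")
    return float((silhouette_score(emb, cell_type) + 1.0) / 2.0)


def asw_batch(emb: np.ndarray, batch, cell_type) -> float:
    """Batch-mixing silhouette: per cell type, 1 - |ASW over batches|.

    Computed within each cell type with batch as the grouping label, scaled
    so 1 means batches are indistinguishable there; unweighted mean over
    the cell types that contain more than one batch.
    """
    batch, cell_type = np.asarray(batch), np.asarray(cell_type)
    if len(set(batch)) < 2:
        raise ValueError("need at least 2 batches")
    vals = []
    for ct in sorted(set(cell_type)):
        mask = cell_type == ct
        b = batch[mask]
        if len(set(b)) < 2 or mask.sum() <= len(set(b)):
            logger.warning("cell type %s has a single batch (or too few cells); skipped", ct)
            continue
        vals.append(1.0 - abs(float(silhouette_score(emb[mask], b))))
    if not vals:
        raise ValueError("no cell type spans more than one batch")
    return float(np.mean(vals))


def isolated_label_scores(emb: np.ndarray, cell_type, batch, *, k: int = 15,
                          resolutions: np.ndarray | None = None, seed: int = 0) -> tuple[float, float]:
    """(F1, ASW) scores for the cell types present in the fewest batches.

    F1: over a Louvain resolution sweep, the cluster holding the most cells
    of the isolated label is scored as a binary retrieval of that label and
    the best F1 is kept.  ASW: silhouette of the isolated-versus-rest
    bipartition, rescaled to [0, 1].  Ties in batch count are all evaluated
    and averaged.
    """
    cell_type, batch = np.asarray(cell_type), np.asarray(batch)
    if len(set(cell_type)) < 2:
        raise ValueError("need at least 2 cell types")
    if resolutions is None:
        resolutions = np.round(np.arange(0.1, 2.01, 0.1), 2)
    presence = {ct: len(set(batch[cell_type == ct])) for ct in sorted(set(cell_type))}
    fewest = min(presence.values())
    isolated = [ct for ct, n in presence.items() if n == fewest]

    adj = knn_graph(emb, k=k)
    sweep = [_louvain(adj, float(r), seed=seed) for r in resolutions]
    f1s, asws = [], []
    for ct in isolated:
        truth = cell_type == ct
        best_f1 = 0.0
        for labels in sweep:
            counts = np.bincount(labels[truth], minlength=labels.max() + 1)
            cluster = int(np.argmax(counts))
            pred = labels == cluster
            best_f1 = max(best_f1, float(f1_score(truth, pred, zero_division=0)))
        f1s.append(best_f1)
        binary = np.where(truth, "isolated", "rest")
        asws.append((float(silhouette_score(emb, binary)) + 1.0) / 2.0)
    return float(np.mean(f1s)), float(np.mean(asws))


# ----------------------------------------------------------------------
# variance / graph based batch metrics
# ----------------------------------------------------------------------

def pcr_batch(data: np.ndarray, batch, n_pcs: int = 50) -> float:
    """Fraction of principal-component variance explained by batch.

    PCA on the (centred) matrix; for each PC, R^2 from a linear regression
    on one-hot batch; the batch variance contribution is the
    variance-weighted mean of the R^2 values.  Returns the raw fraction in
    [0, 1] (0 = batch explains nothing).
    """
    batch = np.asarray(batch)
    cats = sorted(set(batch))
    if len(cats) < 2:
        raise ValueError("need at least 2 batches")
    X = np.asarray(data, dtype=np.float64)
    X = X - X.mean(axis=0)
    n_pcs = max(1, min(n_pcs, X.shape[1], X.shape[0] - 1))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :n_pcs] * S[:n_pcs]
    var = S[:n_pcs] ** 2 / (len(X) - 1)
    B = np.zeros((len(batch), len(cats)))
    for j, c in enumerate(cats):
        B[batch == c, j] = 1.0
    # R^2 of each PC on one-hot batch = between-group share of its variance
    r2 = np.empty(n_pcs)
    for i in range(n_pcs):
        y = pcs[:, i]
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        tot = ((y - y.mean()) ** 2).sum()
        r2[i] = 0.0 if tot == 0 else 1.0 - (resid**2).sum() / tot
    return float((var * r2).sum() / var.sum())


def pcr_comparison(pre: np.ndarray, post: np.ndarray, batch, n_pcs: int = 50) -> float:
    """Scaled PCR score: fraction of batch variance removed by integration."""
    v_pre = pcr_batch(pre, batch, n_pcs)
    v_post = pcr_batch(post, batch, n_pcs)
    if v_pre == 0:
        return 0.0
    return float(np.clip((v_pre - v_post) / v_pre, 0.0, 1.0))


def graph_connectivity(emb_or_graph, cell_type, k: int = 15) -> float:
    """Mean over cell types of |largest connected component| / |cells|.

    The kNN graph is built over all cells and restricted to each type.
    """
    cell_type = np.asarray(cell_type)
    adj = emb_or_graph if sp.issparse(emb_or_graph) else knn_graph(np.asarray(emb_or_graph), k=k)
    scores = []
    for ct in sorted(set(cell_type)):
        idx = np.flatnonzero(cell_type == ct)
        sub = adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        scores.append(np.bincount(labels).max() / idx.size)
    return float(np.mean(scores))


def _neighbourhood_chi2_reject(neigh_counts: np.ndarray, global_props: np.ndarray,
                               alpha: float) -> bool:
    """Pearson chi-squared test of k neighbourhood batch counts vs global."""
    k = neigh_counts.sum()
    expected = global_props * k
    keep = expected > 0
    stat = ((neigh_counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    dof = max(keep.sum() - 1, 1)
    return stat > chi2.ppf(1 - alpha, dof)


def kbet(emb: np.ndarray, batch, cell_type=None, *, k: int = 50, alpha: float = 0.05,
         n_iterations: int = 50, subsample: float = 0.1, seed: int = 0) -> float:
    """kBET batch-mixing score in [0, 1] (1 = perfect mixing).

    Within each cell type (all cells if ``cell_type`` is None) and each
    connected component of its kNN graph, neighbourhood batch counts of
    randomly subsampled cells are chi-squared tested against the
    component's batch proportions; the score is one minus the mean
    rejection rate.  Components smaller than ``k`` are skipped.
    """
    batch = np.asarray(batch)
    emb = np.asarray(emb)
    if len(emb) <= k:
        raise ValueError(f"need more than k={k} cells")
    rng = np.random.default_rng(seed)
    cats = sorted(set(batch))
    groups = [np.arange(len(emb))] if cell_type is None else [
        np.flatnonzero(np.asarray(cell_type) == ct) for ct in sorted(set(cell_type))]
    rates = []
    for idx in groups:
        if idx.size <= k:
            logger.warning("group of %d cells <= k=%d; skipped", idx.size, k)
            continue
        adj = knn_graph(emb[idx], k=k)
        n_comp, comp = connected_components(adj, directed=False)
        # expected frequencies are the group-level (cell-type) proportions, so
        # a spatially pure component rejects instead of trivially passing
        group_codes = np.searchsorted(cats, batch[idx])
        props = np.bincount(group_codes, minlength=len(cats)) / idx.size
        for ci in range(n_comp):
            cells = idx[comp == ci]
            if cells.size <= k:
                logger.warning("connected component of %d cells <= k=%d; skipped", cells.size, k)
                continue
            sub = emb[cells]
            nn = NearestNeighbors(n_neighbors=min(k + 1, cells.size)).fit(sub)
            _, nbrs = nn.kneighbors(sub)
            nbrs = nbrs[:, 1:]
            b_codes = np.searchsorted(cats, batch[cells])
            rejections = []
            n_sub = max(1, int(round(subsample * cells.size)))
            for _ in range(n_iterations):
                pick = rng.choice(cells.size, size=n_sub, replace=False)
                for c in pick:
                    counts = np.bincount(b_codes[nbrs[c]], minlength=len(cats))
                    rejections.append(_neighbourhood_chi2_reject(counts, props, alpha))
            rates.append((np.mean(rejections), cells.size))
    if not rates:
        raise ValueError("no group large enough for kBET")
    total = sum(nc for _, nc in rates)
    rate = sum(r * nc for r, nc in rates) / total
    return float(1.0 - rate)


# ----------------------------------------------------------------------
# LISI and positive / true-positive cells
# ----------------------------------------------------------------------

def _simpson_per_cell(dist: np.ndarray, nbrs: np.ndarray, codes: np.ndarray,
                      n_cats: int, perplexity: float) -> np.ndarray:
    """Inverse Simpson's index with Gaussian weights tuned to perplexity."""
    n = dist.shape[0]
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        lo, hi = 1e-10, 1e10
        beta = 1.0
        for _ in range(64):  # bisection on precision for entropy == log(perplexity)
            w = np.exp(-d2 * beta)
            s = w.sum()
            if s <= 0:
                entropy = 0.0
            else:
                p = w / s
                entropy = -(p[p > 0] * np.log(p[p > 0])).sum()
            if abs(entropy - target) < 1e-5:
                break
            if entropy > target:
                lo = beta
                beta = beta * 2 if hi >= 1e10 else (beta + hi) / 2
            else:
                hi = beta
                beta = (lo + beta) / 2
        w = np.exp(-d2 * beta)
        p = w / w.sum() if w.sum() > 0 else np.full_like(w, 1.0 / len(w))
        sums = np.bincount(codes[nbrs[i]], weights=p, minlength=n_cats)
        out[i] = 1.0 / np.maximum((sums**2).sum(), 1e-12)
    return out


def lisi(emb_or_graph, labels, *, perplexity: float = 30.0, mode: str = "iLISI") -> np.ndarray:
    """Per-cell local inverse Simpson's index in [1, #labels].

    Neighbourhood label proportions use Gaussian weights with per-cell
    bandwidth tuned to ``perplexity``; embedding inputs use Euclidean kNN
    (3 * perplexity neighbours), sparse-graph inputs use Dijkstra
    shortest-path distances.  ``mode`` is informational (iLISI = batch
    labels, cLISI = cell-type labels).
    """
    labels = np.asarray(labels)
    cats = sorted(set(labels))
    if len(cats) == 1:
        return np.ones(len(labels))
    codes = np.searchsorted(np.asarray(cats, dtype=object), labels)
    k = int(min(3 * perplexity, len(labels) - 1))
    if sp.issparse(emb_or_graph):
        dmat = dijkstra(emb_or_graph.astype(np.float64), directed=False, limit=np.inf)
        np.fill_diagonal(dmat, np.inf)
        nbrs = np.argsort(dmat, axis=1)[:, :k]
        dist = np.take_along_axis(dmat, nbrs, axis=1)
        dist[~np.isfinite(dist)] = 1e6
    else:
        emb = np.asarray(emb_or_graph)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
        dist, nbrs = nn.kneighbors(emb)
        dist, nbrs = dist[:, 1:], nbrs[:, 1:]
    return _simpson_per_cell(dist, nbrs, codes, len(cats), perplexity)


def positive_truepositive(emb: np.ndarray, cell_type, batch, k: int = 20,
                          alpha: float = 0.05) -> tuple[float, float]:
    """Percentages of positive and true-positive cells.

    A cell is positive when all its k nearest neighbours share its type; a
    positive cell is true positive when its neighbourhood batch counts pass
    a chi-squared test against the global batch proportions at ``alpha``.
    """
    cell_type, batch = np.asarray(cell_type), np.asarray(batch)
    emb = np.asarray(emb)
    cats = sorted(set(batch))
    b_codes = np.searchsorted(np.asarray(cats, dtype=object), batch)
    global_props = np.bincount(b_codes, minlength=len(cats)) / len(batch)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, nbrs = nn.kneighbors(emb)
    nbrs = nbrs[:, 1:]
    positive = np.array([np.all(cell_type[nbrs[i]] == cell_type[i]) for i in range(len(emb))])
    if not positive.any():
        return 0.0, 0.0
    tp = 0
    for i in np.flatnonzero(positive):
        counts = np.bincount(b_codes[nbrs[i]], minlength=len(cats))
        if not _neighbourhood_chi2_reject(counts, global_props, alpha):
            tp += 1
    return float(100.0 * positive.mean()), float(100.0 * tp / positive.sum())


# ----------------------------------------------------------------------
# composite scoring
# ----------------------------------------------------------------------

def composite_scores(raw_metrics_by_method: dict) -> dict:
    """Min-max scale each metric across methods and average into composites.

    bio = mean(NMI', ASW_cell_type', ARI'); batch = mean(ASW_batch', PCR',
    GC', kBET') with kBET dropped (divisor 3) when absent; isolated =
    mean(isolated F1', isolated ASW'); combined = (bio + batch) / 2.
    """
    methods = list(raw_metrics_by_method)
    if len(methods) < 2:
        raise ValueError("min-max scaling needs at least 2 methods")
    metric_names = sorted({m for v in raw_metrics_by_method.values() for m in v})
    scaled = {m: {} for m in methods}
    for name in metric_names:
        vals = {m: raw_metrics_by_method[m][name]
                for m in methods if name in raw_metrics_by_method[m]}
        lo, hi = min(vals.values()), max(vals.values())
        for m, v in vals.items():
            scaled[m][name] = 0.0 if hi == lo else (v - lo) / (hi - lo)
    reports = {}
    for m in methods:
        s = scaled[m]
        comps = {}
        if all(k in s for k in BIO_METRICS):
            comps["bio"] = float(np.mean([s[k] for k in BIO_METRICS]))
        batch_keys = [k for k in BATCH_METRICS if k in s]
        if "kbet" not in s:
            batch_keys = [k for k in batch_keys if k != "kbet"]
        if len(batch_keys) >= 3:
            comps["batch"] = float(np.mean([s[k] for k in batch_keys]))
        if "isolated_f1" in s and "isolated_asw" in s:
            comps["isolated"] = float(np.mean([s["isolated_f1"], s["isolated_asw"]]))
        if "bio" in comps and "batch" in comps:
            comps["combined"] = (comps["bio"] + comps["batch"]) / 2.0
        reports[m] = EvaluationReport(raw=dict(raw_metrics_by_method[m]), scaled=s, composites=comps)
    return reports


def evaluate_embedding(emb: np.ndarray, batch, cell_type, *, data_for_pcr: np.ndarray | None = None,
                       k: int = 15, kbet_k: int = 50, pt_k: int = 20, seed: int = 0,
                       with_kbet: bool = True, with_lisi: bool = False) -> dict:
    """All raw metrics for one embedding, as a name -> value dict."""
    batch, cell_type = np.asarray(batch), np.asarray(cell_type)
    clusters = louvain_optimal_nmi(emb, cell_type, k=k, seed=seed)
    out = {
        "nmi": nmi(cell_type, clusters),
        "ari": ari(cell_type, clusters),
        "asw_cell_type": asw_cell_type(emb, cell_type),
        "asw_batch": asw_batch(emb, batch, cell_type),
        "pcr_batch": 1.0 - pcr_batch(data_for_pcr if data_for_pcr is not None else emb, batch),
        "graph_connectivity": graph_connectivity(emb, cell_type, k=k),
    }
    if with_kbet:
        try:
            out["kbet"] = kbet(emb, batch, cell_type, k=kbet_k, seed=seed)
        except ValueError as e:
            logger.warning("kBET unavailable: %s", e)
    f1_iso, asw_iso = isolated_label_scores(emb, cell_type, batch, k=k, seed=seed)
    out["isolated_f1"], out["isolated_asw"] = f1_iso, asw_iso
    if with_lisi:
        out["ilisi_median"] = float(np.median(lisi(emb, batch, mode="iLISI")))
        out["clisi_median"] = float(np.median(lisi(emb, cell_type, mode="cLISI")))
        pos, tpos = positive_truepositive(emb, cell_type, batch, k=pt_k)
        out["pct_positive"], out["pct_true_positive"] = pos, tpos
    return out
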