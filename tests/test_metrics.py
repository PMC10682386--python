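"""Metric suite vs independent brute-force oracles on small instances."""

import numpy as np
import pytest

from scdreamer_kit import metrics as M


# ----------------------------------------------------------------------
# independent oracles (naive implementations, no sklearn/scipy graph calls)
# ----------------------------------------------------------------------

def oracle_nmi(a, b):
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    cats_a, cats_b = sorted(set(a)), sorted(set(b))
    cont = np.zeros((len(cats_a), len(cats_b)))
    for x, y in zip(a, b):
        cont[cats_a.index(x), cats_b.index(y)] += 1
    p = cont / n
    pa, pb = p.sum(1), p.sum(0)
    mi = sum(p[i, j] * np.log(p[i, j] / (pa[i] * pb[j]))
             for i in range(len(cats_a)) for j in range(len(cats_b)) if p[i, j] > 0)
    ha = -sum(q * np.log(q) for q in pa if q > 0)
    hb = -sum(q * np.log(q) for q in pb if q > 0)
    if ha == 0 and hb == 0:
        return 1.0
    return mi / ((ha + hb) / 2)


def oracle_ari(a, b):
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    same_a = np.equal.outer(a, a)
    same_b = np.equal.outer(b, b)
    iu = np.triu_indices(n, 1)
    n11 = np.sum(same_a[iu] & same_b[iu])
    n_pairs = n * (n - 1) / 2
    sum_a = sum(np.sum(a == c) * (np.sum(a == c) - 1) / 2 for c in set(a))
    sum_b = sum(np.sum(b == c) * (np.sum(b == c) - 1) / 2 for c in set(b))
    expected = sum_a * sum_b / n_pairs
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 0.0
    return (n11 - expected) / (maximum - expected)


def oracle_silhouette(emb, labels):
    emb, labels = np.asarray(emb, dtype=float), np.asarray(labels)
    n = len(emb)
    d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            continue  # singleton cluster: silhouette defined as 0
        a = d[i, own & (np.arange(n) != i)].mean()
        b = min(d[i, labels == c].mean() for c in set(labels) if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


def oracle_macro_f1(true, pred):
    true, pred = np.asarray(true), np.asarray(pred)
    f1s = []
    for c in sorted(set(true)):
        tp = np.sum((pred == c) & (true == c))
        fp = np.sum((pred == c) & (true != c))
        fn = np.sum((pred != c) & (true == c))
        f1s.append(0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn))
    return float(np.mean(f1s))


def oracle_connectivity_fraction(adj, idx):
    """Largest-connected-component fraction via union-find on the subgraph."""
    idx = list(idx)
    pos = {v: i for i, v in enumerate(idx)}
    parent = list(range(len(idx)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rows, cols = adj.nonzero()
    for r, c in zip(rows, cols):
        if r in pos and c in pos:
            parent[find(pos[r])] = find(pos[c])
    sizes = {}
    for i in range(len(idx)):
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return max(sizes.values()) / len(idx)


def oracle_lisi(emb, labels, perplexity=30.0):
    emb, labels = np.asarray(emb, dtype=float), np.asarray(labels)
    cats = sorted(set(labels))
    codes = np.array([cats.index(l) for l in labels])
    n = len(emb)
    k = int(min(3 * perplexity, n - 1))
    dmat = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(dmat, np.inf)
    out = np.empty(n)
    for i in range(n):
        nbrs = np.argsort(dmat[i])[:k]
        d2 = dmat[i, nbrs] ** 2
        lo, hi, beta = 1e-10, 1e10, 1.0
        target = np.log(perplexity)
        for _ in range(64):
            w = np.exp(-d2 * beta)
            s = w.sum()
            if s <= 0:
                ent = 0.0
            else:
                p = w / s
                ent = -(p[p > 0] * np.log(p[p > 0])).sum()
            if abs(ent - target) < 1e-5:
                break
            if ent > target:
                lo = beta
                beta = beta * 2 if hi >= 1e10 else (beta + hi) / 2
            else:
                hi = beta
                beta = (lo + beta) / 2
        w = np.exp(-d2 * beta)
        p = w / w.sum()
        props = np.zeros(len(cats))
        for pj, c in zip(p, codes[nbrs]):
            props[c] += pj
        out[i] = 1.0 / max((props ** 2).sum(), 1e-12)
    return out


def random_instance(rng, n=None):
    n = n or rng.integers(30, 120)
    k = rng.integers(2, 6)
    emb = rng.normal(size=(n, rng.integers(2, 6)))
    a = rng.integers(0, k, n).astype(object)
    b = rng.integers(0, k, n).astype(object)
    return emb, a, b


# ----------------------------------------------------------------------
# oracle-equivalence sweeps (>= 50 random instances each)
# ----------------------------------------------------------------------

def test_nmi_matches_entropy_oracle_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(60):
        _, a, b = random_instance(rng)
        assert M.nmi(a, b) == pytest.approx(oracle_nmi(a, b), abs=1e-10)


def test_ari_matches_pair_counting_oracle_on_random_instances():
    rng = np.random.default_rng(2)
    for _ in range(60):
        _, a, b = random_instance(rng)
        assert M.ari(a, b) == pytest.approx(oracle_ari(a, b), abs=1e-10)


def test_macro_f1_matches_confusion_matrix_oracle_on_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(60):
        _, a, b = random_instance(rng)
        assert M.macro_f1(a, b) == pytest.approx(oracle_macro_f1(a, b), abs=1e-10)


def test_cell_type_asw_matches_naive_silhouette_on_random_instances():
    rng = np.random.default_rng(4)
    for _ in range(50):
        emb, a, _ = random_instance(rng, n=60)
        expected = (oracle_silhouette(emb, a).mean() + 1) / 2
        assert M.asw_cell_type(emb, a) == pytest.approx(expected, abs=1e-6)


def test_batch_asw_matches_naive_per_type_silhouette_on_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(50):
        emb, ct, b = random_instance(rng, n=80)
        vals = []
        for c in sorted(set(ct)):
            mask = ct == c
            if len(set(b[mask])) < 2 or mask.sum() <= len(set(b[mask])):
                continue
            vals.append(1 - abs(oracle_silhouette(emb[mask], b[mask]).mean()))
        if not vals:
            continue
        assert M.asw_batch(emb, b, ct) == pytest.approx(np.mean(vals), abs=1e-6)


def test_graph_connectivity_matches_union_find_oracle_on_random_graphs():
    rng = np.random.default_rng(6)
    for _ in range(50):
        emb, ct, _ = random_instance(rng, n=70)
        adj = M.knn_graph(emb, k=4)
        expected = np.mean([
            oracle_connectivity_fraction(adj, np.flatnonzero(ct == c))
            for c in sorted(set(ct))])
        assert M.graph_connectivity(adj, ct) == pytest.approx(expected, abs=1e-10)


def test_lisi_matches_naive_implementation_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(50):
        emb, _, b = random_instance(rng, n=50)
        np.testing.assert_allclose(M.lisi(emb, b), oracle_lisi(emb, b), atol=1e-6)


def test_composites_match_hand_arithmetic():
    raw = {
        "m1": {"nmi": 1.0, "ari": 0.8, "asw_cell_type": 0.9,
               "asw_batch": 0.7, "pcr_batch": 0.6, "graph_connectivity": 1.0, "kbet": 0.9},
        "m2": {"nmi": 0.5, "ari": 0.4, "asw_cell_type": 0.6,
               "asw_batch": 0.9, "pcr_batch": 0.8, "graph_connectivity": 0.8, "kbet": 0.5},
        "m3": {"nmi": 0.0, "ari": 0.0, "asw_cell_type": 0.3,
               "asw_batch": 0.5, "pcr_batch": 0.4, "graph_connectivity": 0.6, "kbet": 0.1},
    }
    reports = M.composite_scores(raw)
    # m1 best on all bio metrics -> bio composite exactly 1
    assert reports["m1"].composites["bio"] == pytest.approx(1.0)
    assert reports["m3"].composites["bio"] == pytest.approx(0.0)
    # hand arithmetic for m2's scaled values
    s2 = reports["m2"].scaled
    assert s2["nmi"] == pytest.approx(0.5)
    assert s2["ari"] == pytest.approx(0.5)
    assert s2["asw_cell_type"] == pytest.approx(0.5)
    assert reports["m2"].composites["bio"] == pytest.approx(0.5)
    assert reports["m2"].composites["batch"] == pytest.approx((1 + 1 + 0.5 + 0.5) / 4)
    for r in reports.values():
        assert r.composites["combined"] == pytest.approx(
            (r.composites["bio"] + r.composites["batch"]) / 2)
        assert all(0 <= v <= 1 for v in r.scaled.values())


def test_composite_drops_kbet_with_divisor_three_when_absent():
    raw = {
        "m1": {"nmi": 1.0, "ari": 1.0, "asw_cell_type": 1.0,
               "asw_batch": 0.9, "pcr_batch": 0.7, "graph_connectivity": 1.0},
        "m2": {"nmi": 0.0, "ari": 0.0, "asw_cell_type": 0.0,
               "asw_batch": 0.3, "pcr_batch": 0.5, "graph_connectivity": 0.4},
    }
    reports = M.composite_scores(raw)
    assert reports["m1"].composites["batch"] == pytest.approx(1.0)
    assert reports["m2"].composites["batch"] == pytest.approx(0.0)


# ----------------------------------------------------------------------
# constructions with known answers
# ----------------------------------------------------------------------

def test_louvain_optimal_clustering_separates_two_blobs():
    rng = np.random.default_rng(8)
    emb = np.vstack([rng.normal(0, 0.2, (60, 2)), rng.normal(8, 0.2, (60, 2))])
    types = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
    clusters = M.louvain_optimal_nmi(emb, types, seed=0)
    assert M.nmi(types, clusters) == pytest.approx(1.0)
    # argmax contract: at least as good as any single fixed resolution
    adj = M.knn_graph(emb, k=15)
    for res in (0.1, 1.0, 2.0):
        fixed = M._louvain(adj, res, seed=0)
        assert M.nmi(types, clusters) >= M.nmi(types, fixed) - 1e-12


def test_single_cluster_against_anything_gives_zero_ari():
    rng = np.random.default_rng(9)
    b = rng.integers(0, 4, 50)
    assert M.ari(np.zeros(50), b) == pytest.approx(0.0, abs=1e-10)


def test_identical_labelings_are_perfect():
    a = np.array(["x", "y", "x", "z"])
    assert M.nmi(a, a) == 1.0
    assert M.ari(a, a) == 1.0
    assert M.macro_f1(a, a) == 1.0


def test_cell_type_asw_hand_example():
    # two pairs 1 apart, clusters 10 apart: a=1, b=(10+sqrt(101))/2 for all
    emb = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    types = np.array(["A", "A", "B", "B"])
    a, b = 1.0, (10.0 + np.sqrt(101.0)) / 2.0
    expected = ((b - a) / b + 1.0) / 2.0
    assert M.asw_cell_type(emb, types) == pytest.approx(expected)


def test_random_types_in_one_blob_give_half_after_scaling():
    rng = np.random.default_rng(10)
    emb = rng.normal(size=(300, 3))
    types = rng.integers(0, 2, 300).astype(object)
    assert M.asw_cell_type(emb, types) == pytest.approx(0.5, abs=0.03)


def test_batch_asw_extremes():
    rng = np.random.default_rng(11)
    # interleaved batches within one type -> ~1
    emb = rng.normal(size=(200, 2))
    batch = np.array(["a", "b"] * 100, dtype=object)
    ct = np.array(["t"] * 200, dtype=object)
    assert M.asw_batch(emb, batch, ct) > 0.95
    # separated batches -> ~0
    emb2 = np.vstack([rng.normal(0, 0.1, (100, 2)), rng.normal(50, 0.1, (100, 2))])
    batch2 = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
    assert M.asw_batch(emb2, batch2, ct) < 0.05


def test_batch_asw_skips_single_batch_cell_type():
    rng = np.random.default_rng(12)
    emb = rng.normal(size=(60, 2))
    batch = np.array(["a", "b"] * 30, dtype=object)
    ct = np.array(["t1"] * 40 + ["t2"] * 20, dtype=object)
    batch[40:] = "a"  # t2 entirely in batch a
    full = M.asw_batch(emb, batch, ct)
    only_t1 = 1 - abs(oracle_silhouette(emb[:40], batch[:40]).mean())
    assert full == pytest.approx(only_t1, abs=1e-6)


class TestPCR:
    def test_independent_batch_explains_nothing(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(300, 20))
        batch = rng.integers(0, 2, 300).astype(object)
        assert M.pcr_batch(X, batch) < 0.03

    def test_batch_equal_to_pc1_sign_contributes_its_share(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(400, 10))
        X[:, 0] *= 20  # dominant first direction
        batch = np.where(X[:, 0] > 0, "a", "b")
        Xc = X - X.mean(0)
        var = np.linalg.svd(Xc, compute_uv=False) ** 2
        share = var[0] / var.sum()
        out = M.pcr_batch(X, batch)
        # R^2 of PC1 on its own sign is ~ (2/pi fraction); bound it loosely
        assert out > 0.5 * share

    def test_r2_matches_anova_between_group_share_on_two_batches(self):
        rng = np.random.default_rng(15)
        y = np.concatenate([rng.normal(0, 1, 100), rng.normal(3, 1, 100)])
        X = y[:, None] + rng.normal(0, 1e-6, (200, 1))  # 1-D data = the PC itself
        batch = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        grand = y.mean()
        ss_between = sum(100 * (y[g].mean() - grand) ** 2
                         for g in (slice(0, 100), slice(100, 200)))
        ss_total = ((y - grand) ** 2).sum()
        assert M.pcr_batch(X, batch, n_pcs=1) == pytest.approx(ss_between / ss_total, abs=1e-4)

    def test_comparison_score_is_one_when_batch_variance_removed(self):
        rng = np.random.default_rng(16)
        pre = np.concatenate([rng.normal(0, 1, (100, 5)) + 5, rng.normal(0, 1, (100, 5))])
        post = rng.normal(size=(200, 5))
        batch = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        assert M.pcr_comparison(pre, post, batch) > 0.9


class TestGraphConnectivity:
    def test_connected_types_score_one(self):
        rng = np.random.default_rng(17)
        emb = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(6, 0.3, (40, 2))])
        ct = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        assert M.graph_connectivity(emb, ct, k=10) == pytest.approx(1.0)

    def test_split_type_contributes_half(self):
        rng = np.random.default_rng(18)
        emb = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(100, 0.1, (30, 2))])
        ct = np.array(["a"] * 60, dtype=object)
        assert M.graph_connectivity(emb, ct, k=5) == pytest.approx(0.5)


class TestKBET:
    def test_separated_batches_score_near_zero(self):
        rng = np.random.default_rng(19)
        emb = np.vstack([rng.normal(0, 0.3, (150, 2)), rng.normal(30, 0.3, (150, 2))])
        batch = np.array(["a"] * 150 + ["b"] * 150, dtype=object)
        assert M.kbet(emb, batch, k=50, n_iterations=10, seed=0) < 0.05

    def test_well_mixed_batches_score_high(self):
        rng = np.random.default_rng(20)
        emb = rng.normal(size=(400, 3))
        batch = rng.choice(["a", "b"], 400).astype(object)
        assert M.kbet(emb, batch, k=50, n_iterations=10, seed=0) > 0.85

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(21)
        emb = rng.normal(size=(200, 2))
        batch = rng.choice(["a", "b"], 200).astype(object)
        assert M.kbet(emb, batch, k=30, seed=5) == M.kbet(emb, batch, k=30, seed=5)


class TestLISIClosedForms:
    def test_single_label_gives_all_ones(self):
        rng = np.random.default_rng(22)
        emb = rng.normal(size=(50, 2))
        np.testing.assert_array_equal(M.lisi(emb, np.zeros(50)), np.ones(50))

    def test_two_equal_mixed_batches_give_median_two(self):
        rng = np.random.default_rng(23)
        emb = rng.normal(size=(400, 3))
        labels = np.tile(["a", "b"], 200).astype(object)
        med = np.median(M.lisi(emb, labels))
        assert med == pytest.approx(2.0, abs=0.15)

    def test_inverse_simpson_closed_form_on_fixed_proportions(self):
        # neighbourhood proportions (0.5, 0.25, 0.25) -> 1/0.375
        assert 1.0 / (0.5**2 + 0.25**2 + 0.25**2) == pytest.approx(8 / 3)


class TestIsolatedLabels:
    def test_pure_isolated_cluster_scores_one(self):
        rng = np.random.default_rng(24)
        emb = np.vstack([rng.normal(0, 0.2, (50, 2)), rng.normal(10, 0.2, (50, 2))])
        ct = np.array(["common"] * 50 + ["rare"] * 50, dtype=object)
        batch = np.array(["b1", "b2"] * 25 + ["b1"] * 50, dtype=object)  # rare only in b1
        f1, asw = M.isolated_label_scores(emb, ct, batch, seed=0)
        assert f1 == pytest.approx(1.0)
        assert asw > 0.9

    def test_scattered_isolated_label_scores_low(self):
        rng = np.random.default_rng(25)
        emb = rng.normal(size=(300, 2))
        ct = np.array(["common"] * 280 + ["rare"] * 20, dtype=object)
        batch = np.array((["b1", "b2"] * 140) + ["b1"] * 20, dtype=object)
        f1, asw = M.isolated_label_scores(emb, ct, batch, seed=0)
        assert f1 < 0.5
        assert asw == pytest.approx(0.5, abs=0.1)


class TestPositiveTruePositive:
    def test_one_type_iid_batches(self):
        rng = np.random.default_rng(26)
        emb = rng.normal(size=(500, 3))
        ct = np.array(["t"] * 500, dtype=object)
        batch = rng.choice(["a", "b"], 500).astype(object)
        pos, tp = M.positive_truepositive(emb, ct, batch, k=20)
        assert pos == pytest.approx(100.0)
        assert tp > 85.0  # ~95% expected at alpha=0.05

    def test_fully_mixed_types_give_no_positives(self):
        rng = np.random.default_rng(27)
        emb = rng.normal(size=(300, 2))
        ct = rng.choice(["t1", "t2"], 300).astype(object)
        batch = rng.choice(["a", "b"], 300).astype(object)
        pos, _ = M.positive_truepositive(emb, ct, batch, k=10)
        assert pos < 5.0

    def test_spatially_segregated_batches_kill_true_positives(self):
        rng = np.random.default_rng(28)
        emb = np.vstack([rng.normal(0, 0.3, (100, 2)), rng.normal(20, 0.3, (100, 2))])
        ct = np.array(["t"] * 200, dtype=object)
        batch = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        pos, tp = M.positive_truepositive(emb, ct, batch, k=10)
        assert pos == pytest.approx(100.0)
        assert tp == pytest.approx(0.0, abs=1.0)


def test_graph_lisi_tracks_embedding_lisi_on_extremes():
    rng = np.random.default_rng(29)
    # well-mixed blob: graph distances also see mixed neighbourhoods
    emb = rng.normal(size=(150, 3))
    labels = np.tile(["a", "b"], 75).astype(object)
    graph = M.knn_graph(emb, k=10)
    g_vals = M.lisi(graph, labels, perplexity=15)
    assert np.all((g_vals >= 1) & (g_vals <= 2 + 1e-9))
    assert np.median(g_vals) > 1.6
    # separated blobs, labels == blob: neighbourhoods pure
    emb2 = np.vstack([rng.normal(0, 0.2, (75, 2)), rng.normal(30, 0.2, (75, 2))])
    labels2 = np.array(["a"] * 75 + ["b"] * 75, dtype=object)
    g2 = M.lisi(M.knn_graph(emb2, k=10), labels2, perplexity=15)
    assert np.median(g2) < 1.1
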