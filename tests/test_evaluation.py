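"""Evaluation suite vs hand-coded brute-force oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from panfuse import evaluation as ev
from panfuse.factorization import EmbeddingSet


def emb(vectors, ids=None, family="f", space="s", normalized=False):
    vectors = np.asarray(vectors, dtype=float)
    ids = ids or [f"e{i}" for i in range(vectors.shape[0])]
    return EmbeddingSet(family=family, space=space, ids=ids,
                        vectors=vectors, normalized=normalized)


# ---------------------------------------------------------------- oracles

def hypergeom_upper_tail_exact(k, N, K, n) -> float:
    """P[X >= k] as an exact rational, X ~ Hypergeom(N, K, n)."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i),
                          math.comb(N, n))
    return float(total)


def bh_adjust_oracle(pvals):
    """Step-up Benjamini-Hochberg by the textbook formula."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, pvals[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


def ari_pair_oracle(a, b):
    """ARI from explicit enumeration of all element pairs."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            ss += 1
        elif sa and not sb:
            sd += 1
        elif not sa and sb:
            ds += 1
        else:
            dd += 1
    total = math.comb(n, 2)
    expected = (ss + sd) * (ss + ds) / total
    max_index = ((ss + sd) + (ss + ds)) / 2
    if max_index == expected:
        return 1.0 if ss == max_index else 0.0
    return (ss - expected) / (max_index - expected)


def auroc_pair_oracle(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def auprc_step_oracle(scores, labels):
    """Step-wise PR integration over unique score thresholds (no
    interpolation), AP = sum (R_i - R_{i-1}) P_i."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    tp = fp = 0
    for s in sorted(set(scores), reverse=True):
        group = labels[scores == s]
        tp += group.sum()
        fp += len(group) - group.sum()
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group
    assignments of the pooled sample (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def ustat(sample_x, sample_y):
        return sum(1 for a in sample_x for b in sample_y if a > b)

    u_obs = ustat(x, y)
    dist = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        dist.append(ustat(gx, gy))
    dist = np.array(dist)
    p_le = np.mean(dist <= u_obs)
    p_ge = np.mean(dist >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def average_linkage_oracle(D, n_clusters):
    """Naive O(n^3) agglomerative clustering, average linkage on the
    original distances (UPGMA); returns the flat partition."""
    clusters = [[i] for i in range(len(D))]
    while len(clusters) > n_clusters:
        best, pair = None, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best:
                best, pair = d, (a, b)
        a, b = pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return clusters


# ----------------------------------------------------------------- tests

class TestNearestCentroid:
    def test_perfect_assignment(self):
        cents = emb(np.eye(3), ids=["A", "B", "C"])
        pats = emb(np.repeat(np.eye(3), 4, axis=0))
        truth = {p: "ABC"[i // 4] for i, p in enumerate(pats.ids)}
        assert ev.nearest_centroid_macro_f1(pats, cents, truth) == 1.0

    def test_hand_enumerated_confusion(self):
        # predictions: A->A, A->B, B->B, B->B
        cents = emb(np.eye(2), ids=["A", "B"])
        pats = emb([[1, 0], [0, 1], [0, 1], [0, 1]],
                   ids=["p1", "p2", "p3", "p4"])
        truth = {"p1": "A", "p2": "A", "p3": "B", "p4": "B"}
        # class A: tp=1 fp=0 fn=1 -> F1=2/3 ; class B: tp=2 fp=1 fn=0 -> F1=4/5
        want = (2 / 3 + 4 / 5) / 2
        got = ev.nearest_centroid_macro_f1(pats, cents, truth)
        assert got == pytest.approx(want, abs=1e-12)

    def test_adversarial_all_wrong_is_zero(self):
        cents = emb(np.eye(2), ids=["A", "B"])
        pats = emb([[0, 1], [1, 0]], ids=["p1", "p2"])
        truth = {"p1": "A", "p2": "B"}
        assert ev.nearest_centroid_macro_f1(pats, cents, truth) == 0.0

    def test_rotation_invariance(self):
        """Cosine geometry is preserved by any common rotation."""
        rng = np.random.default_rng(4)
        cents_v = rng.random((3, 4))
        pats_v = rng.random((20, 4))
        truth = {f"e{i}": "XYZ"[i % 3] for i in range(20)}
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        base = ev.nearest_centroid_macro_f1(
            emb(pats_v), emb(cents_v, ids=["X", "Y", "Z"]), truth)
        rot = ev.nearest_centroid_macro_f1(
            emb(pats_v @ Q), emb(cents_v @ Q, ids=["X", "Y", "Z"]), truth)
        assert base == pytest.approx(rot, abs=1e-9)


class TestKnn:
    def test_duplicate_of_pure_neighborhood(self):
        train = emb(np.vstack([np.tile([1, 0], (5, 1)),
                               np.tile([0, 1], (5, 1))]))
        labels = {f"e{i}": ("L" if i < 5 else "R") for i in range(10)}
        test = emb([[1, 0]], ids=["t"])
        assert ev.knn_macro_f1(train, labels, test, {"t": "L"}, k=5) == 1.0

    def test_k1_equals_nearest_neighbor(self):
        rng = np.random.default_rng(1)
        train = emb(rng.random((15, 3)))
        labels = {f"e{i}": f"c{i % 4}" for i in range(15)}
        test_v = rng.random((8, 3))
        test = emb(test_v, ids=[f"t{i}" for i in range(8)])
        Tn = train.vectors / np.linalg.norm(train.vectors, axis=1)[:, None]
        preds = {}
        for i in range(8):
            v = test_v[i] / np.linalg.norm(test_v[i])
            preds[f"t{i}"] = labels[f"e{np.argmax(Tn @ v)}"]
        assert ev.knn_macro_f1(train, labels, test, preds, k=1) == 1.0

    def test_against_exhaustive_neighbor_oracle(self):
        rng = np.random.default_rng(7)
        train = emb(rng.random((30, 4)))
        labels = {f"e{i}": f"c{i % 3}" for i in range(30)}
        test_v = rng.random((12, 4))
        test = emb(test_v, ids=[f"t{i}" for i in range(12)])
        # oracle: full distance sort, majority with smallest-label ties
        Tn = train.vectors / np.linalg.norm(train.vectors, axis=1)[:, None]
        preds = {}
        for i in range(12):
            v = test_v[i] / np.linalg.norm(test_v[i])
            order = np.argsort(1 - Tn @ v, kind="stable")[:10]
            votes = {}
            for j in order:
                votes[labels[f"e{j}"]] = votes.get(labels[f"e{j}"], 0) + 1
            top = max(votes.values())
            preds[f"t{i}"] = min(l for l, c in votes.items() if c == top)
        assert ev.knn_macro_f1(train, labels, test, preds, k=10) == 1.0

    def test_k_exceeding_train_size(self):
        train = emb(np.eye(3))
        with pytest.raises(ValueError):
            ev.knn_macro_f1(train, {f"e{i}": "x" for i in range(3)},
                            emb(np.eye(3)), {f"e{i}": "x" for i in range(3)},
                            k=5)


class TestHierarchicalClustering:
    def test_two_orthogonal_bundles(self):
        V = np.vstack([np.tile([1, 0.01], (6, 1)), np.tile([0.01, 1], (6, 1))])
        lab = ev.cosine_hierarchical_clusters(emb(V), 2)
        first, second = set(lab.labels[:6]), set(lab.labels[6:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_n_clusters_equals_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        lab = ev.cosine_hierarchical_clusters(emb(rng.random((7, 3))), 7)
        assert len(set(lab.labels)) == 7

    def test_merge_sequence_matches_naive_oracle(self):
        """Flat partitions at every cut level equal the hand-rolled
        O(n^3) average-linkage oracle (unique random distances)."""
        rng = np.random.default_rng(13)
        V = rng.random((12, 4)) + 0.05
        D = ev.cosine_distance_matrix(V)
        for k in range(1, 12):
            lab = ev.cosine_hierarchical_clusters(emb(V), k)
            got = {}
            for i, c in enumerate(lab.labels):
                got.setdefault(c, []).append(i)
            got_parts = {frozenset(v) for v in got.values()}
            want_parts = {frozenset(c)
                          for c in average_linkage_oracle(D, k)}
            assert got_parts == want_parts, f"k={k}"


class TestARI:
    def test_identical_labelings(self):
        a = ev.Labeling(list("abcdef"), [1, 1, 2, 2, 3, 3])
        b = ev.Labeling(list("abcdef"), ["x", "x", "y", "y", "z", "z"])
        assert ev.adjusted_rand_index(a, a) == 1.0
        assert ev.adjusted_rand_index(a, b) == 1.0  # renaming invariance

    def test_degenerate_single_class_is_zero(self):
        a = ev.Labeling(list("abcd"), [1, 1, 1, 1])
        b = ev.Labeling(list("abcd"), [1, 2, 1, 2])
        assert ev.adjusted_rand_index(a, b) == 0.0

    def test_eight_element_pair_enumeration(self):
        a = [1, 1, 2, 2, 2, 3, 3, 1]
        b = [1, 2, 2, 2, 3, 3, 1, 1]
        la = ev.Labeling([f"e{i}" for i in range(8)], a)
        lb = ev.Labeling([f"e{i}" for i in range(8)], b)
        assert ev.adjusted_rand_index(la, lb) == pytest.approx(
            ari_pair_oracle(a, b), abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        ids = [f"e{i}" for i in range(40)]
        a = ev.Labeling(ids, list(rng.integers(0, 4, 40)))
        b = ev.Labeling(ids, list(rng.integers(0, 3, 40)))
        assert ev.adjusted_rand_index(a, b) == pytest.approx(
            ev.adjusted_rand_index(b, a), abs=1e-12)


class TestEnrichment:
    def test_exact_combinatorial_p(self):
        # population 10, term of size 4, cluster of size 5, overlap 3
        ids = [f"g{i}" for i in range(10)]
        clusters = ev.Labeling(ids, [1] * 5 + [2] * 5)
        term = ["g0", "g1", "g2", "g5"]  # overlap 3 with cluster 1
        rep = ev.cluster_enrichment(clusters, {"T": term})
        row = rep.table[(rep.table.cluster == 1) & (rep.table.term == "T")]
        want = hypergeom_upper_tail_exact(3, 10, 4, 5)
        assert row["p"].iloc[0] == pytest.approx(want, abs=1e-10)

    def test_pure_term_cluster_minimizes_p(self):
        ids = [f"g{i}" for i in range(30)]
        labels = [1] * 10 + [2] * 10 + [3] * 10
        clusters = ev.Labeling(ids, labels)
        annotations = {"T1": ids[:10], "T2": ids[12:18], "T3": ids[20:24]}
        rep = ev.cluster_enrichment(clusters, annotations)
        c1 = rep.table[rep.table.cluster == 1].set_index("term")["p"]
        assert c1["T1"] == c1.min()
        assert rep.table["p_adj"].ge(rep.table["p"] - 1e-15).all()

    def test_bh_adjustment_matches_step_up_oracle(self):
        rng = np.random.default_rng(2)
        ids = [f"g{i}" for i in range(40)]
        clusters = ev.Labeling(ids, list(rng.integers(1, 5, 40)))
        annotations = {f"T{j}": list(rng.choice(ids, size=8, replace=False))
                       for j in range(6)}
        rep = ev.cluster_enrichment(clusters, annotations)
        want = bh_adjust_oracle(rep.table["p"].to_numpy())
        np.testing.assert_allclose(rep.table["p_adj"].to_numpy(), want,
                                   atol=1e-10)

    def test_bh_textbook_example(self):
        # raw p (0.01, 0.02, 0.03), m=3 -> adjusted (0.03, 0.03, 0.03)
        np.testing.assert_allclose(bh_adjust_oracle([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-15)
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03], atol=1e-12)


class TestEnrichmentNull:
    def _clusters_and_annotations(self, strong: bool, n=60, k=4):
        ids = [f"g{i}" for i in range(n)]
        if strong:
            labels = [i * k // n for i in range(n)]
        else:
            labels = list(np.random.default_rng(0).integers(0, k, n))
        annotations = {f"T{c}": [ids[i] for i in range(n)
                                 if i * k // n == c] for c in range(k)}
        return ev.Labeling(ids, labels), annotations

    def test_observed_zero_gives_p_one(self):
        clusters, _ = self._clusters_and_annotations(strong=False)
        # annotation orthogonal to any clustering signal
        annotations = {"T": [f"g{i}" for i in range(0, 60, 4)]}
        res = ev.randomized_enrichment_null(clusters, annotations,
                                            n_reps=50, seed=1)
        if res.observed == 0.0:
            assert res.p_value == 1.0

    def test_determinism(self):
        clusters, annotations = self._clusters_and_annotations(strong=True)
        r1 = ev.randomized_enrichment_null(clusters, annotations,
                                           n_reps=100, seed=9)
        r2 = ev.randomized_enrichment_null(clusters, annotations,
                                           n_reps=100, seed=9)
        np.testing.assert_array_equal(r1.null_fractions, r2.null_fractions)

    def test_planted_signal_minimal_p(self):
        clusters, annotations = self._clusters_and_annotations(strong=True)
        res = ev.randomized_enrichment_null(clusters, annotations,
                                            n_reps=200, seed=3)
        assert res.observed == 1.0
        assert res.p_value <= 1 / 201 + 1e-9

    def test_p_never_below_plus_one_floor(self):
        clusters, annotations = self._clusters_and_annotations(strong=True)
        res = ev.randomized_enrichment_null(clusters, annotations,
                                            n_reps=75, seed=5)
        assert res.p_value >= 1 / 76 - 1e-12


class TestMembershipDistances:
    def _geometry(self, intra_d, exo_d):
        """One gene at (1,0); sets at angles giving the wanted cosine
        distances."""
        gene = emb([[1.0, 0.0]], ids=["g"])
        vs = [[1 - d, np.sqrt(1 - (1 - d) ** 2)] for d in intra_d + exo_d]
        sets = emb(vs, ids=[f"s{i}" for i in range(len(vs))])
        membership = {"g": [f"s{i}" for i in range(len(intra_d))]}
        return gene, sets, membership

    def test_exact_small_sample_p(self):
        # intra {0.1, 0.2} vs exo {0.3, 0.4}: U=0, exact two-sided p=1/3
        gene, sets, membership = self._geometry([0.1, 0.2], [0.3, 0.4])
        res = ev.membership_distance_test(gene, sets, membership)
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-10)
        assert res.p_value == pytest.approx(
            mwu_exact_oracle([0.1, 0.2], [0.3, 0.4]), abs=1e-10)

    def test_planted_membership_orders_means(self):
        gene, sets, membership = self._geometry([0.05, 0.1, 0.15],
                                                [0.5, 0.6, 0.7, 0.8])
        res = ev.membership_distance_test(gene, sets, membership)
        assert res.mean_intra < res.mean_exo

    def test_interleaved_distributions_large_p(self):
        # perfectly interleaved samples: U sits near the null mid-range
        d = list(np.linspace(0.2, 0.8, 16))
        gene, sets, membership = self._geometry(d[::2], d[1::2])
        res = ev.membership_distance_test(gene, sets, membership)
        assert res.p_value > 0.5
        assert abs(res.u_statistic - 32) <= 8  # n1*n2/2 = 32


class TestRankingMetrics:
    def test_perfect_separation(self):
        auroc, auprc = ev.ranking_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auroc == 1.0 and auprc == 1.0

    def test_constant_scores(self):
        auroc, _ = ev.ranking_metrics([0.5] * 6, [1, 0, 1, 0, 0, 1])
        assert auroc == 0.5

    def test_ties_match_pair_counting_oracle(self):
        scores = [0.1, 0.4, 0.4, 0.4, 0.35, 0.8, 0.8, 0.2, 0.5, 0.5, 0.3, 0.6]
        labels = [0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 0, 1]
        auroc, auprc = ev.ranking_metrics(scores, labels)
        assert auroc == pytest.approx(auroc_pair_oracle(scores, labels),
                                      abs=1e-10)
        assert auprc == pytest.approx(auprc_step_oracle(scores, labels),
                                      abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.ranking_metrics([0.1, 0.2], [1, 1])


class TestSurvivalSplit:
    def _survival(self, times, events, ids=None):
        ids = ids or [f"p{i}" for i in range(len(times))]
        return pd.DataFrame({"time": times, "event": events}, index=ids)

    def test_identical_survival_statistic_zero(self):
        times = list(range(1, 21)) * 2
        events = [1] * 40
        ids = [f"p{i}" for i in range(40)]
        expr = {f"p{i}": (2.0 if i < 20 else 0.0) for i in range(40)}
        res = ev.survival_split_logrank(expr, self._survival(times, events, ids))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_disjoint_event_times_significant(self):
        times = list(range(1, 21)) + list(range(100, 120))
        events = [1] * 40
        ids = [f"p{i}" for i in range(40)]
        expr = {f"p{i}": (2.0 if i < 20 else 0.0) for i in range(40)}
        res = ev.survival_split_logrank(expr, self._survival(times, events, ids))
        assert res.p_value < 0.01
        assert res.n_high == res.n_low == 20

    def test_value_at_mean_goes_to_lower_group(self):
        # values {1,1,2,2,3,3} -> mean 2; the two patients exactly at the
        # mean join the lower group by convention
        expr = {"p0": 1.0, "p1": 1.0, "p2": 2.0, "p3": 2.0,
                "p4": 3.0, "p5": 3.0}
        surv = self._survival([5, 6, 7, 8, 9, 10], [1, 1, 1, 0, 1, 1])
        res = ev.survival_split_logrank(expr, surv)
        assert res.n_high == 2 and res.n_low == 4

    def test_degenerate_group_rejected(self):
        expr = {"p0": 0.0, "p1": 0.0, "p2": 0.0, "p3": 5.0}
        surv = self._survival([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            ev.survival_split_logrank(expr, surv)
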