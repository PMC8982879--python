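"""Neighbor rule, Top-K hit ratio, ranking metrics, probe, significance."""

import numpy as np
import pytest

import foldgraph as fg
from foldgraph.retrieval import RankingResult


def _ranking(qid, ordered, distances=None):
    if distances is None:
        distances = np.arange(len(ordered), dtype=float)
    return RankingResult(qid, list(ordered), np.asarray(distances, float))


class TestDefineNeighbors:
    def test_threshold_rule(self):
        row = {"a": 0.9, "b": 0.85, "c": 0.3}
        nbr = fg.define_neighbors("q", row, rho=0.9)
        assert nbr.neighbor_ids == {"a", "b"}  # threshold 0.81
        assert nbr.tm_max == pytest.approx(0.9)

    def test_all_equal_scores_all_neighbors(self):
        nbr = fg.define_neighbors("q", {"a": 0.5, "b": 0.5, "c": 0.5})
        assert nbr.neighbor_ids == {"a", "b", "c"}

    def test_rho_one_keeps_only_maximum(self):
        nbr = fg.define_neighbors("q", {"a": 0.9, "b": 0.89}, rho=1.0)
        assert nbr.neighbor_ids == {"a"}

    def test_empty_row_raises(self):
        with pytest.raises(ValueError):
            fg.define_neighbors("q", {})


class TestTopKHitRatio:
    def test_k1_equals_top1_accuracy_on_random_instances(self, rng):
        # Ratio_1 must coincide with plain Top-1 accuracy
        for _ in range(200):
            n_db, n_q = 12, 6
            ids = [f"s{i}" for i in range(n_db)]
            rankings, nbrs, top1_hits = [], [], 0
            for q in range(n_q):
                order = list(rng.permutation(ids))
                neighbor_ids = set(
                    rng.choice(ids, size=rng.integers(1, 5), replace=False)
                )
                rankings.append(_ranking(f"q{q}", order))
                nbrs.append(fg.NeighborSet(f"q{q}", neighbor_ids, 1.0))
                top1_hits += order[0] in neighbor_ids
            ratio1 = fg.topk_hit_ratio(rankings, nbrs, K=1)
            assert ratio1 == pytest.approx(top1_hits / n_q)

    def test_perfect_retrieval_is_one(self):
        r = _ranking("q", ["a", "b", "c", "x", "y"])
        nbr = fg.NeighborSet("q", {"a", "b", "c"}, 1.0)
        assert fg.topk_hit_ratio([r], [nbr], K=10) == pytest.approx(1.0)

    def test_partial_retrieval_two_of_three(self):
        order = ["a", "x1", "b", "x2", "x3", "x4", "x5", "x6", "x7", "x8", "c"]
        r = _ranking("q", order)
        nbr = fg.NeighborSet("q", {"a", "b", "c"}, 1.0)
        assert fg.topk_hit_ratio([r], [nbr], K=10) == pytest.approx(2 / 3)

    def test_bounded_and_nondecreasing_past_neighbor_count(self, rng):
        # the min(K, N_nbr) denominator makes Ratio_K non-monotone while
        # K < N_nbr; once K >= N_nbr it can only grow with K
        ids = [f"s{i}" for i in range(20)]
        r = _ranking("q", rng.permutation(ids))
        nbr = fg.NeighborSet("q", set(rng.choice(ids, 5, replace=False)), 1.0)
        values = [fg.topk_hit_ratio([r], [nbr], K=k) for k in range(1, 21)]
        assert 0.0 <= min(values) and max(values) <= 1.0
        tail = values[4:]  # K >= N_nbr = 5
        assert all(b >= a - 1e-12 for a, b in zip(tail, tail[1:]))
        assert values[-1] == pytest.approx(1.0)  # all neighbors found at K=20

    def test_zero_neighbor_query_excluded_with_warning(self):
        r1 = _ranking("q1", ["a", "b"])
        r2 = _ranking("q2", ["a", "b"])
        nbrs = [fg.NeighborSet("q1", {"a"}, 1.0), fg.NeighborSet("q2", set(), 1.0)]
        with pytest.warns(UserWarning, match="q2"):
            value = fg.topk_hit_ratio([r1, r2], nbrs, K=1)
        assert value == pytest.approx(1.0)


class TestPerQueryRocPr:
    def test_perfect_ranking(self):
        r = _ranking("q", ["a", "b", "x", "y", "z"])
        nbr = fg.NeighborSet("q", {"a", "b"}, 1.0)
        auroc, auprc = fg.per_query_roc_pr([r], [nbr])
        assert auroc == pytest.approx(1.0)
        assert auprc == pytest.approx(1.0)

    def test_inverted_ranking_gives_zero_auroc(self):
        ids = [f"x{i}" for i in range(100)] + ["pos"]
        r = _ranking("q", ids)
        nbr = fg.NeighborSet("q", {"pos"}, 1.0)
        auroc, _ = fg.per_query_roc_pr([r], [nbr])
        assert auroc == pytest.approx(0.0)

    def test_auroc_equals_concordant_pair_count(self, rng):
        # independent O(P*N) pair-counting oracle
        for q in range(20):
            n = 15
            ids = [f"s{i}" for i in range(n)]
            distances = np.sort(rng.uniform(size=n))
            order = list(rng.permutation(ids))
            pos = set(rng.choice(ids, size=rng.integers(1, n - 1), replace=False))
            r = _ranking(f"q{q}", order, distances)
            auroc, _ = fg.per_query_roc_pr([r], [fg.NeighborSet(f"q{q}", pos, 1.0)])
            concordant = 0.0
            scores = {sid: -d for sid, d in zip(order, distances)}
            positives = [s for s in order if s in pos]
            negatives = [s for s in order if s not in pos]
            for p in positives:
                for ng in negatives:
                    if scores[p] > scores[ng]:
                        concordant += 1.0
                    elif scores[p] == scores[ng]:
                        concordant += 0.5
            expected = concordant / (len(positives) * len(negatives))
            assert auroc == pytest.approx(expected, abs=1e-12)

    def test_random_ranking_auroc_near_half(self, rng):
        rankings, nbrs = [], []
        ids = [f"s{i}" for i in range(40)]
        for q in range(300):
            rankings.append(_ranking(f"q{q}", rng.permutation(ids)))
            nbrs.append(
                fg.NeighborSet(f"q{q}", set(rng.choice(ids, 8, replace=False)), 1.0)
            )
        auroc, _ = fg.per_query_roc_pr(rankings, nbrs)
        assert auroc == pytest.approx(0.5, abs=0.03)

    def test_degenerate_query_skipped(self):
        r1 = _ranking("q1", ["a", "b"])
        r2 = _ranking("q2", ["a", "b"])
        nbrs = [fg.NeighborSet("q1", {"a"}, 1.0),
                fg.NeighborSet("q2", {"a", "b"}, 1.0)]
        with pytest.warns(UserWarning, match="degenerate"):
            auroc, _ = fg.per_query_roc_pr([r1, r2], nbrs)
        assert auroc == pytest.approx(1.0)


class TestClassificationProbe:
    def test_separable_classes_high_accuracy(self, rng):
        # two classes generated with a wide margin along one axis
        X = np.vstack([
            rng.normal(loc=+3.0, scale=0.3, size=(30, 8)),
            rng.normal(loc=-3.0, scale=0.3, size=(30, 8)),
        ])
        y = ["pos"] * 30 + ["neg"] * 30
        f1, acc, per_class = fg.classification_probe(X, y, folds=10, seed=0)
        assert acc >= 0.95 and f1 >= 0.95
        assert set(per_class) == {"pos", "neg"}

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.normal(size=(120, 6))
        y = list(rng.permutation(["a", "b", "c"] * 40))
        f1, acc, _ = fg.classification_probe(X, y, folds=5, seed=1)
        assert abs(f1 - 1 / 3) < 0.15  # Monte-Carlo tolerance

    def test_same_seed_identical_report(self, rng):
        X = rng.normal(size=(40, 5))
        y = ["a", "b"] * 20
        r1 = fg.classification_probe(X, y, folds=4, seed=9)
        r2 = fg.classification_probe(X, y, folds=4, seed=9)
        assert r1 == r2

    def test_small_class_reduces_folds_with_warning(self, rng):
        X = rng.normal(size=(13, 4))
        y = ["a"] * 10 + ["b"] * 3
        with pytest.warns(UserWarning, match="reducing folds"):
            fg.classification_probe(X, y, folds=10, seed=0)


class TestSignificanceTest:
    def test_identical_methods_report_no_difference(self):
        metric = {f"q{i}": 0.5 + 0.01 * i for i in range(20)}
        stat, p, name = fg.significance_test(metric, dict(metric), seed=0)
        assert p == 1.0 and name == "identical"

    def test_dominant_method_is_significant(self, rng):
        a = {f"q{i}": 0.9 + rng.normal(0, 0.01) for i in range(30)}
        b = {f"q{i}": 0.3 + rng.normal(0, 0.01) for i in range(30)}
        _, p, name = fg.significance_test(a, b, seed=0)
        assert p < 0.05
        assert name in ("paired t-test", "wilcoxon signed-rank")

    def test_fixed_seed_reproducible(self, rng):
        a = {f"q{i}": float(rng.uniform()) for i in range(16)}
        b = {f"q{i}": float(rng.uniform()) for i in range(16)}
        assert fg.significance_test(a, b, seed=3) == fg.significance_test(a, b, seed=3)

    def test_too_few_queries_rejected(self):
        with pytest.raises(ValueError):
            fg.significance_test({"a": 1.0}, {"a": 0.5})
        with pytest.raises(ValueError, match="same queries"):
            fg.significance_test({"a": 1.0, "b": 1, "c": 1}, {"a": 1.0, "b": 1, "d": 1})
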