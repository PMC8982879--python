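"""Retrieval and classification evaluation protocol.

Ground truth for the ranking task is the structural-neighbor rule: the
neighbors of a query are the database structures whose similarity is at
least ``rho`` (default 0.9) times the query's maximal non-self
similarity.  Rankings are scored by macro-averaged per-query AUROC and
AUPRC and by the Top-K hit ratio

    Ratio_K = (1/N_q) sum_i  N_hit_i / min(K, N_nbr_i),

which reduces to Top-1 accuracy at K = 1 and, unlike Top-K accuracy,
credits finding several neighbors in the top K.  Descriptor quality is
probed with a multinomial logistic regression on fold-class labels under
stratified cross-validation, and method comparisons use a repeated
half-resampling significance test (paired t-test when the paired
differences pass a Shapiro-Wilk normality check, Wilcoxon signed-rank
otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .retrieval import RankingResult

__all__ = [
    "NeighborSet",
    "EvaluationReport",
    "define_neighbors",
    "topk_hit_ratio",
    "per_query_roc_pr",
    "classification_probe",
    "significance_test",
    "evaluate_rankings",
]


@dataclass
class NeighborSet:
    """Structural neighbors of one query under the rho * max rule."""

    query_id: str
    neighbor_ids: set[str]
    tm_max: float


@dataclass
class EvaluationReport:
    avg_auroc: float
    avg_auprc: float
    hit_ratio_at: dict[int, float]
    n_queries: int


def define_neighbors(query_id: str, sim_row: dict[str, float],
                     rho: float = 0.9) -> NeighborSet:
    """Neighbors = {id : score >= rho * max score}, self excluded.

    ``sim_row`` maps database ids (without the query itself) to
    ground-truth similarity.  The arg-max structure is always a neighbor.
    """
    if not sim_row:
        raise ValueError(f"no similarity scores for query {query_id!r}")
    tm_max = max(sim_row.values())
    threshold = rho * tm_max
    return NeighborSet(
        query_id=query_id,
        neighbor_ids={sid for sid, s in sim_row.items() if s >= threshold},
        tm_max=tm_max,
    )


def _paired(rankings: list[RankingResult],
            neighbors: list[NeighborSet]) -> list[tuple[RankingResult, NeighborSet]]:
    by_query = {n.query_id: n for n in neighbors}
    missing = [r.query_id for r in rankings if r.query_id not in by_query]
    if missing:
        raise ValueError(f"no neighbor set for queries {missing[:5]}")
    return [(r, by_query[r.query_id]) for r in rankings]


def topk_hit_ratio(rankings: list[RankingResult],
                   neighbors: list[NeighborSet], K: int) -> float:
    """Mean over queries of N_hit / min(K, N_nbr).

    Queries with zero neighbors are excluded with a warning (the 0.9*max
    rule guarantees at least one neighbor, so this only fires on
    malformed inputs).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    ratios = []
    for ranking, nbr in _paired(rankings, neighbors):
        n_nbr = len(nbr.neighbor_ids)
        if n_nbr == 0:
            warnings.warn(f"query {ranking.query_id} has no neighbors; excluded")
            continue
        hits = sum(1 for sid in ranking.ordered_ids[:K] if sid in nbr.neighbor_ids)
        ratios.append(hits / min(K, n_nbr))
    if not ratios:
        raise ValueError("no evaluable query")
    return float(np.mean(ratios))


def per_query_roc_pr(
    rankings: list[RankingResult], neighbors: list[NeighborSet]
) -> tuple[float, float]:
    """Macro-averaged AUROC and AUPRC over queries.

    The ranking score of a database entry is its negated distance; AUPRC
    uses non-interpolated step integration (average precision).
    Degenerate queries (all entries positive, or none) are skipped with a
    warning.
    """
    aurocs, auprcs = [], []
    for ranking, nbr in _paired(rankings, neighbors):
        labels = np.array(
            [sid in nbr.neighbor_ids for sid in ranking.ordered_ids]
        )
        if labels.all() or not labels.any():
            warnings.warn(f"query {ranking.query_id} is degenerate; skipped")
            continue
        scores = -ranking.distances
        aurocs.append(roc_auc_score(labels, scores))
        auprcs.append(average_precision_score(labels, scores))
    if not aurocs:
        raise ValueError("no evaluable query")
    return float(np.mean(aurocs)), float(np.mean(auprcs))


def evaluate_rankings(
    rankings: list[RankingResult],
    neighbors: list[NeighborSet],
    ks: tuple[int, ...] = (1, 5, 10),
) -> EvaluationReport:
    """Full ranking report: macro AUROC/AUPRC plus Top-K hit ratios."""
    auroc, auprc = per_query_roc_pr(rankings, neighbors)
    return EvaluationReport(
        avg_auroc=auroc,
        avg_auprc=auprc,
        hit_ratio_at={k: topk_hit_ratio(rankings, neighbors, k) for k in ks},
        n_queries=len(rankings),
    )


def classification_probe(
    descriptors: np.ndarray,
    class_labels: list[str],
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, dict[str, float]]:
    """Linear (logistic-regression) probe of descriptor class separability.

    Stratified k-fold cross-validation; predictions pooled over held-out
    folds; returns (macro F1, accuracy, per-class F1).  If the rarest
    class has fewer members than ``folds`` the fold count is reduced with
    a warning.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    y = np.asarray(class_labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    min_count = int(counts.min())
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} members; reducing folds "
            f"from {folds} to {min_count}"
        )
        folds = min_count
    if folds < 2:
        raise ValueError("need at least 2 samples per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    predictions = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(X[train_idx], y[train_idx])
        predictions[test_idx] = clf.predict(X[test_idx])
    macro_f1 = float(f1_score(y, predictions, average="macro"))
    accuracy = float(np.mean(predictions == y))
    per_class = f1_score(y, predictions, average=None, labels=classes)
    return macro_f1, accuracy, {c: float(f) for c, f in zip(classes, per_class)}


def significance_test(
    metric_per_query_a: dict[str, float],
    metric_per_query_b: dict[str, float],
    repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float, str]:
    """Repeated half-resampling comparison of two methods.

    Ten times (by default), half of the queries are sampled without
    replacement and both methods' mean metric on that half is recorded.
    The 10 paired means are compared with a paired t-test when their
    differences pass Shapiro-Wilk normality at alpha = 0.05, otherwise
    with the Wilcoxon signed-rank test.  Identical inputs report
    (0, 1, "identical").
    """
    if set(metric_per_query_a) != set(metric_per_query_b):
        raise ValueError("metric vectors must be keyed by the same queries")
    ids = sorted(metric_per_query_a)
    if len(ids) < 3:
        raise ValueError("need at least 3 queries")
    a = np.array([metric_per_query_a[i] for i in ids])
    b = np.array([metric_per_query_b[i] for i in ids])
    rng = np.random.default_rng(seed)
    half = max(1, len(ids) // 2)
    means_a, means_b = [], []
    for _ in range(repeats):
        pick = rng.choice(len(ids), size=half, replace=False)
        means_a.append(a[pick].mean())
        means_b.append(b[pick].mean())
    diffs = np.array(means_a) - np.array(means_b)
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0, "identical"
    normal = stats.shapiro(diffs).pvalue > 0.05
    if normal:
        res = stats.ttest_rel(means_a, means_b)
        return float(res.statistic), float(res.pvalue), "paired t-test"
    res = stats.wilcoxon(means_a, means_b)
    return float(res.statistic), float(res.pvalue), "wilcoxon signed-rank"
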