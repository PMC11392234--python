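"""Evaluation: repeated stratified cross-validation, ranking metrics,
rank-list aggregation, and score diagnostics.

Reported metrics follow the field's standard protocol for imbalanced
driver-gene benchmarks: repeated stratified k-fold cross-validation
(default ten repeats of 5 folds) with AUC and AUPR computed on the
held-out labeled genes of each fold, i.e. every labeled gene is scored
out-of-fold by the model that did not train on it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .graph import GeneGraph
from .model import ECDCDGIClassifier, ModelConfig

__all__ = [
    "EvaluationReport",
    "cross_validate",
    "auc",
    "aupr",
    "aggregate_rankings",
    "score_skewness",
    "connectivity_correlation",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int)


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form.

    Equals the probability that a uniformly drawn positive outscores a
    uniformly drawn negative, with ties counted 1/2.  Both classes must
    be present.
    """
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (average precision).

    Computed by a descending-score sweep; tied scores are processed as a
    single block.  At least one positive is required.
    """
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("aupr requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class EvaluationReport:
    """Per-(repeat, fold) metrics plus aggregates and out-of-fold scores."""

    auc: np.ndarray              # (repeats, folds)
    aupr: np.ndarray             # (repeats, folds)
    oof_scores: np.ndarray       # (repeats, N) logits, NaN for unlabeled
    node_ids: list[str] = field(default_factory=list)

    @property
    def auc_mean(self) -> float:
        return float(self.auc.mean())

    @property
    def auc_std(self) -> float:
        return float(self.auc.std(ddof=1)) if self.auc.size > 1 else 0.0

    @property
    def aupr_mean(self) -> float:
        return float(self.aupr.mean())

    @property
    def aupr_std(self) -> float:
        return float(self.aupr.std(ddof=1)) if self.aupr.size > 1 else 0.0

    def to_dict(self) -> dict:
        """JSON-ready report with all three aggregation views (per-fold
        values, per-repeat means, and the joint mean over both)."""
        return {
            "auc": {
                "per_fold": self.auc.tolist(),
                "per_repeat_mean": self.auc.mean(axis=1).tolist(),
                "mean": self.auc_mean,
                "std": self.auc_std,
            },
            "aupr": {
                "per_fold": self.aupr.tolist(),
                "per_repeat_mean": self.aupr.mean(axis=1).tolist(),
                "mean": self.aupr_mean,
                "std": self.aupr_std,
            },
            "n_repeats": int(self.auc.shape[0]),
            "n_folds": int(self.auc.shape[1]),
        }


def cross_validate(
    graph: GeneGraph,
    config: ModelConfig | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified k-fold cross-validation over the labeled genes.

    Each repeat reshuffles the stratified fold assignment (seeded); for
    each fold the model trains on the remaining labeled genes (the full
    graph stays visible -- only the loss is masked) and the held-out
    genes are scored by that model.  Metrics use the out-of-fold logits.
    """
    cfg = config or ModelConfig()
    y = graph.y
    labeled_idx = np.flatnonzero(graph.labeled_mask)
    y_lab = y[labeled_idx].astype(int)
    n_pos, n_neg = int(y_lab.sum()), int((1 - y_lab).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"need at least k={k} labeled genes per class, have {n_pos} positive "
            f"and {n_neg} negative"
        )
    rng = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(repeats)]
    aucs = np.empty((repeats, k))
    auprs = np.empty((repeats, k))
    oof = np.full((repeats, graph.n_nodes), np.nan)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seeds[r])
        for f, (tr, te) in enumerate(skf.split(labeled_idx, y_lab)):
            train_nodes = labeled_idx[tr]
            test_nodes = labeled_idx[te]
            mask = np.zeros(graph.n_nodes, dtype=bool)
            mask[train_nodes] = True
            est = ECDCDGIClassifier.from_config(cfg)
            est.set_params(random_state=(fold_seeds[r] * (k + 1) + f) % (2**31 - 1))
            est.fit_graph(graph, train_mask=mask)
            scores = est.decision_function()
            oof[r, test_nodes] = scores[test_nodes]
            aucs[r, f] = auc(scores[test_nodes], y[test_nodes])
            auprs[r, f] = aupr(scores[test_nodes], y[test_nodes])
    return EvaluationReport(auc=aucs, aupr=auprs, oof_scores=oof,
                            node_ids=list(graph.node_ids))


# ---------------------------------------------------------------------------
# rank aggregation


def aggregate_rankings(lists: list[list[str]]) -> list[str]:
    """Borda (mean-rank) aggregation of several ranked gene lists.

    Each gene's aggregate score is its mean 1-based rank across lists; a
    gene missing from a list is assigned rank ``len(list) + 1`` there.
    The output sorts ascending by mean rank, ties broken by ascending
    gene id, and is a permutation of the union universe.
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    universe: set[str] = set()
    for lst in lists:
        universe.update(lst)
    mean_rank: dict[str, float] = {}
    for g in universe:
        ranks = []
        for lst in lists:
            try:
                ranks.append(lst.index(g) + 1)
            except ValueError:
                ranks.append(len(lst) + 1)
        mean_rank[g] = float(np.mean(ranks))
    return sorted(universe, key=lambda g: (mean_rank[g], g))


# ---------------------------------------------------------------------------
# score diagnostics


def score_skewness(scores) -> float:
    """Adjusted Fisher-Pearson sample skewness, g1 * sqrt(n(n-1)) / (n-2).

    Positive values indicate a right tail -- the signature of a scoring
    model that singles out a small set of high-scoring candidate drivers.
    """
    scores = np.asarray(scores, dtype=float)
    if np.unique(scores).size < 3:
        raise ValueError("skewness requires at least 3 distinct values")
    return float(stats.skew(scores, bias=False))


def connectivity_correlation(
    graph: GeneGraph,
    scores,
    known_positive_set,
    candidates=None,
    exact: bool = False,
) -> tuple[float, float]:
    """Spearman correlation of candidate scores with known-driver connectivity.

    For each candidate gene (every scored gene outside the known-positive
    set unless ``candidates`` is given), counts its direct neighbors that
    are known positives, then correlates those counts with the genes'
    prediction scores (average-rank tie handling).  The p-value uses the
    large-sample t approximation; with ``exact=True`` and at most 10
    candidates it is computed by full permutation enumeration instead.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != graph.n_nodes:
        raise ValueError("scores must cover every node")
    known_idx = np.array(sorted(graph.index[g] for g in known_positive_set), dtype=int)
    if candidates is None:
        cand_idx = np.setdiff1d(np.arange(graph.n_nodes), known_idx)
    else:
        cand_idx = np.array(sorted(graph.index[g] for g in candidates), dtype=int)
    if cand_idx.size < 3:
        raise ValueError("need at least 3 candidate genes")
    sub = graph.A[cand_idx][:, known_idx] if known_idx.size else None
    counts = (np.asarray(sub.sum(axis=1)).ravel() if sub is not None
              else np.zeros(cand_idx.size))
    cand_scores = scores[cand_idx]
    rho, pval = stats.spearmanr(counts, cand_scores)
    if exact:
        n = cand_idx.size
        if n > 10:
            raise ValueError("exact permutation p-value only for n <= 10")
        rc = stats.rankdata(counts)
        rs = stats.rankdata(cand_scores)
        obs = abs(np.corrcoef(rc, rs)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(rs):
            total += 1
            if abs(np.corrcoef(rc, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        pval = hits / total
    return float(rho), float(pval)
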