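"""Feature screening and repeated cross-validated importance ranking.

Two-stage selection: (1) a deliberately permissive Wilcoxon rank-sum
screen that only drops features whose two-sided p-value exceeds 0.8
(near-exact nulls and constants); (2) importance ranking repeated over
many realizations of stratified 10-fold cross-validation, where a
feature's importance in a fold is its univariate AUROC on the held-out
fold (folded to >= 0.5 so either sign of association counts).  Per-feature
mean rank and top-k selection frequency summarize stability across
realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .io_formats import FeatureTable

__all__ = ["SelectionResult", "wilcoxon_screen", "importance_ranking", "select_top_k"]


@dataclass
class SelectionResult:
    """Outcome of the screen and/or ranking stages."""

    retained: list[str]
    p_values: dict = field(default_factory=dict)
    ranks: np.ndarray | None = None  # (n_realizations, n_features), 1 = best
    mean_rank: dict = field(default_factory=dict)
    top_k_frequency: dict = field(default_factory=dict)
    n_realizations: int = 0
    seed: int | None = None


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free groups,
    normal approximation with tie correction otherwise; constants give 1."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def wilcoxon_screen(table: FeatureTable, p_max: float = 0.8) -> SelectionResult:
    """Drop features whose rank-sum p-value exceeds ``p_max``.

    Constant features get p = 1 and are dropped (not an error).  Requires
    both classes with at least two cases each.
    """
    y = table.y()
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least two cases in each class")
    pvals = {}
    retained = []
    for k, name in enumerate(table.feature_names):
        col = table.matrix[:, k]
        p = _rank_sum_p(col[y == 1], col[y == 0])
        pvals[name] = p
        if p <= p_max:
            retained.append(name)
    return SelectionResult(retained=retained, p_values=pvals)


def _auroc_all_features(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Univariate AUROC of every column of x as a score for y==1.

    Rank-based (Mann-Whitney) formulation with midrank tie handling, which
    matches trapezoidal ROC area; vectorized over features.
    """
    ranks = stats.rankdata(x, axis=0)
    n1 = int(y.sum())
    n0 = len(y) - n1
    r1 = ranks[y == 1].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _fold_auroc(x: np.ndarray, y: np.ndarray, folds: int, rng_seed: int) -> np.ndarray:
    """Cross-validated univariate AUROC per feature, folded to >= 0.5."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    aucs = np.zeros(x.shape[1])
    n_used = 0
    for _, test_idx in skf.split(x, y):
        yt = y[test_idx]
        if yt.min() == yt.max():  # degenerate fold, cannot score
            continue
        n_used += 1
        a = _auroc_all_features(x[test_idx], yt)
        aucs += np.maximum(a, 1.0 - a)
    return aucs / max(n_used, 1)


def importance_ranking(
    table: FeatureTable,
    n_realizations: int = 100,
    folds: int = 10,
    seed: int = 0,
    p_max: float = 0.8,
) -> SelectionResult:
    """Repeated cross-validated importance ranking after the screen.

    Each realization reshuffles the stratified folds, scores every retained
    feature by its cross-validated univariate AUROC, and ranks features
    1..k descending by score (ties resolved by feature name for
    determinism).  Aggregates mean rank and top-15 selection frequency.
    """
    screen = wilcoxon_screen(table, p_max=p_max)
    sub = table.subset(screen.retained)
    y = sub.y()
    n_min = int(min(y.sum(), len(y) - y.sum()))
    if n_min < folds:
        folds = max(n_min, 2)
    x = sub.matrix
    names = np.array(sub.feature_names)
    order_by_name = np.argsort(names, kind="stable")

    rng = np.random.default_rng(seed)
    all_ranks = np.zeros((n_realizations, len(names)), dtype=np.int64)
    for r in range(n_realizations):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        scores = _fold_auroc(x, y, folds, fold_seed)
        # sort by (-score, name) for deterministic tie-breaks
        key = np.lexsort((names, -scores))
        ranks = np.empty(len(names), dtype=np.int64)
        ranks[key] = np.arange(1, len(names) + 1)
        all_ranks[r] = ranks

    mean_rank = all_ranks.mean(axis=0)
    top15 = (all_ranks <= 15).mean(axis=0)
    return SelectionResult(
        retained=list(screen.retained),
        p_values=screen.p_values,
        ranks=all_ranks,
        mean_rank={n: float(m) for n, m in zip(names, mean_rank)},
        top_k_frequency={n: float(f) for n, f in zip(names, top15)},
        n_realizations=n_realizations,
        seed=seed,
    )


def select_top_k(result: SelectionResult, k: int = 15) -> list[str]:
    """Top-k feature names by mean rank (ties broken by name)."""
    if not result.mean_rank:
        raise ValueError("result has no ranking stage")
    items = sorted(result.mean_rank.items(), key=lambda kv: (kv[1], kv[0]))
    return [name for name, _ in items[:k]]
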