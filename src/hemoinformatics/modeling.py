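"""Repeated hold-out classification of growth status.

Each evaluation repeat draws a stratified 90/10 train/test split,
standardizes features on the training data only, tunes hyperparameters by
inner stratified 10-fold cross-validation maximizing AUROC, and scores the
held-out 10% (AUROC from decision scores; per-class accuracies at the
classifier's default threshold).  The mean AUROC and its 2.5-97.5
percentile interval over the repeats are the headline metrics.  No class
weighting is applied by default, so a weak model on the imbalanced cohort
drifts toward always predicting the majority (slow) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_formats import FeatureTable

__all__ = ["ModelSpec", "EvalResult", "evaluate", "compare_classifiers", "compose_feature_sets"]

CLASSIFIERS = ("svm_linear", "svm_poly", "lasso_logistic", "knn", "random_forest", "gbm")

# descending so inner-CV ties resolve toward the less-regularized model
_C_GRID = [100.0, 10.0, 1.0, 0.1, 0.01]


@dataclass
class ModelSpec:
    """Classifier + feature-set + hyperparameter grid for one evaluation."""

    classifier: str = "svm_linear"
    feature_names: list[str] | None = None  # None = all features
    param_grid: dict | None = None
    class_weight: str | None = None  # e.g. "balanced"; None matches default

    def build(self):
        cw = self.class_weight
        if self.classifier == "svm_linear":
            est = SVC(kernel="linear", class_weight=cw)
            grid = {"clf__C": _C_GRID}
        elif self.classifier == "svm_poly":
            est = SVC(kernel="poly", class_weight=cw)
            grid = {"clf__C": _C_GRID, "clf__degree": [2, 3]}
        elif self.classifier == "lasso_logistic":
            est = LogisticRegression(l1_ratio=1.0, solver="liblinear", class_weight=cw, max_iter=5000)
            grid = {"clf__C": _C_GRID}
        elif self.classifier == "knn":
            est = KNeighborsClassifier()
            grid = {"clf__n_neighbors": [3, 5, 7, 9]}
        elif self.classifier == "random_forest":
            est = RandomForestClassifier(n_estimators=200, class_weight=cw)
            grid = {"clf__max_depth": [2, 4, None]}
        elif self.classifier == "gbm":
            est = GradientBoostingClassifier(n_estimators=100)
            grid = {"clf__max_depth": [1, 2, 3]}
        else:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.param_grid is not None:
            grid = self.param_grid
        return Pipeline([("scale", StandardScaler()), ("clf", est)]), grid


@dataclass
class EvalResult:
    """Per-repeat and summary metrics of a repeated hold-out evaluation."""

    auroc: np.ndarray  # per repeat
    total_accuracy: np.ndarray  # percent
    fast_accuracy: np.ndarray  # percent
    slow_accuracy: np.ndarray  # percent
    n_repeats: int
    spec: ModelSpec | None = None
    redraws: int = 0

    @property
    def mean_auroc(self) -> float:
        return float(self.auroc.mean())

    @property
    def auroc_interval(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.auroc, [2.5, 97.5])
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.auroc_interval
        return {
            "mean_auroc": self.mean_auroc,
            "auroc_ci_lo": lo,
            "auroc_ci_hi": hi,
            "mean_total_accuracy": float(self.total_accuracy.mean()),
            "mean_fast_accuracy": float(self.fast_accuracy.mean()),
            "mean_slow_accuracy": float(self.slow_accuracy.mean()),
            "n_repeats": self.n_repeats,
        }


def _score_of(model, x) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return model.decision_function(x)
    return model.predict_proba(x)[:, 1]


def evaluate(
    table: FeatureTable,
    spec: ModelSpec | None = None,
    n_repeats: int = 100,
    test_fraction: float = 0.10,
    inner_folds: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Repeated stratified 90/10 hold-out evaluation of one model.

    All randomness (splits, fold shuffles, stochastic learners) derives
    from ``seed``.  A test split missing a class is redrawn (counted in
    ``redraws``), never silently scored.
    """
    spec = spec or ModelSpec()
    sub = table.subset(spec.feature_names) if spec.feature_names else table
    x = sub.matrix
    y = sub.y()  # fast = 1
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    pipe, grid = spec.build()

    rng = np.random.default_rng(seed)
    auroc = np.zeros(n_repeats)
    tot_acc = np.zeros(n_repeats)
    fast_acc = np.zeros(n_repeats)
    slow_acc = np.zeros(n_repeats)
    redraws = 0
    n_min = int(min(y.sum(), len(y) - y.sum()))
    folds = min(inner_folds, max(2, int(np.floor(n_min * (1.0 - test_fraction)))))
    # a stratified split needs at least one case of each class held out
    n_test = max(2, int(round(len(y) * test_fraction)))

    for rep in range(n_repeats):
        for _ in range(100):
            split_seed = int(rng.integers(0, 2**31 - 1))
            idx_tr, idx_te = train_test_split(
                np.arange(len(y)),
                test_size=n_test,
                stratify=y,
                random_state=split_seed,
            )
            if y[idx_te].min() != y[idx_te].max():
                break
            redraws += 1
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split_seed % (2**31 - 1))
        search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, n_jobs=1)
        # seed stochastic estimators through the pipeline params when present
        est = pipe.named_steps["clf"]
        if "random_state" in est.get_params():
            search.estimator.set_params(clf__random_state=split_seed % (2**31 - 1))
        search.fit(x[idx_tr], y[idx_tr])
        best = search.best_estimator_

        scores = _score_of(best, x[idx_te])
        auroc[rep] = roc_auc_score(y[idx_te], scores)
        pred = best.predict(x[idx_te])
        yt = y[idx_te]
        tot_acc[rep] = 100.0 * np.mean(pred == yt)
        fast_acc[rep] = 100.0 * np.mean(pred[yt == 1] == 1)
        slow_acc[rep] = 100.0 * np.mean(pred[yt == 0] == 0)

    return EvalResult(
        auroc=auroc,
        total_accuracy=tot_acc,
        fast_accuracy=fast_acc,
        slow_accuracy=slow_acc,
        n_repeats=n_repeats,
        spec=spec,
        redraws=redraws,
    )


def compare_classifiers(
    table: FeatureTable,
    feature_sets: dict[str, list[str]],
    classifiers: tuple = CLASSIFIERS,
    n_repeats: int = 100,
    seed: int = 0,
) -> list[dict]:
    """Grid of evaluations over (classifier x feature set) with deltas.

    Returns one row per combination; each classifier's rows carry the
    AUROC/accuracy delta relative to that classifier's first feature set.
    """
    rows = []
    for clf in classifiers:
        base = None
        for set_name, names in feature_sets.items():
            res = evaluate(table, ModelSpec(classifier=clf, feature_names=names), n_repeats=n_repeats, seed=seed)
            row = {"classifier": clf, "feature_set": set_name, **res.summary()}
            if base is None:
                base = row
                row["delta_auroc"] = 0.0
                row["delta_total_accuracy"] = 0.0
            else:
                row["delta_auroc"] = row["mean_auroc"] - base["mean_auroc"]
                row["delta_total_accuracy"] = row["mean_total_accuracy"] - base["mean_total_accuracy"]
            rows.append(row)
    return rows


def compose_feature_sets(groups: dict[str, list[str]], recipe: dict) -> dict[str, list[str]]:
    """Set algebra over named feature groups.

    ``recipe`` maps a model name to ``{"add": [...], "remove": [...]}``
    where entries are group names or individual feature names.  Unknown
    names raise with near-matches listed.  Results are deterministic
    (insertion order, duplicates removed).
    """
    import difflib

    all_features = sorted({f for g in groups.values() for f in g})

    def resolve(name: str) -> list[str]:
        if name in groups:
            return list(groups[name])
        if name in all_features:
            return [name]
        near = difflib.get_close_matches(name, list(groups) + all_features, n=3)
        raise KeyError(f"unknown group or feature {name!r}; near matches: {near}")

    out = {}
    for model_name, ops in recipe.items():
        adds = ops.get("add", [])
        if not adds:
            raise ValueError(f"recipe {model_name!r} adds no features")
        selected: dict[str, None] = {}
        for name in adds:
            for f in resolve(name):
                selected[f] = None
        for name in ops.get("remove", []):
            for f in resolve(name):
                selected.pop(f, None)
        if not selected:
            raise ValueError(f"recipe {model_name!r} resolves to an empty set")
        out[model_name] = list(selected)
    return out
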