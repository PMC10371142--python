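"""Shared train/validate/test machinery for the screening classifiers.

Both screening models (AChE reactivation, BBB permeability) are extreme
gradient boosting classifiers built the same way:

* a k-means-stratified 80/20 split — samples are clustered in descriptor
  space and the 20% test quota is drawn from every (cluster x class) cell,
  so both partitions see the full diversity of the data;
* iterative reduced-set (RS) feature selection — features are ranked by
  the importance scores of a model trained on the full set (FS; permutation
  importance by default, which is robust to the strong inter-descriptor
  correlation of the battery — gain importance is available), nested top-m
  subsets over a size grid are scored by cross-validated macro F1, and the
  best (ties to the smaller set) becomes the optimal RS;
* a cross-validated grid search over tree count, depth and learning rate.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from xgboost import XGBClassifier

from .descriptors import TOOLKIT_VERSION

DEFAULT_RS_SIZES = (4, 6, 9, 14, 20, 30, 50)  # "full" is appended automatically
DEFAULT_GRID = {
    "n_estimators": [200, 600],
    "max_depth": [2, 4],
    "learning_rate": [0.05, 0.2],
}


def _base_params(seed: int) -> dict:
    return dict(
        n_estimators=300,
        max_depth=3,
        learning_rate=0.1,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def _encode(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    return np.asarray([index[y] for y in labels], dtype=int)


@dataclass
class SplitPlan:
    test_fraction: float
    k: int
    seed: int
    assignment: dict[str, str]  # sample id -> "train_val" | "test"

    def ids(self, part: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == part]


def stratified_split(
    X: np.ndarray,
    labels: Sequence[str],
    ids: Sequence[str],
    test_fraction: float = 0.2,
    k: int | None = None,
    seed: int = 0,
) -> SplitPlan:
    """k-means-stratified train_val/test split.

    Samples are clustered with k-means (default k = 3 x number of classes)
    on the scaled feature matrix; the global test quota
    ``round(test_fraction * N)`` is apportioned across (cluster x class)
    cells by largest remainder, capped at all-but-one per multi-member cell,
    and members are drawn with a seeded RNG.
    """
    X = np.asarray(X, dtype=float)
    n = len(ids)
    if n != len(labels) or n != X.shape[0]:
        raise ValueError("ids, labels and feature rows must align")
    classes = sorted(set(labels))
    if k is None:
        k = 3 * len(classes)
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    k = max(k, 2)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    clusters = km.fit_predict(X)

    cells: dict[tuple[int, str], list[int]] = {}
    for idx, (cl, lab) in enumerate(zip(clusters, labels)):
        cells.setdefault((int(cl), lab), []).append(idx)

    total_quota = int(round(test_fraction * n))
    keys = sorted(cells)
    exact = {key: test_fraction * len(cells[key]) for key in keys}
    quota = {key: int(np.floor(q)) for key, q in exact.items()}
    for key in keys:  # respect the all-but-one cap
        cap = len(cells[key]) - 1 if len(cells[key]) > 1 else 1
        quota[key] = min(quota[key], cap)
    remaining = total_quota - sum(quota.values())
    by_remainder = sorted(keys, key=lambda key: (-(exact[key] - np.floor(exact[key])), key))
    for key in by_remainder:
        if remaining <= 0:
            break
        cap = len(cells[key]) - 1 if len(cells[key]) > 1 else 1
        if quota[key] < cap:
            quota[key] += 1
            remaining -= 1

    rng = np.random.default_rng(seed)
    assignment = {ids[i]: "train_val" for i in range(n)}
    for key in keys:
        members = np.array(cells[key])
        take = quota[key]
        if take > 0:
            chosen = rng.choice(members, size=take, replace=False)
            for i in chosen:
                assignment[ids[int(i)]] = "test"
    return SplitPlan(test_fraction=test_fraction, k=k, seed=seed, assignment=assignment)


@dataclass
class FeatureSubset:
    names: tuple[str, ...]
    importances: dict[str, float]
    selection_f1: float


def rank_features(
    X: np.ndarray,
    y_labels: Sequence[str],
    feature_names: Sequence[str],
    classes: Sequence[str],
    seed: int = 0,
    importance: str = "gain",
) -> list[tuple[str, float]]:
    """Rank features by importance of a model trained on the full set.

    ``importance`` is ``"gain"`` (XGBoost gain score, default) or
    ``"permutation"``.  Ties break alphabetically for determinism.
    """
    y = _encode(y_labels, classes)
    model = XGBClassifier(**_base_params(seed))
    model.fit(X, y)
    if importance == "gain":
        booster_scores = model.get_booster().get_score(importance_type="gain")
        scores = {
            name: float(booster_scores.get(f"f{i}", 0.0)) for i, name in enumerate(feature_names)
        }
    elif importance == "permutation":
        perm = permutation_importance(model, X, y, n_repeats=5, random_state=seed, n_jobs=1)
        scores = {name: float(s) for name, s in zip(feature_names, perm.importances_mean)}
    else:
        raise ValueError(f"unknown importance measure {importance!r}")
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def select_reduced_set(
    X: np.ndarray,
    y_labels: Sequence[str],
    feature_names: Sequence[str],
    sizes: Sequence[int] = DEFAULT_RS_SIZES,
    cv: int = 5,
    seed: int = 0,
    importance: str = "permutation",
    mode: str = "single",
) -> FeatureSubset:
    """Pick the optimal reduced feature set by cross-validated macro F1.

    ``mode="single"`` ranks once on the full set and evaluates nested top-m
    subsets; ``mode="recursive"`` re-ranks within the surviving set at each
    size (recursive elimination).  Ties go to the smaller subset.
    """
    X = np.asarray(X, dtype=float)
    classes = sorted(set(y_labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to select features")
    names = list(feature_names)
    candidate_sizes = sorted({min(m, len(names)) for m in sizes} | {len(names)})
    y = _encode(y_labels, classes)
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)

    ranked = rank_features(X, y_labels, names, classes, seed=seed, importance=importance)
    best: tuple[float, int, tuple[str, ...]] | None = None
    current_names = [n for n, _ in ranked]
    for m in candidate_sizes:
        if mode == "recursive" and len(current_names) > m:
            idx = [names.index(n) for n in current_names]
            reranked = rank_features(
                X[:, idx], y_labels, current_names, classes, seed=seed, importance=importance
            )
            current_names = [n for n, _ in reranked]
        subset = tuple(current_names[:m]) if mode == "recursive" else tuple(n for n, _ in ranked[:m])
        idx = [names.index(n) for n in subset]
        model = XGBClassifier(**_base_params(seed))
        f1 = float(np.mean(cross_val_score(model, X[:, idx], y, scoring="f1_macro", cv=splitter)))
        if best is None or f1 > best[0] + 1e-12:  # strict improvement: ties keep smaller set
            best = (f1, m, subset)
    f1, _, subset = best
    importances = dict(ranked)
    return FeatureSubset(
        names=subset,
        importances={n: importances.get(n, 0.0) for n in subset},
        selection_f1=f1,
    )


@dataclass
class ClassifierArtifact:
    """A trained gradient-boosting model plus everything needed to reuse it."""

    model: XGBClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    hyperparams: dict
    seed: int
    manifest: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"model expects {len(self.feature_names)} features, got {X.shape[1]}"
            )
        encoded = self.model.predict(X)
        return np.asarray([self.classes[i] for i in encoded])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if not hasattr(self.model, "_estimator_type"):
            # xgboost<3.1 expects the sklearn mixin attribute that
            # scikit-learn>=1.8 removed; restore it for (de)serialization
            self.model._estimator_type = "classifier"
        self.model.save_model(directory / "model.json")
        with open(directory / "manifest.json", "w") as fh:
            json.dump(
                {
                    "feature_names": list(self.feature_names),
                    "classes": list(self.classes),
                    "hyperparams": self.hyperparams,
                    "seed": self.seed,
                    "toolkit_version": TOOLKIT_VERSION,
                    **self.manifest,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, directory: str | Path) -> "ClassifierArtifact":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        model = XGBClassifier()
        if not hasattr(model, "_estimator_type"):
            # xgboost<3.1 expects the sklearn mixin attribute removed in
            # scikit-learn>=1.8; restore it so load_model/predict work
            model._estimator_type = "classifier"
        model.load_model(directory / "model.json")
        return cls(
            model=model,
            feature_names=tuple(manifest.pop("feature_names")),
            classes=tuple(manifest.pop("classes")),
            hyperparams=manifest.pop("hyperparams"),
            seed=manifest.pop("seed"),
            manifest=manifest,
        )


def train(
    X: np.ndarray,
    y_labels: Sequence[str],
    feature_names: Sequence[str],
    grid: dict | None = None,
    cv: int = 5,
    seed: int = 0,
) -> ClassifierArtifact:
    """Cross-validated grid search (accuracy) and refit on all training rows."""
    X = np.asarray(X, dtype=float)
    classes = tuple(sorted(set(y_labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    if grid is None:
        grid = dict(DEFAULT_GRID)
    if not grid or not all(v for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    y = _encode(y_labels, classes)
    base = _base_params(seed)
    for key in grid:
        base.pop(key, None)
    search = GridSearchCV(
        XGBClassifier(**base),
        param_grid=grid,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return ClassifierArtifact(
        model=search.best_estimator_,
        feature_names=tuple(feature_names),
        classes=classes,
        hyperparams={**{k: v for k, v in base.items() if k != "verbosity"}, **search.best_params_},
        seed=seed,
        manifest={"grid": {k: list(v) for k, v in grid.items()}, "cv_folds": cv,
                  "best_cv_accuracy": float(search.best_score_)},
    )
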