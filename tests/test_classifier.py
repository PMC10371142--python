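"""Split, feature selection, training and artifact persistence."""

import numpy as np
import pytest

from oximescreen.classifier import (
    ClassifierArtifact,
    select_reduced_set,
    stratified_split,
    train,
)


def _three_class_blob(n=300, seed=0):
    """Numeric features where the label is a threshold on feature 0."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, 6))
    labels = np.where(X[:, 0] < 0.33, "a", np.where(X[:, 0] < 0.66, "b", "c"))
    ids = [f"s{i}" for i in range(n)]
    return X, list(labels), ids


def test_degenerate_identical_features_split():
    X = np.ones((10, 3))
    labels = ["a"] * 5 + ["b"] * 5
    ids = [f"s{i}" for i in range(10)]
    plan = stratified_split(X, labels, ids, k=2, seed=0)
    assert len(plan.ids("test")) == 2
    assert len(plan.ids("train_val")) == 8


def test_split_deterministic():
    X, labels, ids = _three_class_blob()
    p1 = stratified_split(X, labels, ids, seed=42)
    p2 = stratified_split(X, labels, ids, seed=42)
    assert p1.assignment == p2.assignment


def test_split_class_shares_near_target():
    X, labels, ids = _three_class_blob()
    plan = stratified_split(X, labels, ids, seed=1)
    test_ids = set(plan.ids("test"))
    assert abs(len(test_ids) - 60) <= 1  # global 20% within one sample
    for cls in ("a", "b", "c"):
        members = [i for i, lab in zip(ids, labels) if lab == cls]
        share = sum(1 for m in members if m in test_ids) / len(members)
        assert abs(share - 0.2) <= 0.10


def test_split_k_too_large_rejected():
    X, labels, ids = _three_class_blob(n=20)
    with pytest.raises(ValueError, match="exceeds"):
        stratified_split(X, labels, ids, k=30)


def test_reduced_set_recovers_planted_feature():
    """Labels depend on feature 0 only: the optimal RS must contain it and
    the single-feature model must already classify nearly perfectly."""
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 1, size=(400, 10))
    labels = list(np.where(X[:, 0] > 0.5, "hi", "lo"))
    names = [f"f{i}" for i in range(10)]
    subset = select_reduced_set(X, labels, names, sizes=(1, 3, 5), cv=3, seed=0)
    assert "f0" in subset.names
    single = select_reduced_set(X, labels, names, sizes=(1,), cv=3, seed=0)
    assert single.names == ("f0",)
    assert single.selection_f1 >= 0.95


def test_reduced_set_grid_of_full_size_returns_full():
    rng = np.random.default_rng(4)
    X = rng.uniform(0, 1, size=(60, 4))
    labels = list(np.where(X[:, 1] > 0.5, "hi", "lo"))
    names = [f"f{i}" for i in range(4)]
    subset = select_reduced_set(X, labels, names, sizes=(4,), cv=3, seed=0)
    assert set(subset.names) == set(names)


def test_tie_goes_to_smaller_subset():
    """With a perfectly separable single feature, larger supersets tie at
    F1=1 and the smallest subset must win."""
    rng = np.random.default_rng(5)
    X = rng.uniform(0, 1, size=(200, 5))
    X[:, 0] = np.where(np.arange(200) % 2 == 0, 0.0, 1.0)
    labels = ["lo" if i % 2 == 0 else "hi" for i in range(200)]
    names = [f"f{i}" for i in range(5)]
    subset = select_reduced_set(X, labels, names, sizes=(1, 3, 5), cv=3, seed=0)
    assert subset.names == ("f0",)


def test_train_separable_and_deterministic():
    rng = np.random.default_rng(6)
    X = np.vstack([rng.normal(0, 0.3, size=(40, 3)), rng.normal(5, 0.3, size=(40, 3))])
    labels = ["a"] * 40 + ["b"] * 40
    grid = {"n_estimators": [50], "max_depth": [2], "learning_rate": [0.3]}
    art = train(X, labels, ["f0", "f1", "f2"], grid=grid, cv=3, seed=9)
    assert (art.predict(X) == np.array(labels)).all()
    art2 = train(X, labels, ["f0", "f1", "f2"], grid=grid, cv=3, seed=9)
    probe = rng.normal(2.5, 2.0, size=(30, 3))
    np.testing.assert_array_equal(art.predict(probe), art2.predict(probe))


def test_empty_grid_rejected():
    X = np.zeros((10, 2))
    labels = ["a"] * 5 + ["b"] * 5
    with pytest.raises(ValueError, match="empty"):
        train(X, labels, ["f0", "f1"], grid={}, cv=2)


def test_single_class_rejected():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError, match="2 classes"):
        train(X, ["a"] * 10, ["f0", "f1"])


def test_artifact_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    X = rng.uniform(size=(80, 4))
    labels = list(np.where(X[:, 2] > 0.5, "pos", "neg"))
    art = train(
        X, labels, [f"f{i}" for i in range(4)],
        grid={"n_estimators": [60], "max_depth": [3], "learning_rate": [0.2]},
        cv=3, seed=1,
    )
    art.save(tmp_path / "artifact")
    loaded = ClassifierArtifact.load(tmp_path / "artifact")
    probe = rng.uniform(size=(25, 4))
    np.testing.assert_array_equal(art.predict(probe), loaded.predict(probe))
    assert loaded.classes == art.classes
    assert loaded.feature_names == art.feature_names
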