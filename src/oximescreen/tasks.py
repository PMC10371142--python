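"""Task-specific layers: AChE reactivation and BBB permeability.

Reactivation: in vitro percent-reactivation measurements of SPPO:OP pairs
are binned into three classes — No (|percent| within a small zero
tolerance, default 0.5 points, operationalizing "about 0%"), Low (up to and
including 40%), High (strictly above 40%) — and featurized as concatenated
pair descriptors.  The 40% cutoff reflects where overt physiological
protection was observed in vivo.

BBB: measured logBB (log10 brain/blood ratio) is thresholded at 0 by
default; exactly 0 is conservatively assigned BBB- (no claim of brain
penetration on the boundary).

A :class:`TaskModel` bundles the trained classifier with its preprocessing
(variance filter + min-max scaler fit on the training rows) so raw SMILES
can be screened directly.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    ClassifierArtifact,
    FeatureSubset,
    SplitPlan,
    select_reduced_set,
    stratified_split,
    train,
)
from .compounds import CompoundRecord
from .descriptors import (
    OP_PREFIX,
    SPPO_PREFIX,
    DescriptorVector,
    build_pair_features,
    compute_descriptors,
)
from .features import FeatureTable, apply_scaler, minmax_scale, variance_filter
from .metrics import EvaluationReport

REACTIVATION_CLASSES = ("No", "Low", "High")
BBB_CLASSES = ("BBB-", "BBB+")

DEFAULT_ZERO_TOLERANCE = 0.5  # percentage points around 0 treated as "no reactivation"
DEFAULT_LOGBB_THRESHOLD = 0.0
LOW_HIGH_CUTOFF = 40.0  # percent; informed by in vivo protection observations

PERCENT_MIN, PERCENT_MAX = -10.0, 110.0  # assay noise tolerance on the raw scale


class BinningError(ValueError):
    pass


class DatasetError(ValueError):
    pass


def bin_reactivation(percent: float, zero_tolerance: float = DEFAULT_ZERO_TOLERANCE) -> str:
    """Map a percent reactivation onto {No, Low, High}.

    Low covers (zero_tolerance, 40] — the 40% boundary itself is Low; High
    is strictly greater than 40%.  Negative values beyond the zero tolerance
    are rejected rather than silently binned.
    """
    if not math.isfinite(percent) or percent < PERCENT_MIN or percent > PERCENT_MAX:
        raise BinningError(f"reactivation percent out of range: {percent!r}")
    if abs(percent) <= zero_tolerance:
        return "No"
    if percent < 0:
        raise BinningError(f"negative reactivation beyond zero tolerance: {percent!r}")
    if percent <= LOW_HIGH_CUTOFF:
        return "Low"
    return "High"


def bin_logbb(logbb: float, threshold: float = DEFAULT_LOGBB_THRESHOLD) -> str:
    """BBB+ strictly above the threshold, BBB- at or below it."""
    if not math.isfinite(logbb):
        raise BinningError(f"logBB must be finite: {logbb!r}")
    return "BBB+" if logbb > threshold else "BBB-"


def _descriptor_cache(records: Sequence[CompoundRecord]) -> dict[str, DescriptorVector]:
    return {rec.id: compute_descriptors(rec) for rec in records}


@dataclass
class ReactivationDataset:
    """Assembled SPPO:OP pair samples ready for splitting/scaling."""

    features: FeatureTable  # raw (unscaled) pair descriptors
    labels: list[str]
    percents: list[float]
    pair_ids: list[str]
    tallies: Counter

    def __len__(self) -> int:
        return len(self.pair_ids)


def assemble_reactivation_dataset(
    measurements: pd.DataFrame,
    sppos: Sequence[CompoundRecord],
    ops: Sequence[CompoundRecord],
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE,
) -> ReactivationDataset:
    """Build labeled pair samples from a measurement table.

    ``measurements`` needs columns ``sppo_id, op_id, reactivation_percent``
    (an optional ``replicate`` column is averaged out with the arithmetic
    mean).  Remaining duplicate (sppo, op) rows are tolerated when their
    binned classes agree (percents are then averaged) and are an error
    listing the conflicts otherwise.
    """
    required = {"sppo_id", "op_id", "reactivation_percent"}
    if measurements.empty:
        raise DatasetError("empty measurement table")
    if not required.issubset(measurements.columns):
        raise DatasetError(f"measurement table needs columns {sorted(required)}")
    df = measurements.copy()
    if "replicate" in df.columns:
        df = (
            df.groupby(["sppo_id", "op_id"], sort=False)["reactivation_percent"]
            .mean()
            .reset_index()
        )
    df["label"] = [bin_reactivation(p, zero_tolerance) for p in df["reactivation_percent"]]
    conflicts = []
    grouped = df.groupby(["sppo_id", "op_id"], sort=False)
    rows = []
    for (sid, oid), sub in grouped:
        if sub["label"].nunique() > 1:
            conflicts.append(f"({sid}, {oid}): {sorted(sub['label'].unique())}")
            continue
        rows.append((sid, oid, float(sub["reactivation_percent"].mean()), sub["label"].iloc[0]))
    if conflicts:
        raise DatasetError("conflicting duplicate pairs: " + "; ".join(conflicts))

    sppo_map = {r.id: r for r in sppos}
    op_map = {r.id: r for r in ops}
    missing = {sid for sid, _, _, _ in rows if sid not in sppo_map} | {
        oid for _, oid, _, _ in rows if oid not in op_map
    }
    if missing:
        raise DatasetError(f"measurements reference unknown structures: {sorted(missing)[:10]}")

    sppo_desc = _descriptor_cache([sppo_map[sid] for sid in {r[0] for r in rows}])
    op_desc = _descriptor_cache([op_map[oid] for oid in {r[1] for r in rows}])

    pair_ids, vectors, labels, percents = [], [], [], []
    for sid, oid, percent, label in rows:
        pair_ids.append(f"{sid}:{oid}")
        vectors.append(build_pair_features(sppo_desc[sid], op_desc[oid]))
        labels.append(label)
        percents.append(percent)
    table = FeatureTable.from_vectors(pair_ids, vectors)
    return ReactivationDataset(table, labels, percents, pair_ids, Counter(labels))


@dataclass
class BBBDataset:
    features: FeatureTable
    labels: list[str]
    ids: list[str]
    tallies: Counter

    def __len__(self) -> int:
        return len(self.ids)


def assemble_bbb_dataset(
    table: pd.DataFrame,
    threshold: float = DEFAULT_LOGBB_THRESHOLD,
    column_map: Mapping[str, str] | None = None,
) -> BBBDataset:
    """Build labeled single-molecule samples from a logBB table.

    Default columns ``compound_id, smiles, logBB``; ``column_map`` renames
    published-file headers onto that schema (e.g. the B3DB regression file's
    ``NO./SMILES/logBB``).
    """
    df = table.rename(columns=dict(column_map or {}))
    required = {"compound_id", "smiles", "logBB"}
    if df.empty:
        raise DatasetError("empty logBB table")
    if not required.issubset(df.columns):
        raise DatasetError(f"logBB table needs columns {sorted(required)}")
    ids, vectors, labels = [], [], []
    for _, row in df.iterrows():
        rec = CompoundRecord.from_smiles(str(row["compound_id"]), row["smiles"])
        ids.append(rec.id)
        vectors.append(compute_descriptors(rec))
        labels.append(bin_logbb(float(row["logBB"]), threshold))
    return BBBDataset(FeatureTable.from_vectors(ids, vectors), labels, ids, Counter(labels))


@dataclass
class TaskModel:
    """Trained classifier plus the preprocessing needed to screen raw SMILES."""

    artifact: ClassifierArtifact
    scaler: dict[str, tuple[float, float]]
    surviving_columns: tuple[str, ...]
    kind: str  # "reactivation" | "bbb"
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE
    logbb_threshold: float = DEFAULT_LOGBB_THRESHOLD

    def _transform(self, raw: pd.DataFrame) -> np.ndarray:
        cols = list(self.surviving_columns)
        scaled = apply_scaler(raw[cols], {c: self.scaler[c] for c in cols})
        return scaled[list(self.artifact.feature_names)].to_numpy()

    def predict_pairs(
        self,
        sppo_desc: Mapping[str, DescriptorVector],
        op_desc: Mapping[str, DescriptorVector],
        pairs: Sequence[tuple[str, str]],
    ) -> list[str]:
        if self.kind != "reactivation":
            raise ValueError("pair prediction requires a reactivation model")
        vectors = [build_pair_features(sppo_desc[s], op_desc[o]) for s, o in pairs]
        raw = pd.DataFrame(
            np.vstack([v.values for v in vectors]), columns=list(vectors[0].names)
        )
        return list(self.artifact.predict(self._transform(raw)))

    def predict_molecules(self, smiles: Sequence[str]) -> list[str]:
        if self.kind != "bbb":
            raise ValueError("molecule prediction requires a BBB model")
        vectors = [compute_descriptors(s) for s in smiles]
        raw = pd.DataFrame(np.vstack([v.values for v in vectors]), columns=list(vectors[0].names))
        return list(self.artifact.predict(self._transform(raw)))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.artifact.save(directory / "artifact")
        with open(directory / "preprocessing.json", "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "scaler": {c: list(v) for c, v in self.scaler.items()},
                    "surviving_columns": list(self.surviving_columns),
                    "zero_tolerance": self.zero_tolerance,
                    "logbb_threshold": self.logbb_threshold,
                },
                fh,
            )

    @classmethod
    def load(cls, directory: str | Path) -> "TaskModel":
        directory = Path(directory)
        with open(directory / "preprocessing.json") as fh:
            pre = json.load(fh)
        return cls(
            artifact=ClassifierArtifact.load(directory / "artifact"),
            scaler={c: tuple(v) for c, v in pre["scaler"].items()},
            surviving_columns=tuple(pre["surviving_columns"]),
            kind=pre["kind"],
            zero_tolerance=pre.get("zero_tolerance", DEFAULT_ZERO_TOLERANCE),
            logbb_threshold=pre.get("logbb_threshold", DEFAULT_LOGBB_THRESHOLD),
        )


@dataclass
class TrainingResult:
    model: TaskModel
    report: EvaluationReport
    subset: FeatureSubset
    split: SplitPlan
    tallies: Counter


def _train_task(
    features: FeatureTable,
    labels: Sequence[str],
    ids: Sequence[str],
    kind: str,
    seed: int,
    variance_threshold: float = 0.0,
    rs_sizes: Sequence[int] | None = None,
    grid: dict | None = None,
    cv: int = 5,
    k: int | None = None,
    deploy_on_full: bool = True,
    **task_kwargs,
) -> TrainingResult:
    filtered = variance_filter(features, variance_threshold)
    # clustering for the split uses a provisional all-rows scaling; the model
    # scaler is refit on the training rows only to avoid test leakage
    provisional = minmax_scale(filtered)
    split = stratified_split(provisional.matrix, labels, ids, k=k, seed=seed)
    train_ids = split.ids("train_val")
    test_ids = split.ids("test")
    scaled = minmax_scale(filtered, fit_rows=train_ids)
    label_of = dict(zip(ids, labels))
    Xtr = scaled.data.loc[train_ids].to_numpy()
    ytr = [label_of[i] for i in train_ids]
    subset = select_reduced_set(
        Xtr, ytr, scaled.columns, sizes=rs_sizes or (4, 6, 9, 14, 20, 30, 50), cv=cv, seed=seed
    )
    col_idx = [scaled.columns.index(c) for c in subset.names]
    artifact = train(Xtr[:, col_idx], ytr, subset.names, grid=grid, cv=cv, seed=seed)
    Xte = scaled.data.loc[test_ids].to_numpy()[:, col_idx]
    yte = [label_of[i] for i in test_ids]
    report = EvaluationReport.from_predictions(yte, artifact.predict(Xte), artifact.classes)

    if deploy_on_full:
        # deployment model: same subset and tuned hyperparameters, refit on
        # every labeled sample; the held-out report above stays untouched
        full_scaled = minmax_scale(filtered)
        Xall = full_scaled.data.to_numpy()[
            :, [full_scaled.columns.index(c) for c in subset.names]
        ]
        from .classifier import DEFAULT_GRID

        tuned_keys = set((grid or DEFAULT_GRID).keys())
        point_grid = {key: [artifact.hyperparams[key]] for key in tuned_keys}
        deployed = train(Xall, list(labels), subset.names, grid=point_grid, cv=cv, seed=seed)
        scaler, columns = full_scaled.scaler, full_scaled.columns
        model_artifact = deployed
    else:
        scaler, columns = scaled.scaler, scaled.columns
        model_artifact = artifact
    model = TaskModel(
        artifact=model_artifact,
        scaler=scaler,
        surviving_columns=tuple(columns),
        kind=kind,
        **task_kwargs,
    )
    return TrainingResult(model, report, subset, split, Counter(labels))


def train_reactivation_model(
    dataset: ReactivationDataset, seed: int = 0, **kwargs
) -> TrainingResult:
    return _train_task(
        dataset.features,
        dataset.labels,
        dataset.pair_ids,
        kind="reactivation",
        seed=seed,
        **kwargs,
    )


def train_bbb_model(dataset: BBBDataset, seed: int = 0, **kwargs) -> TrainingResult:
    return _train_task(
        dataset.features, dataset.labels, dataset.ids, kind="bbb", seed=seed, **kwargs
    )


def predict_broad_spectrum(
    model: TaskModel,
    candidate_smiles: Sequence[str],
    op_records: Sequence[CompoundRecord],
) -> pd.DataFrame:
    """Predict per-OP reactivation classes and the broad-spectrum flag.

    Returns a DataFrame indexed by candidate SMILES with one column per OP
    plus ``broad_spectrum`` — True iff the predicted class is High for every
    OP in the panel.
    """
    if not op_records:
        raise DatasetError("empty OP panel")
    op_desc = _descriptor_cache(op_records)
    sppo_desc = {s: compute_descriptors(s) for s in candidate_smiles}
    op_ids = [r.id for r in op_records]
    pairs = [(s, o) for s in candidate_smiles for o in op_ids]
    preds = model.predict_pairs(sppo_desc, op_desc, pairs)
    out = pd.DataFrame(
        np.array(preds).reshape(len(candidate_smiles), len(op_ids)),
        index=list(candidate_smiles),
        columns=op_ids,
    )
    out["broad_spectrum"] = (out[op_ids] == "High").all(axis=1)
    return out
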