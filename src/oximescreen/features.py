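"""Feature tables: named descriptor matrices with scaling and filtering provenance.

A :class:`FeatureTable` wraps a pandas DataFrame (rows = samples, columns =
descriptor names) together with the min-max scaler parameters used to map it
into [0, 1] and the list of columns removed by variance filtering, so that
unseen samples can be pushed through exactly the same transform and scaled
values can be inverted for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .descriptors import TOOLKIT_VERSION, DescriptorVector


@dataclass
class FeatureTable:
    """Descriptor matrix with scaling/filtering provenance.

    ``scaler`` maps column name to the (min, max) observed on the fit rows;
    it is ``None`` for unscaled tables.  ``dropped_columns`` records names
    removed by :func:`variance_filter`.
    """

    data: pd.DataFrame
    scaler: dict[str, tuple[float, float]] | None = None
    dropped_columns: list[str] = field(default_factory=list)

    @classmethod
    def from_vectors(cls, ids: Sequence[str], vectors: Iterable[DescriptorVector]) -> "FeatureTable":
        vectors = list(vectors)
        if not vectors:
            raise ValueError("empty feature table")
        names = vectors[0].names
        for v in vectors[1:]:
            if v.names != names:
                raise ValueError("inconsistent descriptor batteries")
        mat = np.vstack([v.values for v in vectors])
        return cls(pd.DataFrame(mat, index=list(ids), columns=list(names)))

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_csv(self, path: str | Path, manifest: dict | None = None) -> None:
        """Write matrix as CSV plus a sidecar ``<path>.manifest.json``."""
        path = Path(path)
        self.data.to_csv(path, index_label="id")
        payload = {
            "toolkit_version": TOOLKIT_VERSION,
            "scaler": self.scaler,
            "dropped_columns": self.dropped_columns,
        }
        if manifest:
            payload.update(manifest)
        with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
            json.dump(payload, fh, indent=2)


def variance_filter(table: FeatureTable, threshold: float = 0.0) -> FeatureTable:
    """Drop columns whose (population) variance is <= ``threshold``.

    Column order of survivors is preserved; removed names are appended to
    ``dropped_columns``.  Default threshold 0 drops exactly-constant columns.
    """
    if threshold < 0:
        raise ValueError("variance threshold must be >= 0")
    variances = table.data.var(axis=0, ddof=0)
    keep = [c for c in table.columns if variances[c] > threshold]
    dropped = [c for c in table.columns if variances[c] <= threshold]
    return FeatureTable(
        table.data[keep].copy(),
        scaler=None if table.scaler is None else {c: table.scaler[c] for c in keep},
        dropped_columns=table.dropped_columns + dropped,
    )


def minmax_scale(table: FeatureTable, fit_rows: Sequence[str] | None = None) -> FeatureTable:
    """Min-max scale every column into [0, 1].

    The (min, max) per column is computed over ``fit_rows`` (default: all
    rows) and stored; rows outside the fit population are transformed with
    those parameters and clipped into [0, 1].  Constant columns map to 0.
    """
    if table.data.empty:
        raise ValueError("empty table")
    fit = table.data if fit_rows is None else table.data.loc[list(fit_rows)]
    if fit.empty:
        raise ValueError("fit_rows must be nonempty")
    scaler = {c: (float(fit[c].min()), float(fit[c].max())) for c in table.columns}
    scaled = apply_scaler(table.data, scaler)
    return FeatureTable(scaled, scaler=scaler, dropped_columns=list(table.dropped_columns))


def apply_scaler(data: pd.DataFrame, scaler: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Transform a raw descriptor frame with stored (min, max), clipping to [0, 1]."""
    missing = [c for c in data.columns if c not in scaler]
    if missing:
        raise ValueError(f"columns without scaler parameters: {missing[:5]}")
    out = {}
    for c in data.columns:
        lo, hi = scaler[c]
        col = data[c].to_numpy(dtype=float)
        if hi > lo:
            out[c] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
        else:
            out[c] = np.zeros_like(col)  # constant column convention
    return pd.DataFrame(out, index=data.index)


def inverse_scale(table: FeatureTable) -> pd.DataFrame:
    """Invert a scaled table back to raw values (exact for non-clipped entries)."""
    if table.scaler is None:
        raise ValueError("table has no stored scaler")
    out = {}
    for c in table.columns:
        lo, hi = table.scaler[c]
        out[c] = table.data[c].to_numpy() * (hi - lo) + lo
    return pd.DataFrame(out, index=table.data.index)
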