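"""Per-molecule 2D descriptor battery and SPPO:OP pair featurization.

The battery is the full RDKit 2D descriptor list for the pinned toolkit
version, plus an oxime-group count (the functional group that defines a
reactivator and is absent from the stock list).  The battery size is a
property of the toolkit version and is recorded in output manifests rather
than asserted as a constant.

Pair features for a reactivator:challenge pairing are the concatenation of
the two single-molecule vectors with role-prefixed names (``sppo__*`` then
``op__*``), so downstream feature-importance reports attribute each
descriptor unambiguously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import rdkit
from rdkit import Chem
from rdkit.Chem import Descriptors

from .compounds import CompoundRecord

TOOLKIT_VERSION = rdkit.__version__

# C=N-OH with an sp2 carbon: the reactive warhead of oxime reactivators.
_OXIME_SMARTS = Chem.MolFromSmarts("[CX3]=[NX2][OX2H1]")

SPPO_PREFIX = "sppo__"
OP_PREFIX = "op__"


class DescriptorError(RuntimeError):
    """A descriptor failed (exception or non-finite value) on a valid molecule."""


def oxime_group_count(mol: Chem.Mol) -> int:
    """Number of aldoxime/ketoxime groups (SMARTS ``[CX3]=[NX2][OX2H1]``)."""
    return len(mol.GetSubstructMatches(_OXIME_SMARTS))


def descriptor_names() -> list[str]:
    """Ordered battery names, fixed for a given toolkit version."""
    return [name for name, _ in Descriptors.descList] + ["NumOximeGroups"]


@dataclass(frozen=True)
class DescriptorVector:
    """Named, ordered real-valued descriptors for one molecule."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def compute_descriptors(compound: CompoundRecord | str) -> DescriptorVector:
    """Compute the full battery for one molecule.

    Deterministic for a fixed toolkit version.  A descriptor that raises or
    returns a non-finite value is an error naming the descriptor and the
    molecule — never a silent NaN.
    """
    if isinstance(compound, CompoundRecord):
        smiles, label = compound.smiles, compound.id
    else:
        smiles, label = compound, compound
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DescriptorError(f"invalid molecule {label!r}")
    names: list[str] = []
    values: list[float] = []
    for name, fn in Descriptors.descList:
        try:
            val = float(fn(mol))
        except Exception as exc:  # noqa: BLE001 - reported with context
            raise DescriptorError(f"descriptor {name!r} failed on {label!r}: {exc}") from exc
        if not math.isfinite(val):
            raise DescriptorError(f"descriptor {name!r} non-finite on {label!r}")
        names.append(name)
        values.append(val)
    names.append("NumOximeGroups")
    values.append(float(oxime_group_count(mol)))
    return DescriptorVector(tuple(names), np.asarray(values, dtype=float))


def build_pair_features(sppo: DescriptorVector, op: DescriptorVector) -> DescriptorVector:
    """Concatenate reactivator and challenge descriptors with role prefixes."""
    if sppo.names != op.names:
        raise ValueError("pairing requires vectors from the same descriptor battery")
    names = tuple(SPPO_PREFIX + n for n in sppo.names) + tuple(OP_PREFIX + n for n in op.names)
    return DescriptorVector(names, np.concatenate([sppo.values, op.values]))
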