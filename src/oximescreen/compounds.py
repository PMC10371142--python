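"""Compound records, SMILES canonicalization and structure file I/O.

Structures move through the package as :class:`CompoundRecord` objects whose
SMILES are canonicalized once on ingestion; canonical SMILES is also the
deduplication key everywhere downstream.  The organophosphate (OP) challenge
panel used for broad-spectrum screening is shipped here as named records,
encoded from the compounds' IUPAC names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


class Role(str, Enum):
    SPPO = "SPPO"
    OP = "OP"
    UNKNOWN = "UNKNOWN"


class CompoundError(ValueError):
    """Raised for unparseable structures or malformed structure files."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES, raising :class:`CompoundError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """RDKit canonical SMILES (toolkit-default dialect, stereo preserved)."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


@dataclass(frozen=True)
class CompoundRecord:
    """A molecule with identity and a role in the screening workflow."""

    id: str
    smiles: str
    role: Role = Role.UNKNOWN
    name: str | None = None

    @classmethod
    def from_smiles(
        cls,
        id: str,
        smiles: str,
        role: Role | str = Role.UNKNOWN,
        name: str | None = None,
    ) -> "CompoundRecord":
        return cls(id=id, smiles=canonical_smiles(smiles), role=Role(role), name=name)

    @property
    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


def read_compounds(path: str | Path, format: str | None = None) -> list[CompoundRecord]:
    """Read structures from a headered CSV (``id,smiles[,role,name]``) or an SDF.

    The format is inferred from the file extension when not given.  Every
    SMILES is canonicalized; unparseable entries abort with an error naming
    the offending row/record.  Duplicate ids and files with zero valid
    molecules are errors.
    """
    path = Path(path)
    if not path.exists():
        raise CompoundError(f"no such file: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "csv"
    if format == "csv":
        records = _read_csv(path)
    elif format == "sdf":
        records = _read_sdf(path)
    else:
        raise CompoundError(f"unsupported format: {format!r}")
    if not records:
        raise CompoundError(f"{path}: zero valid molecules")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise CompoundError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
    return records


def _read_csv(path: Path) -> list[CompoundRecord]:
    records: list[CompoundRecord] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in [f.lower() for f in reader.fieldnames]:
            raise CompoundError(f"{path}: CSV needs a header row with a 'smiles' column")
        fieldmap = {f.lower(): f for f in reader.fieldnames}
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            smiles = (row.get(fieldmap["smiles"]) or "").strip()
            rid = (row.get(fieldmap.get("id", ""), "") or "").strip() or f"row{i}"
            role = (row.get(fieldmap.get("role", ""), "") or "").strip() or "UNKNOWN"
            name = (row.get(fieldmap.get("name", ""), "") or "").strip() or None
            try:
                records.append(CompoundRecord.from_smiles(rid, smiles, Role(role.upper()), name))
            except (CompoundError, ValueError) as exc:
                errors.append(f"row {i}: {exc}")
    if errors:
        raise CompoundError(f"{path}: " + "; ".join(errors))
    return records


def _read_sdf(path: Path) -> list[CompoundRecord]:
    records: list[CompoundRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    errors: list[str] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            errors.append(f"record {i}: unparseable")
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"rec{i}"
        role = Role(mol.GetProp("role").upper()) if mol.HasProp("role") else Role.UNKNOWN
        records.append(CompoundRecord(id=rid, smiles=Chem.MolToSmiles(mol), role=role))
    if errors:
        raise CompoundError(f"{path}: " + "; ".join(errors))
    return records


def write_compounds_csv(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "role", "name"])
        for rec in records:
            writer.writerow([rec.id, rec.smiles, rec.role.value, rec.name or ""])


# The five-member OP challenge panel: surrogates for G-/V-/GV-series nerve
# agents plus a potent insecticide metabolite.  GV has no in vitro training
# data anywhere in the workflow and is prediction-only.
OP_PANEL_SMILES: dict[str, str] = {
    # phthalimidyl isopropyl methylphosphonate (sarin surrogate)
    "PIMP": "CC(C)OP(C)(=O)ON1C(=O)c2ccccc2C1=O",
    # 4-nitrophenyl ethyl methylphosphonate (VX surrogate)
    "NEMP": "CCOP(C)(=O)Oc1ccc(cc1)[N+](=O)[O-]",
    # paraoxon, active metabolite of parathion
    "PXN": "CCOP(=O)(OCC)Oc1ccc(cc1)[N+](=O)[O-]",
    # diisopropyl phosphorofluoridate (sarin/soman surrogate)
    "DFP": "CC(C)OP(F)(=O)OC(C)C",
    # 2-[dimethylamino(fluoro)phosphoryl]oxy-N,N-dimethylethanamine
    "GV": "CN(C)CCOP(=O)(F)N(C)C",
}

# phorate oxon: active metabolite of the phosphorodithioate insecticide
# phorate; used only as an external generalization challenge, never trained on.
PHORATE_OXON_SMILES = "CCOP(=O)(OCC)SCSCC"


def op_panel(names: Sequence[str] | None = None) -> list[CompoundRecord]:
    """The OP challenge panel as records (default: PIMP, NEMP, PXN, DFP, GV)."""
    names = list(names) if names is not None else list(OP_PANEL_SMILES)
    records = []
    for name in names:
        try:
            smi = OP_PANEL_SMILES[name] if name != "PHORATE_OXON" else PHORATE_OXON_SMILES
        except KeyError:
            raise CompoundError(f"unknown OP panel member: {name!r}") from None
        records.append(CompoundRecord.from_smiles(name, smi, Role.OP, name))
    return records
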