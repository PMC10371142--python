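"""SPPO scaffolds, R-group decomposition and reassembly.

The substituted phenoxyalkyl pyridinium oxime (SPPO) chemotype is a
pyridinium aldoxime whose ring nitrogen carries an alkyl linker of n
carbons ending in a phenyl ether; the phenoxy ring bears up to five
substituents R1..R5 (R1/R5 ortho, R2/R4 meta, R3 para to the ether oxygen).
The scaffold registry holds the three shared cores of the platform — the
positional isomers with the aldoxime at pyridinium ring position 2, 3 or 4.

``decompose`` factors a molecule into (scaffold, linker length n, position →
fragment); ``reassemble`` is its exact inverse on canonical SMILES.
"Special" R-groups span two adjacent positions (R2&R3 or R3&R4) and create a
ring fused to the phenoxy ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

from rdkit import Chem

from .compounds import CompoundRecord, Role, canonical_smiles, mol_from_smiles

R_POSITIONS = (1, 2, 3, 4, 5)
IN_RULE_LINKERS = (3, 4, 5)
# linker lengths tried during decomposition (out-of-rule lengths are flagged)
_SEARCH_LINKERS = (3, 4, 5, 1, 2, 6, 7, 8)

_PHENOXY = "c2c{r1}c{r2}c{r3}c{r4}c2{r5}"


class ScaffoldMatchError(ValueError):
    """Molecule does not decompose against any registered scaffold."""


class ReassemblyError(ValueError):
    """Fragment attachment produced an invalid (e.g. valence-violating) molecule."""


@dataclass(frozen=True)
class ScaffoldTemplate:
    """One shared SPPO core with a formatting template for its SMILES.

    ``template`` has ``{link}`` for the alkyl linker and ``{ph}`` for the
    substituted phenoxy ring.
    """

    id: str
    oxime_ring_position: int
    template: str

    def core_smiles(self, n: int, rgroups: Mapping[int, str] | None = None) -> str:
        """Core SMILES with linker length ``n``.

        ``rgroups`` maps position -> SMILES inset (e.g. ``"([*:3])"``);
        unlisted positions are left as implicit hydrogen.
        """
        if n < 1:
            raise ValueError("linker length must be >= 1")
        rgroups = rgroups or {}
        ph = _PHENOXY.format(**{f"r{k}": rgroups.get(k, "") for k in R_POSITIONS})
        return self.template.format(link="C" * n, ph=ph)


SCAFFOLDS: tuple[ScaffoldTemplate, ...] = (
    ScaffoldTemplate("S2", 2, "ON=Cc1cccc[n+]1{link}O{ph}"),
    ScaffoldTemplate("S3", 3, "ON=Cc1ccc[n+]({link}O{ph})c1"),
    ScaffoldTemplate("S4", 4, "ON=Cc1cc[n+]({link}O{ph})cc1"),
)

_SCAFFOLD_BY_ID = {s.id: s for s in SCAFFOLDS}


def get_scaffold(scaffold_id: str) -> ScaffoldTemplate:
    try:
        return _SCAFFOLD_BY_ID[scaffold_id]
    except KeyError:
        raise ScaffoldMatchError(f"unknown scaffold id {scaffold_id!r}") from None


@dataclass(frozen=True)
class RGroupFragment:
    """A substituent fragment with 1 (ordinary) or 2 (special, fused) attachment points.

    ``smiles`` uses atom-mapped dummies ``[*:k]``; map numbers are
    positional placeholders and are re-targeted on placement.  The canonical
    pool key ignores map numbers, so the same chemical fragment observed at
    different positions pools to one entry.
    """

    smiles: str
    positions_observed: frozenset = frozenset()
    source_ids: tuple[str, ...] = ()

    @property
    def attachment_count(self) -> int:
        return sum(1 for a in mol_from_smiles(self.smiles).GetAtoms() if a.GetAtomicNum() == 0)

    @property
    def is_special(self) -> bool:
        return self.attachment_count == 2

    @property
    def is_hydrogen(self) -> bool:
        """True when the fragment carries no heavy atoms (the null substituent)."""
        mol = mol_from_smiles(self.smiles)
        return all(a.GetAtomicNum() in (0, 1) for a in mol.GetAtoms())

    @property
    def pool_key(self) -> str:
        return _pool_key(self.smiles)

    def with_positions(self, positions: Sequence[int]) -> str:
        """SMILES with dummy map numbers rewritten to ``positions`` (sorted order)."""
        mol = mol_from_smiles(self.smiles)
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != len(positions):
            raise ReassemblyError(
                f"fragment {self.smiles!r} has {len(dummies)} attachment points, "
                f"got {len(positions)} positions"
            )
        dummies.sort(key=lambda a: a.GetAtomMapNum())
        for atom, pos in zip(dummies, sorted(positions)):
            atom.SetAtomMapNum(pos)
        return Chem.MolToSmiles(mol)


HYDROGEN_FRAGMENT = RGroupFragment("[H][*:1]")


@lru_cache(maxsize=4096)
def _pool_key(smiles: str) -> str:
    mol = mol_from_smiles(smiles)
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Decomposition:
    """A molecule factored as scaffold + linker length + positioned fragments.

    ``assignment`` holds only non-hydrogen fragments, keyed by a sorted
    position tuple — ``(3,)`` for an ordinary fragment at R3, ``(2, 3)`` for
    a special fused fragment.  ``in_rule`` is False when the linker length
    falls outside the enumeration rule set {3, 4, 5}.
    """

    sppo_id: str
    scaffold_id: str
    n: int
    assignment: Mapping[tuple[int, ...], RGroupFragment]
    in_rule: bool = True

    def fragment_at(self, position: int) -> RGroupFragment | None:
        for positions, frag in self.assignment.items():
            if position in positions:
                return frag
        return None


@lru_cache(maxsize=64)
def _core_query(scaffold_id: str, n: int):
    """Bare core mol for substructure matching + core-atom index per R position."""
    scaffold = get_scaffold(scaffold_id)
    labeled = Chem.MolFromSmiles(
        scaffold.core_smiles(n, {k: f"([*:{k}])" for k in R_POSITIONS})
    )
    dummy_info = []  # (dummy_idx, position, neighbor_idx)
    for atom in labeled.GetAtoms():
        if atom.GetAtomicNum() == 0:
            (nb,) = atom.GetNeighbors()
            dummy_info.append((atom.GetIdx(), atom.GetAtomMapNum(), nb.GetIdx()))
    rw = Chem.RWMol(labeled)
    for d_idx, _, _ in sorted(dummy_info, reverse=True):
        rw.RemoveAtom(d_idx)
    bare = rw.GetMol()
    Chem.SanitizeMol(bare)
    dummy_idxs = sorted(d for d, _, _ in dummy_info)
    pos_to_core_atom = {}
    for _, pos, nb_idx in dummy_info:
        shift = sum(1 for d in dummy_idxs if d < nb_idx)
        pos_to_core_atom[pos] = nb_idx - shift
    return bare, pos_to_core_atom


def _try_match(mol: Chem.Mol, scaffold: ScaffoldTemplate, n: int):
    """All valid decomposition assignments of ``mol`` against (scaffold, n)."""
    core, pos_atoms = _core_query(scaffold.id, n)
    atom_to_pos = {v: k for k, v in pos_atoms.items()}
    results = []
    for match in mol.GetSubstructMatches(core, uniquify=True):
        mset = set(match)
        work = Chem.Mol(mol)
        Chem.Kekulize(work, clearAromaticFlags=True)
        cut_bonds: list[int] = []
        labels: list[tuple[int, int]] = []
        ok = True
        for core_idx, mol_idx in enumerate(match):
            outside = [
                nb.GetIdx()
                for nb in work.GetAtomWithIdx(mol_idx).GetNeighbors()
                if nb.GetIdx() not in mset
            ]
            if not outside:
                continue
            pos = atom_to_pos.get(core_idx)
            if pos is None:  # substitution off the core outside R1..R5
                ok = False
                break
            for nb_idx in outside:
                cut_bonds.append(work.GetBondBetweenAtoms(mol_idx, nb_idx).GetIdx())
                labels.append((pos, pos))
        if not ok:
            continue
        if not cut_bonds:
            results.append({})
            continue
        fragmented = Chem.FragmentOnBonds(work, cut_bonds, dummyLabels=labels)
        # FragmentOnBonds appends dummy atoms, so original atom indices are
        # preserved; the piece containing match[0] is the core.
        piece_index_sets = Chem.GetMolFrags(fragmented)
        pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=False)
        assignment: dict[tuple[int, ...], RGroupFragment] = {}
        valid = True
        for piece, idxs in zip(pieces, piece_index_sets):
            if match[0] in idxs:
                continue  # the scaffold core itself
            piece_positions = sorted(
                a.GetIsotope() for a in piece.GetAtoms() if a.GetAtomicNum() == 0 and a.GetIsotope()
            )
            if not piece_positions or len(piece_positions) > 2:
                valid = False
                break
            if len(piece_positions) == 2 and (
                piece_positions[0] == piece_positions[1]
                or abs(piece_positions[0] - piece_positions[1]) != 1
            ):
                valid = False  # two cuts to the same or non-adjacent positions
                break
            for a in piece.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetAtomMapNum(a.GetIsotope())
                    a.SetIsotope(0)
            key = tuple(piece_positions)
            if key in assignment or any(
                set(key) & set(k) for k in assignment
            ):
                valid = False  # a position claimed twice
                break
            assignment[key] = RGroupFragment(
                Chem.MolToSmiles(piece), positions_observed=frozenset([key] if len(key) > 1 else key)
            )
        if valid:
            results.append(assignment)
    return results


def _assignment_sort_key(assignment):
    return sorted((pos, frag.pool_key) for pos, frag in assignment.items())


def decompose(
    sppo: CompoundRecord,
    scaffolds: Sequence[ScaffoldTemplate] = SCAFFOLDS,
    linker_lengths: Sequence[int] = _SEARCH_LINKERS,
) -> Decomposition:
    """Factor an SPPO into scaffold + linker + positioned R-groups.

    Scaffolds are tried in registry order; for each, in-rule linker lengths
    are tried before out-of-rule ones.  When the symmetric phenoxy ring
    admits several equivalent assignments the lexicographically smallest
    (by position, fragment canonical SMILES) is returned, which makes the
    decomposition deterministic.
    """
    mol = sppo.mol
    for scaffold in scaffolds:
        for n in linker_lengths:
            candidates = _try_match(mol, scaffold, n)
            for assignment in sorted(candidates, key=_assignment_sort_key):
                d = Decomposition(
                    sppo_id=sppo.id,
                    scaffold_id=scaffold.id,
                    n=n,
                    assignment=dict(assignment),
                    in_rule=n in IN_RULE_LINKERS,
                )
                # contract: reassembly must reproduce the input exactly
                try:
                    rebuilt = reassemble(d)
                except ReassemblyError:
                    continue
                if rebuilt.smiles == sppo.smiles:
                    return d
    raise ScaffoldMatchError(f"{sppo.id}: no scaffold match for {sppo.smiles!r}")


def reassemble(d: Decomposition) -> CompoundRecord:
    """Inverse of :func:`decompose`: rebuild the canonical molecule."""
    scaffold = get_scaffold(d.scaffold_id)
    rgroups: dict[int, str] = {}
    frag_smiles: list[str] = []
    for positions, frag in d.assignment.items():
        positions = tuple(sorted(positions))
        if frag.is_hydrogen:
            continue
        for pos in positions:
            if pos not in R_POSITIONS:
                raise ReassemblyError(f"invalid position {pos}")
            if pos in rgroups:
                raise ReassemblyError(f"position R{pos} assigned twice")
            rgroups[pos] = f"([*:{pos}])"
        frag_smiles.append(frag.with_positions(positions))
    core = Chem.MolFromSmiles(scaffold.core_smiles(d.n, rgroups))
    if core is None:
        raise ReassemblyError(f"core build failed for {d.scaffold_id}, n={d.n}")
    combined = core
    for fs in frag_smiles:
        frag_mol = Chem.MolFromSmiles(fs)
        if frag_mol is None:
            raise ReassemblyError(f"bad fragment SMILES {fs!r}")
        combined = Chem.CombineMols(combined, frag_mol)
    try:
        zipped = Chem.molzip(combined)
        Chem.SanitizeMol(zipped)
    except Exception as exc:  # noqa: BLE001
        raise ReassemblyError(f"attachment failed for {d.sppo_id}: {exc}") from exc
    return CompoundRecord(id=d.sppo_id, smiles=Chem.MolToSmiles(zipped), role=Role.SPPO)


def fragment_pool(decompositions: Sequence[Decomposition]):
    """Pool unique fragments across decompositions, tracking observed positions.

    Returns a dict pool_key -> RGroupFragment with merged
    ``positions_observed`` (ints for ordinary, position-tuples for special)
    and ``source_ids``.
    """
    pool: dict[str, RGroupFragment] = {}
    for d in decompositions:
        for positions, frag in d.assignment.items():
            key = frag.pool_key
            observed = frozenset([positions if len(positions) > 1 else positions[0]])
            if key in pool:
                prev = pool[key]
                pool[key] = RGroupFragment(
                    prev.smiles,
                    prev.positions_observed | observed,
                    tuple(dict.fromkeys(prev.source_ids + (d.sppo_id,))),
                )
            else:
                pool[key] = RGroupFragment(frag.smiles, observed, (d.sppo_id,))
    return pool
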