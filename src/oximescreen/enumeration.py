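"""Constrained combinatorial enumeration of the SPPO virtual library.

Candidates are every valence-valid (scaffold, linker length n, R-group
assignment) combination permitted by three rules:

1. n is limited to 3, 4 or 5;
2. R3 (para) comes only from the fragments observed at R3 in the input set
   (the position with the highest observed variability);
3. fragments observed at R1, R2, R4, R5 may swap freely among those four
   positions (their generation pool is the union of the four observed sets,
   plus hydrogen).

Special fused-ring fragments, when enabled, are placed only at their
observed paired positions (R2&R3 or R3&R4) and consume the R3 slot.
Duplicates are removed by canonical SMILES and, by default, the input SPPOs
themselves are excluded so the library contains only new variations.
"""

from __future__ import annotations

import gzip
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem

from .compounds import CompoundRecord, Role
from .scaffolds import (
    HYDROGEN_FRAGMENT,
    IN_RULE_LINKERS,
    SCAFFOLDS,
    Decomposition,
    RGroupFragment,
    ReassemblyError,
    ScaffoldTemplate,
    fragment_pool,
    reassemble,
)

SWAP_POSITIONS = (1, 2, 4, 5)

_PYRIDINIUM = Chem.MolFromSmarts("[n+;r6]")
_OXIME = Chem.MolFromSmarts("[CX3]=[NX2][OX2H1]")


class EnumerationError(ValueError):
    pass


@dataclass(frozen=True)
class EnumerationRules:
    """Constraint set for library generation.

    ``swap_mode`` is ``"union"`` (default: one pooled fragment set shared by
    R1/R2/R4/R5) or ``"positional"`` (each position restricted to fragments
    observed exactly there).  ``allow_out_of_rule_n`` overrides the n in
    {3,4,5} restriction.
    """

    r3_whitelist: tuple[RGroupFragment, ...]
    swap_pool: tuple[RGroupFragment, ...] = ()
    positional_pools: dict | None = None
    n_values: tuple[int, ...] = IN_RULE_LINKERS
    special_fragments: tuple[RGroupFragment, ...] = ()
    include_special: bool = True
    swap_mode: str = "union"
    exclude_inputs: bool = True
    allow_out_of_rule_n: bool = False

    def __post_init__(self) -> None:
        if not self.r3_whitelist and not (self.include_special and self.special_fragments):
            raise EnumerationError("empty R3 whitelist")
        if not self.allow_out_of_rule_n:
            bad = [n for n in self.n_values if n not in IN_RULE_LINKERS]
            if bad:
                raise EnumerationError(
                    f"linker lengths {bad} outside {{3,4,5}}; set allow_out_of_rule_n to override"
                )
        if self.swap_mode not in ("union", "positional"):
            raise EnumerationError(f"unknown swap_mode {self.swap_mode!r}")


def rules_from_decompositions(
    decompositions: Sequence[Decomposition],
    max_swap_fragments: int | None = None,
    **overrides,
) -> EnumerationRules:
    """Derive rules from an input set: R3 whitelist = fragments seen at R3;
    swap pool = union of fragments seen at R1/R2/R4/R5; specials collected
    with their observed paired positions.

    ``max_swap_fragments`` keeps only that many swap fragments (the most
    frequently observed ones, hydrogen not counted) — the same kind of
    feasibility constraint as the three enumeration rules themselves, for
    when the full cross product is larger than a run can afford.
    """
    pool = fragment_pool(decompositions)
    r3, swap, special = [], [], []
    positional: dict[int, list[RGroupFragment]] = {p: [] for p in SWAP_POSITIONS}
    for frag in pool.values():
        if frag.is_special:
            special.append(frag)
            continue
        if 3 in frag.positions_observed:
            r3.append(frag)
        for p in SWAP_POSITIONS:
            if p in frag.positions_observed:
                positional[p].append(frag)
                if frag.pool_key not in {f.pool_key for f in swap}:
                    swap.append(frag)
    if max_swap_fragments is not None:
        swap = sorted(
            (f for f in swap if not f.is_hydrogen),
            key=lambda f: (-len(f.source_ids), f.pool_key),
        )[:max_swap_fragments]
    kwargs = dict(
        r3_whitelist=tuple(sorted(r3, key=lambda f: f.pool_key)),
        swap_pool=tuple(sorted(swap, key=lambda f: f.pool_key)),
        positional_pools={p: tuple(sorted(v, key=lambda f: f.pool_key)) for p, v in positional.items()},
        special_fragments=tuple(sorted(special, key=lambda f: f.pool_key)),
    )
    kwargs.update(overrides)
    return EnumerationRules(**kwargs)


@dataclass
class Candidate:
    """One enumerated library member with full provenance."""

    record: CompoundRecord
    scaffold_id: str
    n: int
    assignment: dict

    def provenance(self) -> dict:
        return {
            "id": self.record.id,
            "smiles": self.record.smiles,
            "scaffold_id": self.scaffold_id,
            "n": self.n,
            "assignment": {
                "+".join(f"R{p}" for p in positions): frag.pool_key
                for positions, frag in self.assignment.items()
            },
        }


@dataclass
class CandidateLibrary:
    records: list[Candidate] = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def smiles(self) -> list[str]:
        return [c.record.smiles for c in self.records]


def _pool_for_position(rules: EnumerationRules, position: int) -> tuple[RGroupFragment, ...]:
    if rules.swap_mode == "positional" and rules.positional_pools:
        pool = rules.positional_pools.get(position, ())
    else:
        pool = rules.swap_pool
    # hydrogen (the unsubstituted position) is always available
    return (HYDROGEN_FRAGMENT,) + tuple(f for f in pool if not f.is_hydrogen)


def _r3_options(rules: EnumerationRules):
    """Yield (claimed position tuple, fragment) choices for the R3 slot."""
    for frag in rules.r3_whitelist:
        if not frag.is_special:
            yield (3,), frag
    if rules.include_special:
        for frag in rules.special_fragments:
            observed = [p for p in frag.positions_observed if isinstance(p, tuple)]
            for pair in sorted(observed) or [(2, 3), (3, 4)]:
                yield tuple(sorted(pair)), frag


def iter_candidates(
    rules: EnumerationRules,
    scaffolds: Sequence[ScaffoldTemplate] = SCAFFOLDS,
    input_smiles: Iterable[str] = (),
    id_prefix: str = "cand",
) -> Iterator[Candidate]:
    """Stream deduplicated candidates; memory holds only the dedup key set."""
    seen: set[str] = set(input_smiles) if rules.exclude_inputs else set()
    counter = itertools.count(1)
    for scaffold in scaffolds:
        for n in rules.n_values:
            for r3_positions, r3_frag in _r3_options(rules):
                open_positions = [p for p in SWAP_POSITIONS if p not in r3_positions]
                pools = [_pool_for_position(rules, p) for p in open_positions]
                for combo in itertools.product(*pools):
                    assignment: dict[tuple[int, ...], RGroupFragment] = {}
                    if not r3_frag.is_hydrogen:
                        assignment[r3_positions] = r3_frag
                    for pos, frag in zip(open_positions, combo):
                        if not frag.is_hydrogen:
                            assignment[(pos,)] = frag
                    d = Decomposition("candidate", scaffold.id, n, assignment)
                    try:
                        rec = reassemble(d)
                    except ReassemblyError:
                        continue  # valence-invalid combination
                    if rec.smiles in seen:
                        continue
                    seen.add(rec.smiles)
                    cid = f"{id_prefix}{next(counter):06d}"
                    yield Candidate(
                        CompoundRecord(cid, rec.smiles, Role.SPPO),
                        scaffold.id,
                        n,
                        assignment,
                    )


def enumerate_candidates(
    rules: EnumerationRules,
    scaffolds: Sequence[ScaffoldTemplate] = SCAFFOLDS,
    input_smiles: Iterable[str] = (),
    limit: int | None = None,
) -> CandidateLibrary:
    """Materialize the library with per-scaffold / per-n / per-branch stats."""
    lib = CandidateLibrary()
    per_scaffold: dict[str, int] = {}
    per_n: dict[int, int] = {}
    n_special = 0
    for cand in iter_candidates(rules, scaffolds, input_smiles):
        lib.records.append(cand)
        per_scaffold[cand.scaffold_id] = per_scaffold.get(cand.scaffold_id, 0) + 1
        per_n[cand.n] = per_n.get(cand.n, 0) + 1
        if any(len(pos) > 1 for pos in cand.assignment):
            n_special += 1
        if limit is not None and len(lib.records) >= limit:
            break
    lib.stats = {
        "total": len(lib.records),
        "per_scaffold": per_scaffold,
        "per_n": {str(k): v for k, v in sorted(per_n.items())},
        "with_special_fragment": n_special,
    }
    return lib


def is_valid_sppo(smiles: str) -> bool:
    """Structural sanity for the chemotype: one pyridinium ring, >= 1 oxime."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return (
        len(mol.GetSubstructMatches(_PYRIDINIUM)) == 1
        and len(mol.GetSubstructMatches(_OXIME)) >= 1
    )


def write_library(
    library: CandidateLibrary, smi_path: str | Path, provenance_path: str | Path | None = None
) -> None:
    """Write ``smiles<TAB>id`` lines (gzip if the suffix says so) + JSONL provenance."""
    smi_path = Path(smi_path)
    opener = gzip.open if smi_path.suffix == ".gz" else open
    with opener(smi_path, "wt") as fh:
        for cand in library.records:
            fh.write(f"{cand.record.smiles}\t{cand.record.id}\n")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            for cand in library.records:
                fh.write(json.dumps(cand.provenance()) + "\n")
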