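"""R-group decomposition and reassembly round-trips."""

import pytest

from oximescreen.compounds import CompoundRecord, canonical_smiles
from oximescreen.scaffolds import (
    SCAFFOLDS,
    Decomposition,
    RGroupFragment,
    ScaffoldMatchError,
    decompose,
    fragment_pool,
    reassemble,
)


def _frag(smiles: str) -> RGroupFragment:
    return RGroupFragment(smiles)


@pytest.mark.parametrize("scaffold_id", ["S2", "S3", "S4"])
@pytest.mark.parametrize("n", [3, 4, 5])
def test_constructed_round_trip(scaffold_id, n):
    """reassemble(decompose(m)) is the identity for hand-built molecules."""
    d = Decomposition("toy", scaffold_id, n, {(3,): _frag("[*:1]C"), (1,): _frag("[*:1]Cl")})
    rec = reassemble(d)
    back = decompose(rec)
    assert back.scaffold_id == scaffold_id
    assert back.n == n
    assert reassemble(back).smiles == rec.smiles


def test_bare_scaffold_round_trip():
    d = Decomposition("bare", "S2", 3, {})
    rec = reassemble(d)
    assert rec.smiles == canonical_smiles("ON=Cc1cccc[n+]1CCCOc2ccccc2")
    back = decompose(rec)
    assert back.assignment == {}


def test_special_fused_fragment_round_trip():
    """A fused-ring fragment at paired positions survives the round trip."""
    d = Decomposition("fused", "S2", 3, {(2, 3): _frag("[*:1]C=CC=C[*:2]")})
    rec = reassemble(d)
    # the reassembled molecule contains a naphthalene-like fused system
    assert canonical_smiles(rec.smiles) == rec.smiles
    back = decompose(rec)
    (positions,) = back.assignment.keys()
    assert len(positions) == 2
    assert abs(positions[0] - positions[1]) == 1
    assert reassemble(back).smiles == rec.smiles


def test_no_scaffold_match_is_an_error():
    with pytest.raises(ScaffoldMatchError, match="no scaffold match"):
        decompose(CompoundRecord.from_smiles("benzene", "c1ccccc1"))


def test_out_of_rule_linker_flagged_not_clamped():
    d = Decomposition("long", "S2", 6, {(3,): _frag("[*:1]C")})
    rec = reassemble(d)
    back = decompose(rec)
    assert back.n == 6
    assert back.in_rule is False


def test_fixture_round_trip_identity(sppo_fixture):
    """Every generated SPPO decomposes and reassembles to itself."""
    for rec in sppo_fixture.sppos:
        d = decompose(rec)
        assert reassemble(d).smiles == rec.smiles
        assert d.in_rule


def test_decomposition_matches_generator_provenance(sppo_fixture):
    """Recovered scaffold/linker agree with what the generator assembled."""
    by_id = {d.sppo_id: d for d in sppo_fixture.decompositions}
    for rec in sppo_fixture.sppos[:12]:
        d = decompose(rec)
        src = by_id[rec.id]
        assert d.scaffold_id == src.scaffold_id
        assert d.n == src.n


def test_fragment_pool_merges_positions():
    d1 = Decomposition("a", "S2", 3, {(3,): _frag("[*:1]C"), (1,): _frag("[*:1]Cl")})
    d2 = Decomposition("b", "S2", 4, {(2,): _frag("[*:1]C")})
    pool = fragment_pool([d1, d2])
    methyl = pool["*C"]
    assert methyl.positions_observed == frozenset({3, 2})
    assert set(methyl.source_ids) == {"a", "b"}
    assert pool["*Cl"].positions_observed == frozenset({1})


def test_decompose_deterministic(sppo_fixture):
    rec = sppo_fixture.sppos[0]
    d1, d2 = decompose(rec), decompose(rec)
    assert d1.scaffold_id == d2.scaffold_id and d1.n == d2.n
    assert {k: v.smiles for k, v in d1.assignment.items()} == {
        k: v.smiles for k, v in d2.assignment.items()
    }
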