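"""Combinatorial library generation against a brute-force oracle."""

import itertools

import pytest
from rdkit import Chem

from oximescreen.enumeration import (
    EnumerationError,
    EnumerationRules,
    enumerate_candidates,
    is_valid_sppo,
    rules_from_decompositions,
)
from oximescreen.scaffolds import SCAFFOLDS, RGroupFragment, get_scaffold


def _frag(smiles: str, positions=frozenset({3})) -> RGroupFragment:
    return RGroupFragment(smiles, positions)


def _oracle_library(scaffolds, n_values, r3_bodies, swap_bodies):
    """Independent brute force: assemble candidate SMILES by direct string
    substitution into the scaffold template (no molzip), canonicalize, dedup.

    Fragment "bodies" are plain SMILES written attachment-atom-first, e.g.
    "OC" for methoxy.
    """
    out = set()
    swap_options = [None] + list(swap_bodies)  # None = hydrogen
    for scaffold in scaffolds:
        for n in n_values:
            for r3 in r3_bodies:
                for combo in itertools.product(swap_options, repeat=4):
                    rgroups = {3: f"({r3})"}
                    for pos, body in zip((1, 2, 4, 5), combo):
                        if body is not None:
                            rgroups[pos] = f"({body})"
                    smi = scaffold.core_smiles(n, rgroups)
                    mol = Chem.MolFromSmiles(smi)
                    assert mol is not None, smi
                    out.add(Chem.MolToSmiles(mol))
    return out


def test_enumerator_equals_brute_force_oracle():
    """Streaming enumerator and string-assembly oracle emit the same set."""
    r3_bodies = ["C", "OC"]
    swap_bodies = ["F", "Cl"]
    rules = EnumerationRules(
        r3_whitelist=tuple(_frag(f"[*:1]{b}") for b in r3_bodies),
        swap_pool=tuple(_frag(f"[*:1]{b}", frozenset({1, 2, 4, 5})) for b in swap_bodies),
        n_values=(3, 4),
    )
    library = enumerate_candidates(rules, scaffolds=SCAFFOLDS[:1])
    oracle = _oracle_library(SCAFFOLDS[:1], (3, 4), r3_bodies, swap_bodies)
    assert set(library.smiles) == oracle


def test_r3_only_count_is_exact():
    """With hydrogen-only swap pools the library is |scaffolds|*|n|*|R3|."""
    r3 = tuple(_frag(f"[*:1]{b}") for b in
               ["C", "CC", "CCC", "C(C)C", "C(C)(C)C", "F", "Cl", "Br", "I", "OC",
                "OCC", "O", "CO", "C#N", "[N+](=O)[O-]", "C(F)(F)F", "N", "N(C)C",
                "c1ccccc1"])
    assert len(r3) == 19
    rules = EnumerationRules(r3_whitelist=r3, swap_pool=(), n_values=(3, 4, 5))
    library = enumerate_candidates(rules, scaffolds=SCAFFOLDS[:1])
    assert len(library) == 57  # 3 linker lengths x 19 para fragments


def test_out_of_rule_n_rejected_unless_overridden():
    r3 = (_frag("[*:1]C"),)
    with pytest.raises(EnumerationError, match="outside"):
        EnumerationRules(r3_whitelist=r3, n_values=(6,))
    rules = EnumerationRules(r3_whitelist=r3, n_values=(6,), allow_out_of_rule_n=True)
    library = enumerate_candidates(rules, scaffolds=SCAFFOLDS[:1])
    assert len(library) == 1


def test_empty_r3_whitelist_rejected():
    with pytest.raises(EnumerationError, match="empty R3"):
        EnumerationRules(r3_whitelist=())


def test_dedup_soundness_and_structural_sanity():
    rules = EnumerationRules(
        r3_whitelist=(_frag("[*:1]C"), _frag("[*:1]F")),
        swap_pool=(_frag("[*:1]Cl", frozenset({1, 2, 4, 5})),),
        n_values=(3,),
    )
    library = enumerate_candidates(rules)
    smiles = library.smiles
    assert len(smiles) == len(set(smiles))
    assert all(is_valid_sppo(s) for s in smiles)


def test_input_structures_excluded_by_default(sppo_fixture):
    decomps = sppo_fixture.decompositions
    rules = rules_from_decompositions(decomps, max_swap_fragments=1)
    input_smiles = [r.smiles for r in sppo_fixture.sppos]
    library = enumerate_candidates(rules, input_smiles=input_smiles)
    assert not set(library.smiles) & set(input_smiles)
    # with exclusion off, some inputs reappear (they satisfy the rules)
    rules_in = rules_from_decompositions(decomps, max_swap_fragments=1, exclude_inputs=False)
    library_in = enumerate_candidates(rules_in, input_smiles=input_smiles)
    assert len(library_in) >= len(library)


def test_special_fragments_occupy_paired_positions(sppo_fixture):
    rules = rules_from_decompositions(sppo_fixture.decompositions, max_swap_fragments=0)
    assert rules.special_fragments  # the generator planted fused-ring members
    library = enumerate_candidates(rules)
    special = [c for c in library.records if any(len(p) > 1 for p in c.assignment)]
    assert special
    for cand in special:
        (positions,) = [p for p in cand.assignment if len(p) > 1]
        assert positions in ((2, 3), (3, 4))
        assert is_valid_sppo(cand.record.smiles)


def test_rules_derivation_collects_r3_whitelist(sppo_fixture):
    rules = rules_from_decompositions(sppo_fixture.decompositions)
    observed_r3 = {
        frag.pool_key
        for d in sppo_fixture.decompositions
        for pos, frag in d.assignment.items()
        if pos == (3,)
    }
    assert {f.pool_key for f in rules.r3_whitelist} == observed_r3
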