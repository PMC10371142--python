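"""Ground-truth faithfulness and determinism of the synthetic data generators."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from oximescreen.compounds import read_compounds
from oximescreen.fixtures import (
    LOGBB_COEFFICIENTS,
    LOGBB_DESCRIPTORS,
    LOGBB_INTERCEPT,
    FixtureError,
    FixtureSpec,
    generate_logbb_fixture,
    generate_sppo_fixture,
)
from oximescreen.descriptors import compute_descriptors
from oximescreen.tasks import bin_logbb, bin_reactivation


def test_zero_noise_percents_reproduce_ledger():
    fx = generate_sppo_fixture(FixtureSpec(seed=5, n_sppos=20, noise_rate=0.0))
    binned = [bin_reactivation(p) for p in fx.measurements.reactivation_percent]
    assert binned == list(fx.ledger.true_class)
    assert not fx.ledger.flipped.any()


def test_seeded_determinism():
    a = generate_sppo_fixture(FixtureSpec(seed=9, n_sppos=15))
    b = generate_sppo_fixture(FixtureSpec(seed=9, n_sppos=15))
    assert [r.smiles for r in a.sppos] == [r.smiles for r in b.sppos]
    assert a.measurements.equals(b.measurements)
    la = generate_logbb_fixture(FixtureSpec(seed=9, n_logbb=60))
    lb = generate_logbb_fixture(FixtureSpec(seed=9, n_logbb=60))
    assert la.table.equals(lb.table)


def test_label_flip_fraction_within_binomial_ci():
    """At noise 0.05 over 600 pairs the realized flip count sits inside the
    99% binomial band, and flips are exactly the ledger's flagged rows."""
    fx = generate_sppo_fixture(FixtureSpec(seed=13, n_sppos=150, noise_rate=0.05))
    assert len(fx.ledger) == 600
    emitted = [bin_reactivation(p) for p in fx.measurements.reactivation_percent]
    mismatch = [e != t for e, t in zip(emitted, fx.ledger.true_class)]
    assert mismatch == list(fx.ledger.flipped)
    lo, hi = stats.binom.interval(0.99, 600, 0.05)
    assert lo <= sum(mismatch) <= hi


def test_generated_structures_pass_ingestion(tmp_path, sppo_fixture):
    sppo_fixture.save(tmp_path)
    records = read_compounds(tmp_path / "sppos.csv")
    assert len(records) == len(sppo_fixture.sppos)
    assert (tmp_path / "reactivation.csv").exists()


def test_noiseless_logbb_recovers_coefficients():
    fx = generate_logbb_fixture(FixtureSpec(seed=3, n_logbb=120, logbb_noise_sd=0.0))
    X = np.array(
        [
            [compute_descriptors(s).as_dict()[d] for d in LOGBB_DESCRIPTORS]
            for s in fx.table.smiles
        ]
    )
    design = np.hstack([X, np.ones((len(X), 1))])
    coef, *_ = np.linalg.lstsq(design, fx.table.logBB.to_numpy(), rcond=None)
    np.testing.assert_allclose(coef[:-1], LOGBB_COEFFICIENTS, atol=1e-6)
    assert coef[-1] == pytest.approx(LOGBB_INTERCEPT, abs=1e-6)


def test_logbb_both_classes_populated(logbb_fixture):
    tallies = Counter(bin_logbb(v) for v in logbb_fixture.table.logBB)
    assert tallies["BBB+"] > 0 and tallies["BBB-"] > 0


def test_logbb_diversity_limit_is_an_error():
    with pytest.raises(FixtureError, match="diversity"):
        generate_logbb_fixture(FixtureSpec(seed=1, n_logbb=10_000_000))


def test_invalid_noise_rate_rejected():
    with pytest.raises(FixtureError, match="noise rate"):
        FixtureSpec(seed=1, noise_rate=0.7)


def test_planted_class_is_rule_consistent(sppo_fixture):
    """planted_class on training pairs equals the ledger's true class."""
    by_id = {r.id: r for r in sppo_fixture.sppos}
    ops = {r.id: r for r in sppo_fixture.ops}
    sample = sppo_fixture.ledger.sample(10, random_state=0)
    for _, row in sample.iterrows():
        got = sppo_fixture.planted_class(by_id[row.sppo_id].smiles, ops[row.op_id].smiles)
        assert got == row.true_class
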