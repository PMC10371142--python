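"""Reactivation binning, logBB thresholding, dataset assembly, broad-spectrum logic."""

import numpy as np
import pandas as pd
import pytest

from oximescreen.compounds import op_panel
from oximescreen.tasks import (
    BinningError,
    DatasetError,
    assemble_bbb_dataset,
    assemble_reactivation_dataset,
    bin_logbb,
    bin_reactivation,
    predict_broad_spectrum,
)


@pytest.mark.parametrize(
    "percent,expected",
    [
        (0.0, "No"),
        (0.5, "No"),     # boundary of the zero tolerance
        (-0.4, "No"),    # small negative within tolerance
        (0.51, "Low"),
        (40.0, "Low"),   # 40% boundary belongs to Low
        (40.01, "High"),
        (63.0, "High"),
        (110.0, "High"),
    ],
)
def test_reactivation_bins(percent, expected):
    assert bin_reactivation(percent) == expected


@pytest.mark.parametrize("percent", [-11.0, 111.0, float("nan"), -5.0])
def test_reactivation_out_of_range_rejected(percent):
    with pytest.raises(BinningError):
        bin_reactivation(percent)


def test_reactivation_binning_total_and_monotone():
    order = {"No": 0, "Low": 1, "High": 2}
    grid = np.linspace(-0.5, 110, 500)
    classes = [bin_reactivation(p) for p in grid]
    ranks = [order[c] for c in classes]
    assert ranks == sorted(ranks)  # order-preserving
    assert set(classes) == {"No", "Low", "High"}


@pytest.mark.parametrize(
    "logbb,expected", [(0.5, "BBB+"), (-1.2, "BBB-"), (0.0, "BBB-"), (1e-9, "BBB+")]
)
def test_logbb_bins(logbb, expected):
    assert bin_logbb(logbb) == expected


def test_logbb_nonfinite_rejected():
    with pytest.raises(BinningError):
        bin_logbb(float("inf"))


def test_assembly_tallies_match_generator_ledger(sppo_fixture, reactivation_dataset):
    from collections import Counter

    expected = Counter(sppo_fixture.ledger.emitted_class)
    assert reactivation_dataset.tallies == expected
    # row conservation
    assert len(reactivation_dataset) == len(sppo_fixture.measurements)


def test_assembly_rejects_empty_and_unknown_ids(sppo_fixture):
    with pytest.raises(DatasetError, match="empty"):
        assemble_reactivation_dataset(
            pd.DataFrame(columns=["sppo_id", "op_id", "reactivation_percent"]),
            sppo_fixture.sppos,
            sppo_fixture.ops,
        )
    bad = pd.DataFrame(
        {"sppo_id": ["GHOST"], "op_id": ["PIMP"], "reactivation_percent": [10.0]}
    )
    with pytest.raises(DatasetError, match="GHOST"):
        assemble_reactivation_dataset(bad, sppo_fixture.sppos, sppo_fixture.ops)


def test_assembly_conflicting_duplicates_listed(sppo_fixture):
    rows = pd.DataFrame(
        {
            "sppo_id": ["SPPO001", "SPPO001"],
            "op_id": ["PIMP", "PIMP"],
            "reactivation_percent": [10.0, 80.0],  # Low vs High
        }
    )
    with pytest.raises(DatasetError, match="SPPO001"):
        assemble_reactivation_dataset(rows, sppo_fixture.sppos, sppo_fixture.ops)


def test_assembly_averages_replicates(sppo_fixture):
    rows = pd.DataFrame(
        {
            "sppo_id": ["SPPO001"] * 3,
            "op_id": ["PIMP"] * 3,
            "reactivation_percent": [50.0, 60.0, 70.0],
            "replicate": [1, 2, 3],
        }
    )
    ds = assemble_reactivation_dataset(rows, sppo_fixture.sppos, sppo_fixture.ops)
    assert len(ds) == 1
    assert ds.percents[0] == pytest.approx(60.0)
    assert ds.labels[0] == "High"


def test_bbb_assembly_column_mapping(logbb_fixture):
    renamed = logbb_fixture.table.rename(
        columns={"compound_id": "NO.", "smiles": "SMILES", "logBB": "logbb_exp"}
    )
    ds = assemble_bbb_dataset(
        renamed, column_map={"NO.": "compound_id", "SMILES": "smiles", "logbb_exp": "logBB"}
    )
    assert len(ds) == len(logbb_fixture.table)
    assert set(ds.tallies) <= {"BBB+", "BBB-"}


def test_broad_spectrum_is_all_high_reduction(reactivation_result, sppo_fixture):
    """The flag equals an independently computed row-wise all-High check and
    is monotone non-increasing as the panel grows."""
    model = reactivation_result.model
    candidates = [r.smiles for r in sppo_fixture.sppos[:6]]
    panel5 = op_panel(("PIMP", "NEMP", "PXN", "DFP", "GV"))
    out5 = predict_broad_spectrum(model, candidates, panel5)
    op_cols = [c for c in out5.columns if c != "broad_spectrum"]
    # set-logic oracle on the per-OP classes
    expected = (out5[op_cols] == "High").all(axis=1)
    assert (out5["broad_spectrum"] == expected).all()
    # growing the panel can only lose the flag
    out2 = predict_broad_spectrum(model, candidates, panel5[:2])
    for smi in candidates:
        if out5.loc[smi, "broad_spectrum"]:
            assert out2.loc[smi, "broad_spectrum"]


def test_broad_spectrum_empty_panel_rejected(reactivation_result):
    with pytest.raises(DatasetError, match="empty OP panel"):
        predict_broad_spectrum(reactivation_result.model, ["CCO"], [])
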