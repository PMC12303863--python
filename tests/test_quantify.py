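"""Per-residue roll-up: PSM weighting, unique-peptide intensity aggregation,
conservation and additivity laws, and the brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from pepcover import (
    ConfigurationError,
    DataError,
    TargetEntry,
    coverage_summary,
    match_peptides,
    quantify_positions,
)
from tests.conftest import make_records, oracle_position_sums


def _matches(rows):
    return pd.DataFrame(rows, columns=["record_id", "target_id", "start", "end"])


def test_single_peptide_without_psm_counts_one_per_position():
    records = make_records([{"stripped_sequence": "AAAAAA"}])
    matches = _matches([("r000000", "T", 3, 8)])
    quant = quantify_positions(matches, records, metric="psm")
    assert list(quant["position"]) == [3, 4, 5, 6, 7, 8]
    assert set(quant["value"]) == {1.0}
    assert quant["value"].sum() == 6  # match length x weight 1


def test_psm_weighted_accumulation_over_overlapping_peptides():
    records = make_records([
        {"record_id": "a", "stripped_sequence": "AAAA", "psm": 2},
        {"record_id": "b", "stripped_sequence": "CCCC", "psm": 1},
    ])
    matches = _matches([("a", "T", 1, 4), ("b", "T", 3, 6)])
    quant = quantify_positions(matches, records, metric="psm")
    expected = {1: 2.0, 2: 2.0, 3: 3.0, 4: 3.0, 5: 1.0, 6: 1.0}
    assert dict(zip(quant["position"], quant["value"])) == expected


def test_intensity_mode_aggregates_duplicate_sequences_before_rollup():
    records = make_records([
        {"record_id": "a", "stripped_sequence": "AAAA", "intensity": 100.0},
        {"record_id": "b", "stripped_sequence": "AAAA", "intensity": 50.0},
    ])
    matches = _matches([("a", "T", 2, 5), ("b", "T", 2, 5)])
    quant = quantify_positions(matches, records, metric="intensity")
    assert list(quant["position"]) == [2, 3, 4, 5]
    assert set(quant["value"]) == {150.0}


def test_distinct_peptides_mode_counts_unique_sequences():
    records = make_records([
        {"record_id": "a", "stripped_sequence": "AAAA", "psm": 5},
        {"record_id": "b", "stripped_sequence": "AAAA", "psm": 2},
        {"record_id": "c", "stripped_sequence": "CCCC", "psm": 1},
    ])
    matches = _matches([("a", "T", 1, 4), ("b", "T", 1, 4), ("c", "T", 3, 6)])
    quant = quantify_positions(matches, records, metric="psm", distinct_peptides=True)
    got = dict(zip(quant["position"], quant["value"]))
    assert got == {1: 1, 2: 1, 3: 2, 4: 2, 5: 1, 6: 1}


def test_psm_conservation_on_random_instances():
    """Positional sums equal sum(match length x psm weight); values agree with
    a brute-force per-position loop."""
    rng = np.random.default_rng(2024)
    for _ in range(25):
        n = int(rng.integers(1, 20))
        rows, mrows = [], []
        for i in range(n):
            length = int(rng.integers(3, 12))
            start = int(rng.integers(1, 90))
            psm = float(rng.integers(1, 5)) if rng.random() < 0.7 else np.nan
            rows.append({"record_id": f"p{i}", "stripped_sequence": f"S{i}" * 2,
                         "psm": psm})
            mrows.append((f"p{i}", "T", start, start + length - 1))
        records = make_records(rows)
        quant = quantify_positions(_matches(mrows), records, metric="psm")
        weights = [1.0 if np.isnan(r["psm"]) else r["psm"] for r in rows]
        expected_total = sum((m[3] - m[2] + 1) * w for m, w in zip(mrows, weights))
        assert quant["value"].sum() == pytest.approx(expected_total)
        oracle = oracle_position_sums(
            [(m[2], m[3], w) for m, w in zip(mrows, weights)])
        assert dict(zip(quant["position"], quant["value"])) == pytest.approx(oracle)


def test_intensity_values_bounded_by_group_total():
    rng = np.random.default_rng(7)
    rows, mrows = [], []
    for i in range(15):
        seq = ["AAAA", "CCCC", "DDDD"][i % 3]
        rows.append({"record_id": f"p{i}", "stripped_sequence": seq,
                     "intensity": float(rng.uniform(10, 1000))})
        start = int(rng.integers(1, 50))
        mrows.append((f"p{i}", "T", start, start + 3))
    records = make_records(rows)
    quant = quantify_positions(_matches(mrows), records, metric="intensity")
    total = records["intensity"].sum()
    assert (quant["value"] <= total + 1e-9).all()


def test_group_additivity():
    """Quantifying disjoint groups separately equals one grouped run."""
    rows, mrows = [], []
    for i, donor in enumerate(["D1", "D1", "D2"]):
        rows.append({"record_id": f"p{i}", "stripped_sequence": "AAAA",
                     "psm": i + 1, "donor": donor})
        mrows.append((f"p{i}", "T", 2 + i, 5 + i))
    records = make_records(rows)
    matches = _matches(mrows)
    combined = quantify_positions(matches, records, metric="psm", group_by=["donor"])
    for donor in ("D1", "D2"):
        solo_records = records[records["donor"] == donor]
        solo_matches = matches[matches["record_id"].isin(solo_records["record_id"])]
        solo = quantify_positions(solo_matches, solo_records, metric="psm")
        part = combined[combined["donor"] == donor]
        assert dict(zip(part["position"], part["value"])) == \
            dict(zip(solo["position"], solo["value"]))


def test_metric_errors():
    records = make_records([{"stripped_sequence": "AAAA"}])
    matches = _matches([("r000000", "T", 1, 4)])
    with pytest.raises(ConfigurationError):
        quantify_positions(matches, records, metric="xic")
    with pytest.raises(ConfigurationError, match="intensity"):
        quantify_positions(matches, records, metric="intensity")
    negative = make_records([{"stripped_sequence": "AAAA", "psm": -1}])
    with pytest.raises(DataError, match="r000000"):
        quantify_positions(matches, negative, metric="psm")


def test_coverage_summary_counts_and_fraction():
    target = TargetEntry("T", "A" * 10)
    records = make_records([{"stripped_sequence": "AAAAAA"}])
    matches = match_peptides(records, [target]).matches
    quant = quantify_positions(matches[matches["start"] == 3], records, metric="psm")
    summary = coverage_summary(quant, [target])
    assert summary.iloc[0]["covered"] == 6
    assert summary.iloc[0]["fraction"] == pytest.approx(0.6)

    empty = coverage_summary(quant.iloc[0:0], [target], expected_groups=[("T",)])
    assert empty.iloc[0]["covered"] == 0 and empty.iloc[0]["fraction"] == 0.0

    with pytest.raises(Exception):
        coverage_summary(quant.assign(target_id="UNKNOWN"), [target])


def test_coverage_summary_independent_rows_per_group():
    records = make_records([
        {"record_id": "a", "stripped_sequence": "AAA", "donor": "D1"},
        {"record_id": "b", "stripped_sequence": "AAA", "donor": "D2"},
    ])
    matches = _matches([("a", "T", 1, 3), ("b", "T", 8, 10)])
    quant = quantify_positions(matches, records, metric="psm", group_by=["donor"])
    summary = coverage_summary(quant, [TargetEntry("T", "A" * 10)])
    assert len(summary) == 2
    assert set(summary["covered"]) == {3}
    assert set(summary["donor"]) == {"D1", "D2"}
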