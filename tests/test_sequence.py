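"""Stripping and PTM extraction: grammar examples, terminal conventions,
annotation-table joins, and the stripping fuzz property."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepcover import (
    CTERM,
    NTERM,
    ConfigurationError,
    NotationError,
    extract_ptms,
    get_dialect,
    normalize_mass_label,
    strip_sequence,
)
from tests.conftest import make_records

COMET = get_dialect("comet").grammar
PEAKS = get_dialect("peaks").grammar
MAXQUANT = get_dialect("maxquant").grammar
MSFRAGGER = get_dialect("msfragger").grammar
SPECTRONAUT = get_dialect("spectronaut").grammar
DIANN = get_dialect("diann").grammar


@pytest.mark.parametrize("modified, grammar, expected", [
    ("NDEQIL", COMET, "NDEQIL"),                      # identity on plain input
    ("K.PEPS[79.9663]TIDE.R", COMET, "PEPSTIDE"),     # flanks + bracketed mass
    ("_AC(Phospho (S))DEFK_", MAXQUANT, "ACDEFK"),    # terminals + nested payload
    ("_ACDE[Phospho (STY)]FK_", SPECTRONAUT, "ACDEFK"),
    ("n[42.0106]PEPTIDEc[17.0027]", MSFRAGGER, "PEPTIDE"),
    ("ACDE(UniMod:21)FK", DIANN, "ACDEFK"),
    ("PEPT(+79.97)IDE", PEAKS, "PEPTIDE"),
])
def test_strip_examples(modified, grammar, expected):
    assert strip_sequence(modified, grammar) == expected


def test_strip_is_idempotent_and_preserves_residue_count():
    modified = "K.PEPS[79.9663]TI[15.9949]DE.R"
    once = strip_sequence(modified, COMET)
    assert strip_sequence(once, COMET) == once
    n_residues = sum(c.isupper() and c.isalpha() for c in "PEPSTIDE")
    assert len(once) == n_residues


@pytest.mark.parametrize("bad, grammar, fragment", [
    ("PEP[79.97TIDE", COMET, "unbalanced"),
    ("PEP]TIDE", COMET, "unbalanced"),
    ("PEP1TIDE", COMET, "non-residue"),
    ("(+42.0)PEP", PEAKS, "terminal"),  # leading mod, grammar has no terminal marker
])
def test_notation_errors_carry_offsets(bad, grammar, fragment):
    with pytest.raises(NotationError, match=fragment) as err:
        strip_sequence(bad, grammar)
    assert "offset" in str(err.value)


@given(st.lists(
    st.tuples(
        st.text(alphabet="ACDEFGHIKLMNPQRSTWYV", min_size=1, max_size=6),
        st.sampled_from(["(+79.9663)", "(-17.0265)", "(+0.984)"]),
    ),
    min_size=1, max_size=5,
))
def test_fuzz_stripping_recovers_plain_sequence(pieces):
    """Random plain sequences decorated with grammar-valid annotations strip
    back to the original sequence exactly."""
    plain = "".join(chunk for chunk, _ in pieces)
    decorated = "".join(chunk + ann for chunk, ann in pieces)
    assert strip_sequence(decorated, PEAKS) == plain
    assert len(strip_sequence(decorated, PEAKS)) == len(plain)


def test_single_ptm_position_counts_preceding_residues():
    records = make_records([{"modified_sequence": "PEPT(+79.97)IDE",
                             "stripped_sequence": "PEPTIDE"}])
    ptms = extract_ptms(records, grammar=PEAKS)
    assert len(ptms) == 1
    row = ptms.iloc[0]
    assert row["ptm_position"] == 4
    assert row["ptm_label"] == "+79.97"
    assert not row["multi_ptm"]


def test_unmodified_peptide_contributes_zero_rows():
    records = make_records([{"modified_sequence": "PEPTIDE",
                             "stripped_sequence": "PEPTIDE"}])
    assert len(extract_ptms(records, grammar=PEAKS)) == 0


def test_multi_ptm_expansion_marks_all_rows():
    records = make_records([{"modified_sequence": "AC(+57.02)DE(+79.97)FK",
                             "stripped_sequence": "ACDEFK"}])
    ptms = extract_ptms(records, grammar=PEAKS)
    assert list(ptms["ptm_position"]) == [2, 4]
    assert list(ptms["multi_ptm"]) == [True, True]


def test_multi_ptm_flag_matches_row_count_per_record():
    records = make_records([
        {"modified_sequence": "AC(+57.02)DE(+79.97)FK", "stripped_sequence": "ACDEFK"},
        {"modified_sequence": "PEPT(+79.97)IDE", "stripped_sequence": "PEPTIDE"},
        {"modified_sequence": "PEPTIDE", "stripped_sequence": "PEPTIDE"},
    ])
    ptms = extract_ptms(records, grammar=PEAKS)
    for _, grp in ptms.groupby("record_id"):
        assert set(grp["multi_ptm"]) == {len(grp) > 1}
    assert ptms["record_id"].nunique() <= len(records)


def test_terminal_annotations_map_to_symbolic_positions():
    mq = make_records([{"modified_sequence": "_(Acetyl (Protein N-term))ACDK_",
                        "stripped_sequence": "ACDK"}])
    assert list(extract_ptms(mq, grammar=MAXQUANT)["ptm_position"]) == [NTERM]
    frag = make_records([{"modified_sequence": "n[42.0106]ACDKc[17.0027]",
                          "stripped_sequence": "ACDK"}])
    assert list(extract_ptms(frag, grammar=MSFRAGGER)["ptm_position"]) == [NTERM, CTERM]


def test_ptm_table_join_by_name_and_by_mass_tolerance():
    records = make_records([
        {"modified_sequence": "PEPT(+79.9663)IDE", "stripped_sequence": "PEPTIDE"},
        {"modified_sequence": "_AC(Oxidation (M))DK_", "stripped_sequence": "ACDK"},
    ])
    table = pd.DataFrame([
        {"ptm_key": "79.97", "display_label": "Phospho", "display_color": "#ff0000"},
        {"ptm_key": "Oxidation (M)", "display_label": "Ox", "display_color": "#00ff00"},
    ])
    peaks_rows = extract_ptms(records.iloc[:1], grammar=PEAKS, ptm_table=table)
    assert peaks_rows.iloc[0]["ptm_label"] == "Phospho"
    assert peaks_rows.iloc[0]["display_color"] == "#ff0000"
    mq_rows = extract_ptms(records.iloc[1:], grammar=MAXQUANT, ptm_table=table)
    assert mq_rows.iloc[0]["ptm_label"] == "Ox"
    assert mq_rows.iloc[0]["display_color"] == "#00ff00"


def test_unknown_ptm_keeps_raw_label_and_gets_palette_color():
    records = make_records([{"modified_sequence": "PEPT(+123.4567)IDE",
                             "stripped_sequence": "PEPTIDE"}])
    ptms = extract_ptms(records, grammar=PEAKS)
    assert ptms.iloc[0]["ptm_label"] == "+123.46"
    assert str(ptms.iloc[0]["display_color"]).startswith("#")


def test_duplicate_ptm_table_keys_rejected():
    records = make_records([{"modified_sequence": "PEPT(+79.97)IDE",
                             "stripped_sequence": "PEPTIDE"}])
    table = pd.DataFrame([
        {"ptm_key": "79.97", "display_label": "A", "display_color": "#111111"},
        {"ptm_key": "79.97", "display_label": "B", "display_color": "#222222"},
    ])
    with pytest.raises(ConfigurationError):
        extract_ptms(records, grammar=PEAKS, ptm_table=table)


def test_mass_labels_render_signed_two_decimals():
    assert normalize_mass_label(79.9663) == "+79.97"
    assert normalize_mass_label(-17.02655) == "-17.03"
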