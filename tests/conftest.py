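"""Shared fixtures and independent oracles.

The oracles here are deliberately written from first principles (hand-spelled
degeneracy class table, per-position accumulation loops) so they share no code
with the implementation they check.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: independent degeneracy class table, spelled out by hand:
#: N/D pair with B, E/Q pair with Z, I and L are interchangeable, X wildcards
ORACLE_CLASSES = {
    "N": set("NBX"), "D": set("DBX"), "B": set("BNDX"),
    "E": set("EZX"), "Q": set("QZX"), "Z": set("ZEQX"),
    "I": set("ILX"), "L": set("ILX"),
    "X": set("ACDEFGHIKLMNPQRSTVWYBZXUO"),
}
for _r in "ACFGHKMPRSTVWYUO":
    ORACLE_CLASSES[_r] = {_r, "X"}

FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZXUO"


def oracle_match_starts(peptide: str, target: str) -> list[int]:
    """Brute-force sliding-window matcher: test class membership at every
    offset; 1-based start positions of all (overlapping) matches."""
    L = len(peptide)
    starts = []
    for s in range(len(target) - L + 1):
        if all(target[s + i] in ORACLE_CLASSES[peptide[i]] for i in range(L)):
            starts.append(s + 1)
    return starts


def oracle_position_sums(entries) -> dict[int, float]:
    """Brute-force per-position accumulation: entries of (start, end, weight)."""
    values: dict[int, float] = {}
    for start, end, weight in entries:
        for pos in range(start, end + 1):
            values[pos] = values.get(pos, 0.0) + weight
    return values


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical record table from minimal row dicts."""
    defaults = {
        "source_file": "test", "modified_sequence": "", "stripped_sequence": "",
        "psm": np.nan, "intensity": np.nan, "area": np.nan, "charge": np.nan,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["record_id"] = row.get("record_id", f"r{i:06d}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    import matplotlib.pyplot as plt

    plt.close("all")


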