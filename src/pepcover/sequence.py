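"""Sequence stripping and PTM extraction.

Search engines print the same peptide in many notations: Comet adds flanking
residues (``K.PEPS[79.9663]TIDE.R``), MaxQuant wraps sequences in underscores
and spells modifications as nested parenthesised names
(``_AC(Phospho (S))DEFK_``), DIA-NN uses UniMod accessions, MSFragger marks
termini with lowercase ``n``/``c``. This module reduces all of them to two
canonical artifacts:

* the *stripped sequence* — uppercase residue letters only, and
* a table of :data:`PTM records <PTM_COLUMNS>` — one row per modification
  occurrence, positioned 1-based within the stripped peptide (terminal
  modifications get the symbolic positions ``NTERM`` / ``CTERM``).

Positions are computed as the number of residue letters preceding the
annotation in the modified string, i.e. an annotation modifies the residue it
follows. Mass-delta labels are normalised to a signed 2-decimal string
(``+79.97``) so that differently rounded sources join consistently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .dialects import RESIDUE_ALPHABET, ModificationGrammar, get_dialect
from .errors import ConfigurationError, DataError, NotationError

NTERM = "NTERM"
CTERM = "CTERM"

#: columns of the PTM record table
PTM_COLUMNS = ["record_id", "ptm_label", "ptm_position", "ptm_mass", "multi_ptm", "display_color"]

#: fixed cycling palette for PTM labels absent from the user annotation table
DEFAULT_PTM_PALETTE = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
    "#a65628", "#f781bf", "#17becf", "#666666", "#bcbd22",
)


@dataclass(frozen=True)
class Annotation:
    """One modification annotation found in a modified peptide string."""

    position: object  # int (1-based) or NTERM / CTERM
    payload: str


@dataclass(frozen=True)
class ParsedPeptide:
    stripped: str
    annotations: tuple[Annotation, ...]


def normalize_mass_label(mass: float) -> str:
    """Render a mass delta as the canonical signed 2-decimal label, e.g. ``+79.97``."""
    return f"{mass:+.2f}"


def _strip_flanking(s: str) -> str:
    # "K.PEPTIDE.R" or "-.PEPTIDE.K": one residue (or '-') on each side of a dot
    if len(s) >= 2 and s[1] == "." and (s[0] in RESIDUE_ALPHABET or s[0] == "-"):
        s = s[2:]
    if len(s) >= 2 and s[-2] == "." and (s[-1] in RESIDUE_ALPHABET or s[-1] == "-"):
        s = s[:-2]
    return s


def parse_modified(modified: str, grammar: ModificationGrammar) -> ParsedPeptide:
    """Tokenise a modified peptide string into residues + annotations.

    Raises
    ------
    NotationError
        On unbalanced delimiters, annotations before any residue in a grammar
        without a terminal convention, or residual non-residue characters.
    """
    s = modified.strip()
    if grammar.flanking:
        s = _strip_flanking(s)

    residues: list[str] = []
    raw: list[tuple[object, str]] = []  # (position or marker, payload)
    after_closing_terminal = False
    i, n = 0, len(s)
    while i < n:
        ch = s[i]
        if ch == "_" and grammar.terminal == "underscore":
            if i > 0 and residues:
                after_closing_terminal = True
            i += 1
            continue
        if grammar.terminal == "nc" and ch in "nc" and i + 1 < n and s[i + 1] == grammar.opener:
            marker = NTERM if ch == "n" else CTERM
            payload, i = _read_payload(s, i + 1, grammar)
            raw.append((marker, payload))
            continue
        if ch == grammar.opener:
            start = i
            payload, i = _read_payload(s, i, grammar)
            if after_closing_terminal:
                raw.append((CTERM, payload))
            elif not residues:
                if grammar.terminal is None:
                    raise NotationError(
                        "modification before any residue in a grammar without "
                        "a terminal convention", offset=start,
                    )
                raw.append((NTERM, payload))
            else:
                raw.append((len(residues), payload))
            continue
        if ch == grammar.closer:
            raise NotationError(f"unbalanced closing delimiter {ch!r}", offset=i)
        up = ch.upper()
        if up in RESIDUE_ALPHABET and ch.isalpha():
            residues.append(up)
            i += 1
            continue
        raise NotationError(f"residual non-residue character {ch!r}", offset=i)

    return ParsedPeptide("".join(residues), tuple(Annotation(p, pl) for p, pl in raw))


def _read_payload(s: str, start: int, grammar: ModificationGrammar) -> tuple[str, int]:
    """Read one delimited payload starting at ``s[start] == opener``.

    Returns the payload text and the index just past the closing delimiter.
    Supports nested same-type delimiters when the grammar allows them.
    """
    depth = 0
    for j in range(start, len(s)):
        c = s[j]
        if c == grammar.opener:
            depth += 1
            if depth > 1 and not grammar.nested:
                raise NotationError("nested delimiter in a non-nesting grammar", offset=j)
        elif c == grammar.closer:
            depth -= 1
            if depth == 0:
                return s[start + 1 : j], j + 1
    raise NotationError(f"unbalanced opening delimiter {grammar.opener!r}", offset=start)


def strip_sequence(modified: str, grammar: ModificationGrammar) -> str:
    """Strip modification annotations, terminal markers and flanking residues.

    The result contains only uppercase residue letters, in original order.
    Idempotent: stripping an already-plain sequence returns it unchanged.
    """
    return parse_modified(modified, grammar).stripped


def strip_table(records: pd.DataFrame, platform: str | None = None,
                grammar: ModificationGrammar | None = None) -> pd.DataFrame:
    """Fill ``stripped_sequence`` from ``modified_sequence`` where empty.

    Rows whose source already provided a stripped sequence keep it (uppercased).
    Exactly one of ``platform`` / ``grammar`` selects the modification grammar.
    """
    if grammar is None:
        if platform is None:
            raise ConfigurationError("strip_table needs a platform or an explicit grammar")
        grammar = get_dialect(platform).grammar
    out = records.copy()

    def _one(row: pd.Series) -> str:
        stripped = row.get("stripped_sequence")
        if isinstance(stripped, str) and stripped:
            return stripped.upper()
        return strip_sequence(str(row["modified_sequence"]), grammar)

    out["stripped_sequence"] = out.apply(_one, axis=1)
    return out


# ---------------------------------------------------------------------------
# PTM annotation table
# ---------------------------------------------------------------------------

def load_ptm_table(path: str | Path) -> pd.DataFrame:
    """Read a user PTM annotation table (TSV or CSV) with columns
    ``ptm_key``, ``display_label``, ``display_color``."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"ptm_key", "display_label", "display_color"} - set(table.columns)
    if missing:
        raise ConfigurationError(f"PTM table {path} missing columns: {sorted(missing)}")
    return table


def _validate_ptm_table(ptm_table: pd.DataFrame) -> None:
    dup = ptm_table["ptm_key"].astype(str)[ptm_table["ptm_key"].astype(str).duplicated()]
    if len(dup):
        raise ConfigurationError(f"duplicate ptm_key values in PTM table: {sorted(set(dup))}")


def _match_ptm_key(label: str, mass: float | None, ptm_table: pd.DataFrame,
                  tolerance: float) -> pd.Series | None:
    for _, row in ptm_table.iterrows():
        key = str(row["ptm_key"])
        if key == label:
            return row
        if mass is not None:
            try:
                key_mass = float(key)
            except ValueError:
                continue
            if abs(key_mass - mass) <= tolerance:
                return row
    return None


# ---------------------------------------------------------------------------
# PTM extraction
# ---------------------------------------------------------------------------

def extract_ptms(records: pd.DataFrame, platform: str | None = None,
                 grammar: ModificationGrammar | None = None,
                 ptm_table: pd.DataFrame | None = None,
                 mass_tolerance: float = 0.01) -> pd.DataFrame:
    """Expand modification annotations into one PTM record per occurrence.

    Rows from standardised formats (mzTab / mzIdentML) carry explicit
    positional modifications in a ``std_mods`` column and bypass grammar
    parsing. Unmodified peptides contribute zero rows. ``multi_ptm`` is true
    for every row of a peptide that contributed more than one PTM row, so
    downstream joins can de-duplicate by ``record_id`` without changing
    peptide match counts.
    """
    if ptm_table is not None:
        _validate_ptm_table(ptm_table)
    if grammar is None and platform is not None and platform not in ("mztab", "mzid"):
        grammar = get_dialect(platform).grammar

    rows: list[dict] = []
    has_std = "std_mods" in records.columns
    for _, rec in records.iterrows():
        std = rec.get("std_mods") if has_std else None
        if isinstance(std, (list, tuple)) and len(std) > 0:
            rows.extend(_rows_from_std(rec, std))
        elif std is None or (isinstance(std, (list, tuple)) and len(std) == 0):
            modified = rec.get("modified_sequence")
            if not isinstance(modified, str) or not modified:
                continue
            if grammar is None:
                raise ConfigurationError(
                    "extract_ptms needs a platform or grammar for grammar-notated rows"
                )
            parsed = parse_modified(modified, grammar)
            for ann in parsed.annotations:
                label, mass = _payload_label(ann.payload, grammar)
                rows.append({
                    "record_id": rec["record_id"],
                    "ptm_label": label,
                    "ptm_position": ann.position,
                    "ptm_mass": mass,
                })

    ptms = pd.DataFrame(rows, columns=["record_id", "ptm_label", "ptm_position", "ptm_mass"])
    counts = ptms.groupby("record_id")["ptm_label"].transform("size")
    ptms["multi_ptm"] = counts > 1
    ptms["display_color"] = None
    ptms = _apply_ptm_table(ptms, ptm_table, mass_tolerance)
    return ptms[PTM_COLUMNS]


def _rows_from_std(rec: pd.Series, std: list) -> list[dict]:
    """Map explicit positional modifications (mzTab/mzIdentML) to PTM rows.

    Position 0 denotes the N-terminus and length+1 the C-terminus, per both
    standards' conventions.
    """
    stripped = rec.get("stripped_sequence") or ""
    out = []
    for mod in std:
        pos, label, mass = mod["position"], mod.get("label"), mod.get("mass")
        if isinstance(pos, int):
            if pos == 0:
                pos = NTERM
            elif stripped and pos == len(stripped) + 1:
                pos = CTERM
            elif pos < 0 or (stripped and pos > len(stripped)):
                raise DataError(
                    f"modification position {pos} outside peptide "
                    f"{stripped!r} (record {rec['record_id']})"
                )
        if label is None:
            label = normalize_mass_label(float(mass))
        out.append({
            "record_id": rec["record_id"],
            "ptm_label": str(label),
            "ptm_position": pos,
            "ptm_mass": float(mass) if mass is not None else None,
        })
    return out


def _payload_label(payload: str, grammar: ModificationGrammar) -> tuple[str, float | None]:
    payload = payload.strip()
    if grammar.payload == "mass":
        try:
            mass = float(payload)
        except ValueError:
            raise NotationError(f"unparsable mass payload {payload!r}") from None
        return normalize_mass_label(mass), mass
    return payload, None


def _apply_ptm_table(ptms: pd.DataFrame, ptm_table: pd.DataFrame | None,
                     tolerance: float) -> pd.DataFrame:
    """Join display labels/colors from the user table; unmatched labels keep
    their raw label and draw colors from a fixed cycling palette."""
    if ptms.empty:
        return ptms
    distinct = sorted(ptms["ptm_label"].unique())
    label_map: dict[str, str] = {}
    color_map: dict[str, str] = {}
    palette = itertools.cycle(DEFAULT_PTM_PALETTE)
    for label in distinct:
        mass = None
        masses = ptms.loc[ptms["ptm_label"] == label, "ptm_mass"].dropna()
        if len(masses):
            mass = float(masses.iloc[0])
        row = None
        if ptm_table is not None:
            row = _match_ptm_key(label, mass, ptm_table, tolerance)
        if row is not None:
            label_map[label] = str(row["display_label"])
            color_map[label] = str(row["display_color"])
        else:
            label_map[label] = label
            color_map[label] = next(palette)
    ptms = ptms.copy()
    ptms["display_color"] = ptms["ptm_label"].map(color_map)
    ptms["ptm_label"] = ptms["ptm_label"].map(label_map)
    return ptms


def parse_mztab_modifications(raw: str | None, stripped: str) -> list[dict]:
    """Parse an mzTab PSM ``modifications`` field like ``3-UNIMOD:21,7-MOD:00412``.

    Returns explicit positional modification dicts; the mzTab ``null`` token
    yields an empty list. Position 0 / length+1 follow the terminal convention
    handled downstream.
    """
    if raw is None or not str(raw).strip() or str(raw).strip().lower() == "null":
        return []
    mods = []
    for part in str(raw).split(","):
        part = part.strip()
        if "-" not in part:
            raise NotationError(f"malformed mzTab modification {part!r}")
        pos_str, accession = part.split("-", 1)
        try:
            pos = int(pos_str)
        except ValueError:
            raise NotationError(f"malformed mzTab modification position in {part!r}") from None
        mods.append({"position": pos, "label": accession, "mass": None})
    return mods
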