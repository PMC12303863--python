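"""Degeneracy-aware peptide-to-target mapping.

Mass spectrometry cannot distinguish isoleucine from leucine, and database
sequences may carry the ambiguity codes B (Asn/Asp), Z (Glu/Gln), and X (any
residue). Mapping therefore decomposes a peptide into one *residue class* per
position and accepts a target window when every target residue is a member of
the corresponding class. The class table::

    N -> {N, B, X}    D -> {D, B, X}
    E -> {E, Z, X}    Q -> {Q, Z, X}
    I -> {I, L, X}    L -> {I, L, X}
    B -> {B, N, D, X} Z -> {Z, E, Q, X}
    X -> all 25       any other residue r -> {r, X}

is symmetric (a matches b iff b matches a), so degenerate codes on either
side — peptide or target — behave identically. The canonical string rendering
of the pattern for ``NDEQIL`` is ``[NBX][DBX][EZX][QZX][ILX][ILX]``.

Coordinates are 1-based inclusive throughout; ``end - start + 1`` equals the
peptide length for every match. All match positions on all joined targets are
reported (overlapping matches included); quantification decides how
multiplicity is counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dialects import RESIDUE_ALPHABET
from .errors import (
    AlphabetError,
    ConfigurationError,
    CrossReferenceError,
    SchemaError,
)

# ---------------------------------------------------------------------------
# residue classes
# ---------------------------------------------------------------------------

_FULL = "".join(sorted(RESIDUE_ALPHABET))


def _build_classes() -> dict[str, frozenset]:
    classes = {r: frozenset({r, "X"}) for r in RESIDUE_ALPHABET}
    classes.update({
        "N": frozenset("NBX"), "D": frozenset("DBX"),
        "E": frozenset("EZX"), "Q": frozenset("QZX"),
        "I": frozenset("ILX"), "L": frozenset("ILX"),
        "B": frozenset("BNDX"), "Z": frozenset("ZEQX"),
        "X": frozenset(RESIDUE_ALPHABET),
    })
    return classes


#: residue -> set of target residues it matches (symmetric)
RESIDUE_CLASSES: dict[str, frozenset] = _build_classes()

#: canonical rendering order of each class; class sets alone do not fix
#: member order, so the conventional strings are spelled out
_RENDER = {
    "N": "NBX", "D": "DBX", "E": "EZX", "Q": "QZX",
    "I": "ILX", "L": "ILX", "B": "BNDX", "Z": "ZEQX",
    "X": _FULL,
}


@dataclass(frozen=True)
class DegeneratePattern:
    """Ordered residue classes for one peptide, with its canonical rendering."""

    peptide: str
    classes: tuple[frozenset, ...]

    def __str__(self) -> str:
        return "".join(
            f"[{_RENDER.get(r, r + 'X')}]" for r in self.peptide
        )

    def to_regex(self) -> re.Pattern:
        """Compile to a regex finding all (overlapping) match starts."""
        body = "".join("[" + "".join(sorted(c)) + "]" for c in self.classes)
        return re.compile(f"(?=({body}))")


def expand_degenerate(peptide: str) -> DegeneratePattern:
    """Convert a stripped peptide into its per-position residue classes.

    ``str()`` of the result renders the conventional bracket notation, e.g.
    ``NDEQIL`` -> ``[NBX][DBX][EZX][QZX][ILX][ILX]``.
    """
    peptide = peptide.upper()
    for i, r in enumerate(peptide):
        if r not in RESIDUE_ALPHABET:
            raise AlphabetError(f"character {r!r} at offset {i} outside the residue alphabet")
    return DegeneratePattern(peptide, tuple(RESIDUE_CLASSES[r] for r in peptide))


def residues_match(a: str, b: str) -> bool:
    """Whether peptide residue ``a`` is compatible with target residue ``b``."""
    return b in RESIDUE_CLASSES[a]


# ---------------------------------------------------------------------------
# targets and regions
# ---------------------------------------------------------------------------

@dataclass
class TargetEntry:
    """A named target protein/chain sequence, possibly with degenerate codes."""

    target_id: str
    sequence: str
    chain: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ConfigurationError(f"target {self.target_id!r} has an empty sequence")
        for i, r in enumerate(self.sequence):
            if r not in RESIDUE_ALPHABET:
                raise AlphabetError(
                    f"target {self.target_id!r}: character {r!r} at offset {i} "
                    "outside the residue alphabet"
                )

    def __len__(self) -> int:
        return len(self.sequence)


REGION_CATEGORIES = ("domain", "cdr", "mutation", "other")

#: region annotation table columns (1-based inclusive coordinates)
REGION_COLUMNS = ["target_id", "label", "start", "end", "category"]


def load_targets(path) -> list[TargetEntry]:
    """Read targets from FASTA or TSV.

    FASTA headers are parsed as ``>target_id key=value ...``; a ``chain=``
    token populates the chain field, all other tokens land in metadata. TSV
    needs columns ``target_id`` and ``sequence``; ``chain`` and any further
    columns become metadata.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return _targets_from_fasta(path)
    return _targets_from_tsv(path)


def _targets_from_fasta(path: Path) -> list[TargetEntry]:
    from Bio import SeqIO

    targets = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = {}
        chain = None
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, value = token.split("=", 1)
                if key == "chain":
                    chain = value
                else:
                    meta[key] = value
        targets.append(TargetEntry(rec.id, str(rec.seq), chain=chain, metadata=meta))
    if not targets:
        raise SchemaError(f"{path}: no FASTA records found")
    return targets


def _targets_from_tsv(path: Path) -> list[TargetEntry]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"target_id", "sequence"} - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: target table missing columns {sorted(missing)}")
    targets = []
    extra = [c for c in table.columns if c not in ("target_id", "sequence", "chain")]
    for _, row in table.iterrows():
        meta = {c: row[c] for c in extra if pd.notna(row[c])}
        chain = row["chain"] if "chain" in table.columns and pd.notna(row["chain"]) else None
        targets.append(TargetEntry(row["target_id"], row["sequence"], chain=chain, metadata=meta))
    return targets


def load_regions(path) -> pd.DataFrame:
    """Read region annotations from TSV with columns
    ``target_id, label, start, end, category`` (1-based inclusive)."""
    table = pd.read_csv(path, sep="\t", dtype={"target_id": str, "label": str, "category": str})
    missing = set(REGION_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: region table missing columns {sorted(missing)}")
    table["start"] = table["start"].astype(int)
    table["end"] = table["end"].astype(int)
    return table[REGION_COLUMNS]


def validate_regions(regions: pd.DataFrame, targets: list[TargetEntry]) -> None:
    lengths = {t.target_id: len(t) for t in targets}
    for _, row in regions.iterrows():
        if row["target_id"] not in lengths:
            raise CrossReferenceError(
                f"region {row['label']!r} references unknown target {row['target_id']!r}"
            )
        if not (1 <= row["start"] <= row["end"] <= lengths[row["target_id"]]):
            raise ConfigurationError(
                f"region {row['label']!r}: interval {row['start']}-{row['end']} "
                f"outside target {row['target_id']!r} (length {lengths[row['target_id']]})"
            )
        if row["category"] not in REGION_CATEGORIES:
            raise ConfigurationError(
                f"region {row['label']!r}: unknown category {row['category']!r}"
            )


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

MATCH_COLUMNS = ["record_id", "target_id", "start", "end", "region_labels"]


@dataclass
class MatchResult:
    """Matches plus a summary of records that matched nowhere."""

    matches: pd.DataFrame
    unmatched: pd.DataFrame  # record_id, stripped_sequence

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched)


def match_peptides(records: pd.DataFrame, targets: list[TargetEntry],
                   join_on: list[str] | None = None) -> MatchResult:
    """Place every stripped peptide on every (joined) target.

    Each position where the degeneracy-expanded pattern matches the target
    window yields one match row (1-based inclusive ``start``/``end``);
    overlapping and multiple matches are all reported. Records with zero
    matches across all their targets appear in the unmatched summary.

    ``join_on`` restricts the peptide x target pairing to rows whose condition
    fields equal the target's metadata on the given keys; by default every
    peptide is matched against every target (cartesian pairing).
    """
    if not targets:
        raise ConfigurationError("match_peptides needs at least one target")
    if join_on:
        for key in join_on:
            if key not in records.columns:
                raise SchemaError(f"join_on key {key!r} missing from the record table")
            for t in targets:
                if key not in t.metadata and not (key == "chain" and t.chain is not None):
                    raise SchemaError(
                        f"join_on key {key!r} missing from target {t.target_id!r} metadata"
                    )

    patterns: dict[str, re.Pattern] = {}
    rows: list[dict] = []
    unmatched: list[dict] = []
    for _, rec in records.iterrows():
        pep = rec["stripped_sequence"]
        if not isinstance(pep, str) or not pep:
            raise SchemaError(f"record {rec['record_id']!r} has no stripped sequence")
        pep = pep.upper()
        if pep not in patterns:
            patterns[pep] = expand_degenerate(pep).to_regex()
        regex = patterns[pep]
        hit = False
        for target in targets:
            if join_on and not _join_ok(rec, target, join_on):
                continue
            for m in regex.finditer(target.sequence):
                start = m.start() + 1
                rows.append({
                    "record_id": rec["record_id"],
                    "target_id": target.target_id,
                    "start": start,
                    "end": start + len(pep) - 1,
                    "region_labels": [],
                })
                hit = True
        if not hit:
            unmatched.append({"record_id": rec["record_id"], "stripped_sequence": pep})

    matches = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    return MatchResult(matches, pd.DataFrame(unmatched, columns=["record_id", "stripped_sequence"]))


def _join_ok(rec: pd.Series, target: TargetEntry, join_on: list[str]) -> bool:
    for key in join_on:
        tval = target.chain if key == "chain" and key not in target.metadata else target.metadata.get(key)
        if str(rec[key]) != str(tval):
            return False
    return True


def annotate_regions(matches: pd.DataFrame, regions: pd.DataFrame,
                     targets: list[TargetEntry]) -> pd.DataFrame:
    """Fill ``region_labels`` with every region overlapping each match.

    Overlap is inclusive intersection of >= 1 residue; labels are ordered by
    region start.
    """
    validate_regions(regions, targets)
    out = matches.copy()
    ordered = regions.sort_values(["target_id", "start"], kind="stable")
    by_target = {tid: grp for tid, grp in ordered.groupby("target_id")}
    labels = []
    for _, m in out.iterrows():
        grp = by_target.get(m["target_id"])
        if grp is None:
            labels.append([])
            continue
        overlap = grp[(grp["start"] <= m["end"]) & (grp["end"] >= m["start"])]
        labels.append(list(overlap["label"]))
    out["region_labels"] = labels
    return out


def write_matches(matches: pd.DataFrame, path) -> None:
    """Write a match table as TSV (region label lists joined with ';')."""
    out = matches.copy()
    if "region_labels" in out.columns:
        out["region_labels"] = out["region_labels"].map(
            lambda v: ";".join(v) if isinstance(v, list) else (v or "")
        )
    out.to_csv(path, sep="\t", index=False)
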