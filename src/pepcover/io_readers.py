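"""Readers for search-engine outputs.

Seven tool dialects (PEAKS, Spectronaut, MSFragger, Comet, DIA-NN, Skyline,
MaxQuant — see :mod:`pepcover.dialects`) plus the standardised mzTab and
mzIdentML formats are normalised into one canonical peptide-record table with
columns::

    record_id, source_file, <condition fields>, modified_sequence,
    stripped_sequence, psm, intensity, area, charge

Multiple files are read simultaneously; each file contributes its
user-assigned condition labels (donor, antibody, timepoint, ...) as extra
columns, enabling comparative analysis downstream. Quantitative fields a
dialect does not define stay absent (NaN) — missing intensity and zero
intensity are different facts, and quantification decides their treatment.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from lxml import etree

from .dialects import STANDARD_FORMATS, SUPPORTED_PLATFORMS, DialectSpec, get_dialect
from .errors import (
    ConfigurationError,
    CrossReferenceError,
    FormatError,
    SchemaError,
    UnsupportedPlatformError,
)
from .sequence import parse_mztab_modifications

logger = logging.getLogger(__name__)

#: canonical columns in their documented output order (condition columns are
#: inserted after source_file, sorted lexicographically)
CANONICAL_ORDER = [
    "record_id", "source_file", "modified_sequence", "stripped_sequence",
    "psm", "intensity", "area", "charge",
]

_QUANT_FIELDS = ("psm", "intensity", "area")


def _sniff_sep(path: Path, default: str) -> str:
    """Choose the field separator by header inspection (tab vs comma)."""
    with open(path) as fh:
        header = fh.readline()
    tabs, commas = header.count("\t"), header.count(",")
    if tabs == 0 and commas == 0:
        return default
    return "\t" if tabs >= commas else ","


def _empty_canonical() -> dict:
    return {
        "modified_sequence": "", "stripped_sequence": "",
        "psm": None, "intensity": None, "area": None, "charge": None,
        "protein_hint": None, "std_mods": None, "std_mods_raw": None,
    }


def _finalize(frames: list[pd.DataFrame]) -> pd.DataFrame:
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    df.insert(0, "record_id", [f"r{i:06d}" for i in range(len(df))])
    for col in _QUANT_FIELDS:
        if col in df.columns:
            bad = df.loc[pd.to_numeric(df[col], errors="coerce") < 0, "record_id"]
            if len(bad):
                raise SchemaError(f"negative {col} value for record(s) {list(bad)[:5]}")
    return df


def _condition_frame(n: int, source: str, conditions: dict | None) -> dict:
    cols = {"source_file": [source] * n}
    for key, value in (conditions or {}).items():
        if key in CANONICAL_ORDER or key in ("protein_hint", "std_mods", "std_mods_raw"):
            raise ConfigurationError(f"condition label {key!r} collides with a canonical column")
        cols[key] = [value] * n
    return cols


def read_results(paths, platform: str, condition_labels=None,
                 dialect_overrides: dict | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read one or more search-result files into the canonical record table.

    Parameters
    ----------
    paths:
        File paths, read in order; row order within each file is preserved.
    platform:
        One of the supported platform identifiers (tool dialects plus
        ``mztab`` / ``mzid``).
    condition_labels:
        One mapping of condition label -> value per path (or a single mapping
        applied to every path, or None for no condition columns).
    dialect_overrides:
        Partial dialect spec patching renamed source columns, e.g.
        ``{"column_map": {"intensity": "MS2 Intensity"}}``.
    sep:
        Explicit field separator, overriding header-based sniffing.
    """
    paths = [Path(p) for p in ([paths] if isinstance(paths, (str, Path)) else paths)]
    if platform not in SUPPORTED_PLATFORMS:
        raise UnsupportedPlatformError(
            f"unsupported platform {platform!r}; supported: {', '.join(SUPPORTED_PLATFORMS)}"
        )
    if condition_labels is None:
        condition_labels = [{} for _ in paths]
    elif isinstance(condition_labels, dict):
        condition_labels = [condition_labels for _ in paths]
    if len(condition_labels) != len(paths):
        raise ConfigurationError(
            f"{len(paths)} path(s) but {len(condition_labels)} condition label set(s)"
        )

    frames = []
    for path, conditions in zip(paths, condition_labels):
        if platform == "mztab":
            frames.append(_read_mztab_file(path, conditions))
        elif platform == "mzid":
            frames.append(_read_mzid_file(path, conditions))
        else:
            spec = get_dialect(platform, dialect_overrides)
            frames.append(_read_dialect_file(path, spec, conditions, sep))
    df = _finalize(frames)
    logger.info("read %d records from %d file(s) [%s]", len(df), len(paths), platform)
    return df


def _read_dialect_file(path: Path, spec: DialectSpec, conditions: dict | None,
                       sep: str | None) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"cannot read {path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"cannot read {path}: file is empty")
    use_sep = sep or _sniff_sep(path, spec.sep)
    try:
        raw = pd.read_csv(path, sep=use_sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error classes vary
        raise FormatError(f"cannot read {path}: {exc}") from exc

    cmap = spec.column_map
    seq_cols = {f: cmap[f] for f in ("modified_sequence", "stripped_sequence") if f in cmap}
    present = {f: c for f, c in seq_cols.items() if c in raw.columns}
    if not present:
        raise SchemaError(
            f"{path}: missing mandatory sequence column(s) "
            f"{sorted(seq_cols.values())} for platform {spec.platform_id!r}"
        )

    out = pd.DataFrame(index=raw.index)
    base = _empty_canonical()
    for field in ("modified_sequence", "stripped_sequence"):
        col = cmap.get(field)
        out[field] = raw[col].fillna("") if col in raw.columns else base[field]
    for field in ("psm", "intensity", "area", "charge"):
        col = cmap.get(field)
        if col is not None and col in raw.columns:
            out[field] = pd.to_numeric(raw[col].replace("", None), errors="coerce")
        else:
            out[field] = float("nan")
    hint_col = cmap.get("protein_hint")
    out["protein_hint"] = raw[hint_col] if hint_col in raw.columns else None
    out["std_mods"] = None
    out["std_mods_raw"] = None
    empty_seq = (out["modified_sequence"] == "") & (out["stripped_sequence"] == "")
    if empty_seq.any():
        raise SchemaError(f"{path}: {int(empty_seq.sum())} row(s) with no peptide sequence")
    for key, values in _condition_frame(len(out), str(path), conditions).items():
        out[key] = values
    return out


# ---------------------------------------------------------------------------
# mzTab
# ---------------------------------------------------------------------------

def read_mztab(path, condition_labels: dict | None = None) -> pd.DataFrame:
    """Read the PSM section of an mzTab file into the canonical table.

    mzTab modification strings (position–accession pairs like
    ``3-UNIMOD:21``) are retained verbatim in ``std_mods_raw`` and parsed into
    explicit positional modifications in ``std_mods``.
    """
    return _finalize([_read_mztab_file(Path(path), condition_labels)])


def _read_mztab_file(path: Path, conditions: dict | None) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"cannot read {path}: no such file")
    section = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            prefix = line.split("\t", 1)[0].strip()
            if prefix in ("PSH", "PEH"):
                section = prefix
                break
            if prefix not in ("MTD", "COM", "", "PRH", "PRT"):
                raise SchemaError(f"{path}:{lineno}: malformed mzTab section prefix {prefix!r}")
    if section is None:
        raise SchemaError(f"{path}: no PSM/PEP section header (PSH/PEH) found")

    from pyteomics import mztab

    try:
        tab = mztab.MzTab(str(path))
    except Exception as exc:
        raise SchemaError(f"{path}: mzTab parse failure: {exc}") from exc
    table = tab.spectrum_match_table
    if table is None or len(table) == 0:
        table = tab.peptide_table
    if table is None or len(table) == 0:
        raise SchemaError(f"{path}: PSM/PEP section contains no rows")

    out = pd.DataFrame(index=range(len(table)))
    seqs = table["sequence"].astype(str).tolist()
    out["modified_sequence"] = ""
    out["stripped_sequence"] = [s.upper() for s in seqs]
    out["psm"] = float("nan")
    out["intensity"] = float("nan")
    out["area"] = float("nan")
    charge = table["charge"] if "charge" in table.columns else None
    out["charge"] = pd.to_numeric(charge, errors="coerce").tolist() if charge is not None else float("nan")
    out["protein_hint"] = table["accession"].tolist() if "accession" in table.columns else None
    raw_mods = table["modifications"].tolist() if "modifications" in table.columns else [None] * len(table)
    out["std_mods_raw"] = [None if m is None else str(m) for m in raw_mods]
    out["std_mods"] = [parse_mztab_modifications(m, s) for m, s in zip(raw_mods, seqs)]
    for key, values in _condition_frame(len(out), str(path), conditions).items():
        out[key] = values
    return out


# ---------------------------------------------------------------------------
# mzIdentML
# ---------------------------------------------------------------------------

def read_mzid(path, condition_labels: dict | None = None) -> pd.DataFrame:
    """Read an mzIdentML 1.1/1.2 file into the canonical table.

    Parsing is streaming and element-wise (``lxml.etree.iterparse`` with
    element clearing): peak memory stays bounded by the largest single element,
    independent of the identification count. One record is emitted per
    ``SpectrumIdentificationItem``; its ``Modification`` elements (location,
    monoisotopic mass delta, name) are retained in ``std_mods``.
    """
    return _finalize([_read_mzid_file(Path(path), condition_labels)])


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_mzid_file(path: Path, conditions: dict | None) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"cannot read {path}: no such file")
    peptides: dict[str, tuple[str, list[dict]]] = {}
    rows: list[dict] = []
    try:
        context = etree.iterparse(str(path), events=("end",))
        for _, elem in context:
            tag = _local(elem.tag)
            if tag == "Peptide":
                peptides[elem.get("id")] = _parse_peptide(elem)
                elem.clear()
            elif tag == "SpectrumIdentificationItem":
                ref = elem.get("peptide_ref")
                if ref not in peptides:
                    raise CrossReferenceError(
                        f"{path}: SpectrumIdentificationItem {elem.get('id')!r} "
                        f"references unresolvable peptide {ref!r}"
                    )
                seq, mods = peptides[ref]
                charge = elem.get("chargeState")
                rows.append({
                    **_empty_canonical(),
                    "stripped_sequence": seq,
                    "charge": float(charge) if charge is not None else float("nan"),
                    "std_mods": mods,
                })
                elem.clear()
            elif tag == "SpectrumIdentificationResult":
                elem.clear()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: XML parse failure: {exc}") from exc
    if not peptides:
        raise CrossReferenceError(f"{path}: SequenceCollection defines no Peptide elements")

    out = pd.DataFrame(rows, columns=list(_empty_canonical()))
    for key, values in _condition_frame(len(out), str(path), conditions).items():
        out[key] = values
    return out


def _parse_peptide(elem) -> tuple[str, list[dict]]:
    seq = ""
    mods: list[dict] = []
    for child in elem:
        tag = _local(child.tag)
        if tag == "PeptideSequence":
            seq = (child.text or "").strip().upper()
        elif tag == "Modification":
            name = None
            for cv in child:
                if _local(cv.tag) == "cvParam" and cv.get("name"):
                    name = cv.get("name")
                    break
            delta = child.get("monoisotopicMassDelta")
            mods.append({
                "position": int(child.get("location")) if child.get("location") else None,
                "label": name,
                "mass": float(delta) if delta is not None else None,
            })
    return seq, mods


# ---------------------------------------------------------------------------
# canonical table output
# ---------------------------------------------------------------------------

def condition_columns(records: pd.DataFrame) -> list[str]:
    """Condition-label columns of a canonical table, sorted lexicographically."""
    internal = set(CANONICAL_ORDER) | {"protein_hint", "std_mods", "std_mods_raw"}
    return sorted(c for c in records.columns if c not in internal)


def write_records(records: pd.DataFrame, path) -> None:
    """Write a canonical record table as TSV in the documented column order."""
    cond = condition_columns(records)
    order = ["record_id", "source_file"] + cond + [
        "modified_sequence", "stripped_sequence", "psm", "intensity", "area", "charge",
    ]
    out = records.reindex(columns=order)
    out.to_csv(path, sep="\t", index=False)
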