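"""Per-residue roll-up of matched peptides.

Three metrics color the coverage heatmap:

* ``psm`` — each residue position accumulates the PSM count of every match
  occurrence spanning it (weight 1 when a source defines no PSM column). With
  ``distinct_peptides=True`` the value is instead the number of distinct
  stripped sequences covering the position.
* ``intensity`` / ``area`` — within each group, records are first reduced to
  unique stripped sequences (duplicate occurrences of the same sequence are
  aggregated by sum); the aggregated quantity is then added at every residue
  covered by the union of the sequence's match windows, so no position ever
  exceeds the group's total aggregated quantity.

Positions covered by no peptide are absent from the output (rendered blank /
zero downstream). A peptide matching several sites contributes at every site.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CrossReferenceError, DataError
from .mapping import TargetEntry

logger = logging.getLogger(__name__)

METRICS = ("psm", "intensity", "area")

#: long-format output columns (group columns are inserted after target_id)
QUANT_COLUMNS = ["target_id", "position", "metric", "value"]


def quantify_positions(matches: pd.DataFrame, records: pd.DataFrame,
                       metric: str = "psm", group_by: list[str] | None = None,
                       distinct_peptides: bool = False) -> pd.DataFrame:
    """Roll matched peptides up to per-residue metric values per group.

    Parameters
    ----------
    matches:
        Match table (``record_id, target_id, start, end``) from
        :func:`pepcover.mapping.match_peptides`.
    records:
        Canonical peptide-record table the matches refer to.
    metric:
        ``psm``, ``intensity``, or ``area``.
    group_by:
        Condition fields forming the grouping key (e.g. donor); empty for a
        single all-records group.
    distinct_peptides:
        In psm mode, count distinct stripped sequences per position instead of
        summing PSM-weighted occurrences.

    Returns a long-format table with columns
    ``target_id, <group_by...>, position, metric, value`` and at most one row
    per (target, group, position).
    """
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    group_by = list(group_by or [])
    for key in group_by:
        if key not in records.columns:
            raise ConfigurationError(f"group_by field {key!r} missing from the record table")

    need = ["record_id", "stripped_sequence"] + group_by
    if metric in ("intensity", "area"):
        if metric not in records.columns or records[metric].notna().sum() == 0:
            raise ConfigurationError(
                f"metric {metric!r} requested but no record carries a {metric} value"
            )
        need.append(metric)
    elif "psm" in records.columns:
        need.append("psm")

    joined = matches.merge(records[need], on="record_id", how="left", validate="m:1")
    for col in ("psm", "intensity", "area"):
        if col in joined.columns:
            bad = joined.loc[joined[col] < 0, "record_id"]
            if len(bad):
                raise DataError(f"negative {col} value on record {bad.iloc[0]!r}")

    rows: list[dict] = []
    n_missing = 0
    group_cols = group_by if group_by else []
    grouper = joined.groupby(["target_id"] + group_cols, dropna=False, sort=True) \
        if group_cols else joined.groupby(["target_id"], sort=True)
    for key, grp in grouper:
        key = key if isinstance(key, tuple) else (key,)
        target_id, group_vals = key[0], key[1:]
        if metric == "psm":
            values = _accumulate_psm(grp, distinct_peptides)
        else:
            values, miss = _accumulate_quantity(grp, metric)
            n_missing += miss
        for pos in sorted(values):
            row = {"target_id": target_id, "position": pos, "metric": metric,
                   "value": values[pos]}
            row.update(dict(zip(group_cols, group_vals)))
            rows.append(row)
    if n_missing:
        logger.warning("%d record(s) missing %s treated as 0", n_missing, metric)

    cols = ["target_id"] + group_cols + ["position", "metric", "value"]
    return pd.DataFrame(rows, columns=cols)


def _accumulate_psm(grp: pd.DataFrame, distinct: bool) -> dict[int, float]:
    values: dict[int, float] = {}
    if distinct:
        seen: dict[int, set] = {}
        for _, m in grp.iterrows():
            for pos in range(int(m["start"]), int(m["end"]) + 1):
                seen.setdefault(pos, set()).add(m["stripped_sequence"])
        return {pos: float(len(s)) for pos, s in seen.items()}
    for _, m in grp.iterrows():
        weight = m.get("psm")
        weight = 1.0 if weight is None or (isinstance(weight, float) and np.isnan(weight)) \
            else float(weight)
        for pos in range(int(m["start"]), int(m["end"]) + 1):
            values[pos] = values.get(pos, 0.0) + weight
    return values


def _accumulate_quantity(grp: pd.DataFrame, metric: str) -> tuple[dict[int, float], int]:
    # records first: one quantity per record, regardless of its match multiplicity
    per_record = grp.drop_duplicates("record_id")[["record_id", "stripped_sequence", metric]]
    n_missing = int(per_record[metric].isna().sum())
    seq_qty = per_record.groupby("stripped_sequence")[metric].sum(min_count=0)
    # each unique sequence contributes its aggregated quantity once per covered
    # position (union over its match windows), so no position exceeds the
    # group's total aggregated quantity
    windows = grp[["stripped_sequence", "start", "end"]].drop_duplicates()
    values: dict[int, float] = {}
    for seq, seq_windows in windows.groupby("stripped_sequence"):
        qty = float(seq_qty.get(seq, 0.0))
        if np.isnan(qty):
            qty = 0.0
        covered: set[int] = set()
        for _, w in seq_windows.iterrows():
            covered.update(range(int(w["start"]), int(w["end"]) + 1))
        for pos in covered:
            values[pos] = values.get(pos, 0.0) + qty
    return values, n_missing


def group_columns(quant: pd.DataFrame) -> list[str]:
    """The grouping-key columns of a quantification table."""
    return [c for c in quant.columns if c not in QUANT_COLUMNS]


def coverage_summary(quant: pd.DataFrame, targets: list[TargetEntry],
                     expected_groups: list[tuple] | None = None) -> pd.DataFrame:
    """Per (target, group) coverage: covered residue count, covered fraction
    of the target, and maximum metric value.

    ``expected_groups`` optionally lists (target_id, group values...) tuples
    that must appear in the summary even when entirely uncovered (emitted with
    covered=0, fraction=0).
    """
    lengths = {t.target_id: len(t) for t in targets}
    unknown = set(quant["target_id"]) - set(lengths)
    if unknown:
        raise CrossReferenceError(f"quantification references unknown target(s) {sorted(unknown)}")
    gcols = group_columns(quant)
    rows = []
    seen = set()
    if len(quant):
        for key, grp in quant.groupby(["target_id"] + gcols, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            seen.add(key)
            row = {"target_id": key[0], **dict(zip(gcols, key[1:]))}
            row["covered"] = int(grp["position"].nunique())
            row["fraction"] = row["covered"] / lengths[key[0]]
            row["max_value"] = float(grp["value"].max())
            rows.append(row)
    for key in expected_groups or []:
        key = tuple(key)
        if key in seen:
            continue
        if key[0] not in lengths:
            raise CrossReferenceError(f"expected group references unknown target {key[0]!r}")
        rows.append({"target_id": key[0], **dict(zip(gcols, key[1:])),
                     "covered": 0, "fraction": 0.0, "max_value": 0.0})
    return pd.DataFrame(rows, columns=["target_id"] + gcols + ["covered", "fraction", "max_value"])


def write_quant(quant: pd.DataFrame, path) -> None:
    """Write a long-format quantification table as TSV."""
    quant.to_csv(path, sep="\t", index=False)
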