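"""Synthetic ground-truthed fixtures.

Every supported input format can be generated here with a known answer key:
a random target sequence (optionally salted with degenerate B/Z/X codes),
peptides planted as true substrings at recorded positions, grammar-valid
modification annotations, and per-PSM quantitative values. The serializers
share the :class:`~pepcover.dialects.DialectSpec` registry with the readers,
so a schema change breaks both sides loudly, and a single integer seed fully
determines every emitted byte.

Serialization convention: one output row per PSM occurrence in *every*
dialect — which is what Comet, MSFragger, mzTab and mzIdentML genuinely emit —
so the same ground truth yields the same record set in all nine formats
(PSM-count columns, where a dialect has one, are 1 per row). Intensities and
areas are drawn log-uniformly per occurrence; no attempt is made to simulate
spectra, retention times, or realistic abundance distributions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dialects import BUILTIN_DIALECTS, SUPPORTED_PLATFORMS, DialectSpec
from .errors import ConfigurationError, UnsupportedPlatformError
from .mapping import REGION_COLUMNS, TargetEntry

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: (name, monoisotopic mass delta, UniMod accession) of the planted PTMs
MOD_CATALOG = (
    ("Phospho", 79.9663, "UNIMOD:21"),
    ("Oxidation", 15.9949, "UNIMOD:35"),
    ("Carbamidomethyl", 57.0215, "UNIMOD:4"),
)

_EXTENSIONS = {
    "peaks": ".csv", "skyline": ".csv", "comet": ".txt", "maxquant": ".txt",
    "spectronaut": ".tsv", "msfragger": ".tsv", "diann": ".tsv",
    "mztab": ".mztab", "mzid": ".mzid",
}


@dataclass(frozen=True)
class PlantedMod:
    position: int  # 1-based within the peptide
    name: str
    mass: float
    unimod: str


@dataclass(frozen=True)
class PlantedPeptide:
    """One PSM occurrence of a planted peptide."""

    sequence: str
    start: int  # 1-based position on the target
    mods: tuple[PlantedMod, ...]
    intensity: float
    area: float
    charge: int
    conditions: dict


@dataclass
class GroundTruth:
    """Answer key accompanying a generated fixture file."""

    peptides: list[PlantedPeptide]
    target: TargetEntry
    regions: pd.DataFrame
    seed: int

    @property
    def planted_pairs(self) -> set[tuple[str, int]]:
        """Distinct (sequence, start) pairs that must reappear as matches."""
        return {(p.sequence, p.start) for p in self.peptides}

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "target": {
                "target_id": self.target.target_id,
                "chain": self.target.chain,
                "sequence": self.target.sequence,
                "metadata": self.target.metadata,
            },
            "regions": self.regions.to_dict(orient="records"),
            "peptides": [asdict(p) for p in self.peptides],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_target(length: int, n_regions: int, degenerate_fraction: float,
                    seed: int, target_id: str = "TGT1",
                    chain: str | None = None) -> tuple[TargetEntry, pd.DataFrame]:
    """Uniform random target sequence with non-overlapping labeled regions.

    ``degenerate_fraction`` of the positions are replaced by B/Z/X. Regions
    are packed one per equal-width block, alternating domain and CDR
    categories. Deterministic given the seed.
    """
    if length < 10:
        raise ConfigurationError("target length must be >= 10")
    if not (0 <= n_regions <= length // 5):
        raise ConfigurationError(
            f"cannot pack {n_regions} regions into a length-{length} target"
        )
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(_STANDARD_AA), size=length))
    n_deg = int(round(degenerate_fraction * length))
    if n_deg:
        for pos in rng.choice(length, size=n_deg, replace=False):
            seq[pos] = str(rng.choice(list("BZX")))
    target = TargetEntry(target_id, "".join(seq), chain=chain)

    rows = []
    if n_regions:
        block = length // n_regions
        for i in range(n_regions):
            lo, hi = i * block + 1, (i + 1) * block
            start = int(rng.integers(lo, hi - 2))
            end = int(rng.integers(start + 1, hi))
            category = "domain" if i % 2 == 0 else "cdr"
            label = f"{'DOM' if category == 'domain' else 'CDR'}{i + 1}"
            rows.append({"target_id": target_id, "label": label,
                         "start": start, "end": end, "category": category})
    regions = pd.DataFrame(rows, columns=REGION_COLUMNS)
    return target, regions


def generate_fixture(platform: str, n_peptides: int, mod_rate: float = 0.3,
                     seed: int = 0, outdir=".", target_length: int = 90,
                     n_regions: int = 2, degenerate_fraction: float = 0.0,
                     conditions: dict | None = None,
                     max_multiplicity: int = 3) -> tuple[Path, GroundTruth]:
    """Write one search-result file in the platform's dialect plus a ground
    truth answer key (also serialized as a JSON sidecar).

    Peptides (length 7–14) are sampled as true substrings of the generated
    target; at rate ``mod_rate`` a peptide carries 1–2 grammar-valid
    modifications from :data:`MOD_CATALOG`; each peptide is observed as 1 to
    ``max_multiplicity`` PSM occurrences with independent intensity/area
    draws.
    """
    if platform not in SUPPORTED_PLATFORMS:
        raise UnsupportedPlatformError(
            f"unsupported platform {platform!r}; supported: {', '.join(SUPPORTED_PLATFORMS)}"
        )
    if n_peptides < 1:
        raise ConfigurationError("n_peptides must be >= 1")
    conditions = dict(conditions or {"donor": "D1"})
    target, regions = generate_target(target_length, n_regions,
                                      degenerate_fraction, seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))

    peptides: list[PlantedPeptide] = []
    for _ in range(n_peptides):
        length = int(rng.integers(7, 15))
        start = int(rng.integers(1, target_length - length + 2))
        seq = target.sequence[start - 1 : start - 1 + length]
        mods: tuple[PlantedMod, ...] = ()
        if rng.random() < mod_rate:
            k = 2 if rng.random() < 0.35 else 1
            positions = sorted(int(p) + 1 for p in rng.choice(length, size=k, replace=False))
            mods = tuple(
                PlantedMod(pos, *MOD_CATALOG[int(rng.integers(len(MOD_CATALOG)))])
                for pos in positions
            )
        for _ in range(int(rng.integers(1, max_multiplicity + 1))):
            peptides.append(PlantedPeptide(
                sequence=seq, start=start, mods=mods,
                intensity=round(float(10 ** rng.uniform(5, 8)), 1),
                area=round(float(10 ** rng.uniform(5, 8)), 1),
                charge=int(rng.integers(2, 5)),
                conditions=conditions,
            ))

    truth = GroundTruth(peptides, target, regions, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{platform}_results{_EXTENSIONS[platform]}"
    _SERIALIZERS[platform](path, truth, np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(2,))))
    truth.to_json(outdir / f"{platform}_groundtruth.json")
    return path, truth


def write_project(platform: str, outdir, n_peptides: int = 8,
                  mod_rate: float = 0.3, seed: int = 0, **kwargs) -> dict:
    """Generate a complete analysis project: results file, target FASTA,
    region TSV, and the ground-truth JSON. Returns the paths."""
    outdir = Path(outdir)
    path, truth = generate_fixture(platform, n_peptides, mod_rate, seed,
                                   outdir=outdir, **kwargs)
    fasta = outdir / "targets.fasta"
    header = f">{truth.target.target_id}"
    if truth.target.chain:
        header += f" chain={truth.target.chain}"
    fasta.write_text(f"{header}\n{truth.target.sequence}\n")
    regions_path = outdir / "regions.tsv"
    truth.regions.to_csv(regions_path, sep="\t", index=False)
    return {"results": path, "targets": fasta, "regions": regions_path,
            "groundtruth": outdir / f"{platform}_groundtruth.json", "truth": truth}


# ---------------------------------------------------------------------------
# dialect serializers
# ---------------------------------------------------------------------------

def render_modified(pep: PlantedPeptide, spec: DialectSpec, rng) -> str:
    """Render a planted peptide in a dialect's modification notation."""
    g = spec.grammar
    chars = list(pep.sequence)
    for mod in sorted(pep.mods, key=lambda m: -m.position):
        if g.payload == "mass":
            payload = f"{mod.mass:.4f}" if spec.platform_id == "comet" else f"{mod.mass:+.4f}"
        elif g.payload == "unimod":
            payload = f"UniMod:{mod.unimod.split(':')[1]}"
        else:
            payload = f"{mod.name} ({pep.sequence[mod.position - 1]})"
        chars.insert(mod.position, f"{g.opener}{payload}{g.closer}")
    body = "".join(chars)
    if g.terminal == "underscore":
        body = f"_{body}_"
    if g.flanking:
        flank = "".join(rng.choice(list(_STANDARD_AA), size=2))
        body = f"{flank[0]}.{body}.{flank[1]}"
    return body


def _serialize_dialect(path: Path, truth: GroundTruth, rng) -> None:
    platform = path.name.split("_results")[0]
    spec = BUILTIN_DIALECTS[platform]
    cmap = spec.column_map
    rows = []
    for pep in truth.peptides:
        row = {}
        if "modified_sequence" in cmap:
            row[cmap["modified_sequence"]] = render_modified(pep, spec, rng)
        if "stripped_sequence" in cmap:
            row[cmap["stripped_sequence"]] = pep.sequence
        if "psm" in cmap:
            row[cmap["psm"]] = 1
        if "intensity" in cmap:
            row[cmap["intensity"]] = pep.intensity
        if "area" in cmap:
            row[cmap["area"]] = pep.area
        if "charge" in cmap:
            row[cmap["charge"]] = pep.charge
        if "protein_hint" in cmap:
            row[cmap["protein_hint"]] = truth.target.target_id
        rows.append(row)
    table = pd.DataFrame(rows)
    if platform == "comet":  # optional score columns the reader must tolerate losing
        table["e-value"] = [round(float(10 ** rng.uniform(-6, -1)), 8) for _ in rows]
        table["xcorr"] = [round(float(rng.uniform(1, 6)), 4) for _ in rows]
    table.to_csv(path, sep=spec.sep, index=False)


def _serialize_mztab(path: Path, truth: GroundTruth, rng) -> None:
    lines = [
        "MTD\tmzTab-version\t1.0.0",
        "MTD\tmzTab-mode\tSummary",
        "MTD\tmzTab-type\tIdentification",
        "MTD\tdescription\tsynthetic fixture",
        "MTD\tms_run[1]-location\tfile://run1.mzML",
        "MTD\tpsm_search_engine_score[1]\t[MS, MS:1001171, score, ]",
    ]
    header = ["PSH", "sequence", "PSM_ID", "accession", "unique", "database",
              "database_version", "search_engine", "search_engine_score[1]",
              "modifications", "retention_time", "charge", "exp_mass_to_charge",
              "calc_mass_to_charge", "spectra_ref", "pre", "post", "start", "end"]
    lines.append("\t".join(header))
    for i, pep in enumerate(truth.peptides, start=1):
        mods = ",".join(f"{m.position}-{m.unimod}" for m in pep.mods) or "null"
        rt = round(float(rng.uniform(10, 90)), 2)
        lines.append("\t".join(map(str, [
            "PSM", pep.sequence, i, truth.target.target_id, 1, "null", "null",
            "[MS, MS:1002251, engine, ]", round(float(rng.uniform(5, 50)), 2),
            mods, rt, pep.charge, 500.0, 500.0, f"ms_run[1]:scan={i}", "K", "R",
            pep.start, pep.start + len(pep.sequence) - 1,
        ])))
    path.write_text("\n".join(lines) + "\n")


def _serialize_mzid(path: Path, truth: GroundTruth, rng) -> None:
    unique: dict[tuple, str] = {}
    pep_xml = []
    for pep in truth.peptides:
        key = (pep.sequence, pep.mods)
        if key in unique:
            continue
        pid = f"Pep_{len(unique) + 1}"
        unique[key] = pid
        mods = "".join(
            f'\n      <Modification location="{m.position}" '
            f'monoisotopicMassDelta="{m.mass}">'
            f'\n        <cvParam cvRef="UNIMOD" accession="{m.unimod}" name="{m.name}"/>'
            f"\n      </Modification>"
            for m in pep.mods
        )
        pep_xml.append(
            f'    <Peptide id="{pid}">\n'
            f"      <PeptideSequence>{pep.sequence}</PeptideSequence>{mods}\n"
            f"    </Peptide>"
        )
    results = []
    for i, pep in enumerate(truth.peptides, start=1):
        pid = unique[(pep.sequence, pep.mods)]
        results.append(
            f'        <SpectrumIdentificationResult id="SIR_{i}" spectrumID="scan={i}" '
            f'spectraData_ref="SD_1">\n'
            f'          <SpectrumIdentificationItem id="SII_{i}" rank="1" '
            f'chargeState="{pep.charge}" peptide_ref="{pid}" '
            f'experimentalMassToCharge="500.0" calculatedMassToCharge="500.0" '
            f'passThreshold="true"/>\n'
            f"        </SpectrumIdentificationResult>"
        )
    xml = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<MzIdentML id="fixture" version="1.1.0" '
        'xmlns="http://psidev.info/psi/pi/mzIdentML/1.1" '
        'creationDate="2000-01-01T00:00:00">\n'
        "  <SequenceCollection>\n"
        f'    <DBSequence id="DBSeq_1" accession="{truth.target.target_id}" '
        'searchDatabase_ref="SDB_1"/>\n'
        + "\n".join(pep_xml) + "\n"
        "  </SequenceCollection>\n"
        "  <AnalysisCollection>\n"
        '    <SpectrumIdentification id="SI_1" spectrumIdentificationProtocol_ref="SIP_1" '
        'spectrumIdentificationList_ref="SIL_1"/>\n'
        "  </AnalysisCollection>\n"
        "  <DataCollection>\n"
        "    <Inputs>\n"
        '      <SearchDatabase id="SDB_1" location="db.fasta"/>\n'
        '      <SpectraData id="SD_1" location="run1.mzML"/>\n'
        "    </Inputs>\n"
        "    <AnalysisData>\n"
        '      <SpectrumIdentificationList id="SIL_1">\n'
        + "\n".join(results) + "\n"
        "      </SpectrumIdentificationList>\n"
        "    </AnalysisData>\n"
        "  </DataCollection>\n"
        "</MzIdentML>\n"
    )
    path.write_text(xml)


_SERIALIZERS = {p: _serialize_dialect for p in BUILTIN_DIALECTS}
_SERIALIZERS["mztab"] = _serialize_mztab
_SERIALIZERS["mzid"] = _serialize_mzid
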