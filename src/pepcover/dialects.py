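"""Search-engine dialect registry.

Each supported platform is described by a :class:`DialectSpec`: a mapping from
canonical PeptideRecord fields to the tool's column names, plus a
:class:`ModificationGrammar` describing how that tool annotates modifications
inside peptide strings. Dialects are *data*, not code branches — readers and
the fixture serializers both consume the same spec, and ``dialect_overrides``
lets users patch column names when a tool release renames them.

Column names encode each tool's currently documented export schema:

* PEAKS ``proteins.csv``-style peptide exports (``Peptide``, ``#Spec``, ...)
* Spectronaut report TSV (``EG.ModifiedSequence``, ``FG.MS2Quantity``, ...)
* MSFragger/FragPipe ``psm.tsv``
* Comet ``.txt`` tabular output
* DIA-NN ``report.tsv``
* Skyline peptide-level CSV export
* MaxQuant ``evidence.txt``

Tool schemas drift between versions; overriding a column is a one-line call,
not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import UnsupportedPlatformError

#: canonical PeptideRecord fields a dialect may map
CANONICAL_FIELDS = (
    "modified_sequence",
    "stripped_sequence",
    "psm",
    "intensity",
    "area",
    "charge",
    "protein_hint",
)

#: residue alphabet: the 20 standard amino acids plus degenerate/rare codes
RESIDUE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "BZXUO")


@dataclass(frozen=True)
class ModificationGrammar:
    """How a dialect annotates modifications inside a peptide string.

    Parameters
    ----------
    opener, closer:
        The delimiter pair enclosing a modification payload, e.g. ``(`` / ``)``
        for PEAKS ``(+79.97)`` or ``[`` / ``]`` for Comet ``[79.9663]``.
    payload:
        What the payload denotes: ``"mass"`` (a signed or unsigned mass delta),
        ``"name"`` (a modification name, possibly with nested delimiters as in
        MaxQuant ``(Phospho (S))``), or ``"unimod"`` (a UniMod accession like
        ``UniMod:21``).
    flanking:
        Whether peptides may carry flanking residues (``K.PEPTIDE.R``).
    terminal:
        Terminal-marker convention: ``"underscore"`` (MaxQuant/Spectronaut
        ``_PEPTIDE_``), ``"nc"`` (MSFragger ``n[42]PEPTIDEc[17]``), or ``None``.
    nested:
        Whether payloads may contain nested copies of the delimiters
        (MaxQuant modification names do).
    """

    opener: str = "("
    closer: str = ")"
    payload: str = "mass"  # mass | name | unimod
    flanking: bool = False
    terminal: str | None = None  # underscore | nc | None
    nested: bool = False

    def __post_init__(self) -> None:
        if self.opener == self.closer:
            raise ValueError("modification delimiters must differ")
        if len(self.opener) != 1 or len(self.closer) != 1:
            raise ValueError("modification delimiters must be single characters")


@dataclass(frozen=True)
class DialectSpec:
    """Column map plus modification grammar for one platform."""

    platform_id: str
    column_map: dict[str, str] = field(default_factory=dict)
    grammar: ModificationGrammar = field(default_factory=ModificationGrammar)
    #: default field separator of the tool's native export; header sniffing
    #: overrides this when unambiguous
    sep: str = "\t"

    def __post_init__(self) -> None:
        unknown = set(self.column_map) - set(CANONICAL_FIELDS)
        if unknown:
            raise ValueError(f"unknown canonical fields in column map: {sorted(unknown)}")
        if not ({"modified_sequence", "stripped_sequence"} & set(self.column_map)):
            raise ValueError(
                f"dialect {self.platform_id!r} names no sequence column"
            )

    def override(self, partial: dict | None) -> "DialectSpec":
        """Return a copy with ``column_map`` entries (and optionally ``sep``)
        patched from a partial user-supplied mapping."""
        if not partial:
            return self
        cmap = dict(self.column_map)
        cmap.update(partial.get("column_map", {}))
        kwargs: dict = {"column_map": cmap}
        if "sep" in partial:
            kwargs["sep"] = partial["sep"]
        if "grammar" in partial:
            kwargs["grammar"] = partial["grammar"]
        return replace(self, **kwargs)


BUILTIN_DIALECTS: dict[str, DialectSpec] = {
    "peaks": DialectSpec(
        platform_id="peaks",
        column_map={
            "modified_sequence": "Peptide",
            "psm": "#Spec",
            "intensity": "Intensity",
            "area": "Area",
            "charge": "z",
            "protein_hint": "Accession",
        },
        grammar=ModificationGrammar("(", ")", "mass", flanking=True),
        sep=",",
    ),
    "spectronaut": DialectSpec(
        platform_id="spectronaut",
        column_map={
            "modified_sequence": "EG.ModifiedSequence",
            "stripped_sequence": "PEP.StrippedSequence",
            "intensity": "FG.MS2Quantity",
            "charge": "FG.Charge",
            "protein_hint": "PG.ProteinAccessions",
        },
        grammar=ModificationGrammar("[", "]", "name", terminal="underscore"),
    ),
    "msfragger": DialectSpec(
        platform_id="msfragger",
        column_map={
            "modified_sequence": "Modified Peptide",
            "stripped_sequence": "Peptide",
            "intensity": "Intensity",
            "charge": "Charge",
            "protein_hint": "Protein",
        },
        grammar=ModificationGrammar("[", "]", "mass", terminal="nc"),
    ),
    "comet": DialectSpec(
        platform_id="comet",
        column_map={
            "modified_sequence": "modified_peptide",
            "stripped_sequence": "plain_peptide",
            "charge": "charge",
            "protein_hint": "protein",
        },
        grammar=ModificationGrammar("[", "]", "mass", flanking=True),
    ),
    "diann": DialectSpec(
        platform_id="diann",
        column_map={
            "modified_sequence": "Modified.Sequence",
            "stripped_sequence": "Stripped.Sequence",
            "intensity": "Precursor.Quantity",
            "charge": "Precursor.Charge",
            "protein_hint": "Protein.Group",
        },
        grammar=ModificationGrammar("(", ")", "unimod"),
    ),
    "skyline": DialectSpec(
        platform_id="skyline",
        column_map={
            "modified_sequence": "Peptide Modified Sequence",
            "stripped_sequence": "Peptide Sequence",
            "area": "Total Area",
            "protein_hint": "Protein Name",
        },
        grammar=ModificationGrammar("[", "]", "mass"),
        sep=",",
    ),
    "maxquant": DialectSpec(
        platform_id="maxquant",
        column_map={
            "modified_sequence": "Modified sequence",
            "stripped_sequence": "Sequence",
            "psm": "MS/MS count",
            "intensity": "Intensity",
            "charge": "Charge",
            "protein_hint": "Proteins",
        },
        grammar=ModificationGrammar("(", ")", "name", terminal="underscore", nested=True),
    ),
}

#: platforms handled by dedicated readers rather than the tabular dialect path
STANDARD_FORMATS = ("mztab", "mzid")

#: every supported platform identifier
SUPPORTED_PLATFORMS = tuple(BUILTIN_DIALECTS) + STANDARD_FORMATS


def get_dialect(platform: str, overrides: dict | None = None) -> DialectSpec:
    """Look up a built-in dialect, optionally patched with user overrides."""
    try:
        spec = BUILTIN_DIALECTS[platform]
    except KeyError:
        raise UnsupportedPlatformError(
            f"unsupported platform {platform!r}; supported: {', '.join(SUPPORTED_PLATFORMS)}"
        ) from None
    return spec.override(overrides)
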