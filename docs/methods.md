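# Methods

## Scope and assumptions

pepcover operates strictly downstream of a completed search: it assumes the
input tables have already been through quality control, FDR filtering, and
any normalization the user intends. It performs no score thresholding,
protein inference, or cross-run normalization. The unit of input is one row
per reported peptide observation; what that row means (a PSM, a precursor,
an aggregated peptide) depends on the source tool and is preserved, not
reinterpreted.

## Dialect registry

Dialects are data, not code: a `DialectSpec` maps canonical fields to each
tool's documented column names (PEAKS peptide CSV, Spectronaut report TSV,
MSFragger/FragPipe `psm.tsv`, Comet `.txt`, DIA-NN `report.tsv`, Skyline
peptide CSV, MaxQuant `evidence.txt`) and carries a modification-grammar
descriptor (delimiter pair, payload kind, flanking-residue and
terminal-marker conventions). Tool schemas drift between releases, so
`dialect_overrides` patches renamed columns per call without code changes.
The field separator is sniffed from the header line (tab vs comma), with an
explicit override available. Quantitative fields a dialect does not define
stay absent (NaN) rather than being coerced to 0 — missing intensity and
zero intensity are different facts, and the quantification stage decides
their treatment (absent PSM → weight 1; absent intensity → contributes 0
with a logged warning count).

mzTab is parsed via pyteomics; mzIdentML with a streaming
`lxml.etree.iterparse` loop that clears elements as it goes, so peak memory
is bounded by the largest single element rather than the identification
count. Both formats encode modification positions explicitly (0 = N-term,
length+1 = C-term), so their modifications bypass grammar parsing entirely.

## Sequence stripping and PTM positions

An annotation modifies the residue it follows; its peptide-local position is
the count of residue letters preceding it in the modified string, 1-based.
Terminal modifications get the symbolic positions `NTERM`/`CTERM` instead of
0/length+1, which avoids coordinate ambiguity when projecting onto target
coordinates. Three terminal conventions are recognized: underscore markers
(MaxQuant/Spectronaut), lowercase `n[...]`/`c[...]` markers (MSFragger), and
explicit 0/length+1 locations (mzTab/mzIdentML). One genuinely ambiguous
case is decided by convention: in an underscore grammar, an annotation after
the last residue but *inside* the terminal markers is assigned to the last
residue (position = length); only an annotation after the closing marker
maps to `CTERM`. A leading annotation in a grammar without any terminal
convention is a notation error, reported with its character offset, as are
unbalanced delimiters and residual non-residue characters.

Mass-delta labels are normalized to a signed 2-decimal string (`+79.97`) so
that differently rounded sources display and join consistently; the user PTM
annotation table joins either by exact label or by numeric mass within a
tolerance (default 0.01 Da, the scale of rounding differences between tools,
well below the ~1 Da spacing of distinct common modifications). Labels
absent from the table keep their raw rendering and draw colors from a fixed
cycling palette, assigned over sorted distinct labels so coloring is
deterministic.

## Degeneracy-class matching

Each peptide residue expands to the set of target residues it is compatible
with: N→{N,B,X}, D→{D,B,X}, E→{E,Z,X}, Q→{Q,Z,X}, I and L→{I,L,X},
B→{B,N,D,X}, Z→{Z,E,Q,X}, X→everything, and any other residue r→{r,X}. The
published class table covers only the ambiguous residues N/D/E/Q/I/L; the
extension here is its symmetric closure — B and Z on the *target* side must
accept the residues that accept them, unambiguous residues pair only with
the wildcard, and U (Sec) / O (Pyl) match only themselves and X since no MS
ambiguity class applies to them. Symmetry (a matches b iff b matches a) is
property-tested over all 25×25 pairs. Class sets alone do not fix the
rendered member order, so the conventional bracket strings (`[NBX]`, not
`[BNX]`) are spelled out in an explicit table; the rendering of `NDEQIL` is
exactly `[NBX][DBX][EZX][QZX][ILX][ILX]`.

Matching compiles each unique peptide's classes into a regex of character
classes wrapped in a lookahead, which reports *all* match starts including
overlapping ones; the test suite checks it against an independent
brute-force membership matcher. Coordinates are 1-based inclusive
throughout, and every match satisfies end − start + 1 = peptide length. By
default every peptide is matched against every supplied target (cartesian
pairing); `join_on` keys restrict pairing to records whose condition fields
equal the target's metadata, e.g. matching each donor's peptides only
against that donor's antibody. Records that match nowhere are returned in an
unmatched summary rather than silently dropped.

## Quantification

"Coverage depth" is deliberately metric-dependent:

* **psm** (default): position value = Σ over match occurrences spanning the
  position of the record's PSM count, defaulting to 1 where the source has
  no PSM column. The published displays color by PSM count, which is why
  weighted occurrence counting is the default; `distinct_peptides=True`
  switches to counting unique stripped sequences instead, for the reading of
  "number of peptides" as distinct species. The psm mode obeys an exact
  conservation law — Σ over positions = Σ over occurrences of
  (length × weight) — which the tests exercise on hundreds of random
  projects.
* **intensity / area**: within each group, records are first reduced to
  unique stripped sequences (duplicates aggregated by sum, charge ignored);
  each unique sequence then contributes its aggregated quantity once at
  every residue in the union of its match windows. The union rule keeps the
  invariant that no position exceeds the group's total aggregated quantity,
  even when a repeated epitope's own windows overlap.

A peptide matching multiple sites contributes at every site (no
down-weighting); repeated epitopes therefore show at each copy, which is the
informative display for immunopeptidomics. Positions covered by nothing are
absent from the long-format output and render blank.

## Visualization

Heatmap tiles are centered on integer residue positions with unit width
(tile *i* spans *i*−0.5 .. *i*+0.5); domain separators are drawn exactly at
half-integer edges (start−0.5, end+0.5), so the quantification matrix and
all annotation tracks align without off-by-one ambiguity. Default ramps:
white→black for PSM counts, white→blue for intensity/area, both
overridable. Color normalization defaults to one global scale across facets
— cross-condition comparability is the point of the display — with
`per_facet` available. PTM ticks occupy a fixed band above the heatmap; ties
at one position stack vertically in label-sorted order. Comparison figures
stack one panel row per metric with a shared x-extent. Every written figure
is accompanied by a TSV of the exact plotted matrix, and SVG output is
byte-deterministic within an environment (fixed hash salt, no embedded
date). The non-collapsed mode draws each match occurrence in its own lane,
packed greedily first-fit; the collapsed heatmap is the default.

## Synthetic data

The fixture generator emulates the *structural* properties of search-engine
output: dialect-correct columns and modification notation, flanking residues
and terminal markers where the tool uses them, peptides that genuinely occur
in the target (length 7–14, uniform starts), 1–2 modifications per modified
peptide from a small catalog (phospho, oxidation, carbamidomethyl), PSM
multiplicities of 1–3, and log-uniform intensities/areas (10⁵–10⁸,
spanning the dynamic range typical of label-free quantification). Every
dialect serializer emits one row per PSM occurrence — as Comet, MSFragger,
mzTab and mzIdentML genuinely do — so one ground truth produces an identical
record set in all nine formats; PEAKS/MaxQuant PSM-count columns are then 1
per row rather than aggregated counts, a simplification that keeps the
formats information-equivalent. A single integer seed drives one documented
stream, and serializers share the dialect registry with the readers.

What the generator does **not** emulate: retention times and spectra,
realistic missed cleavages or enzyme specificity, correlated intensity
structure across runs, FDR-shaped score distributions, or real tool export
quirks beyond the documented schemas. Passing tests therefore demonstrate
the pipeline's correctness contracts (round-trips, conservation laws,
coordinate fidelity), not robustness to every wild export a given tool
version may produce — the dialect-override mechanism exists for that.

Default problem sizes in the test and acceptance runs (90-residue targets,
2–10 peptides per project, 200 random projects, 1000 random match pairs)
were chosen so each property is exercised across its structural cases while
a full run stays interactive on a laptop.

## Known limitations

* Multi-residue mass-coincidence ambiguity (e.g. GG vs N) is out of scope;
  pair with an external sequence-resolution tool and map its output.
* No mismatch-tolerant or scored alignment — matching is exact at class
  level.
* Peptide "cluster" calling across donors is not implemented; the
  per-residue tables are exported precisely so such downstream analyses can
  be done in statistics tools.
* mzTab parsing covers the PSM/PEP sections used here, not the full
  standard's metadata surface.
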