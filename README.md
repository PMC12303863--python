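# pepcover

Peptide-to-protein mapping, per-residue quantification roll-up, and
linearized, domain-annotated coverage heatmaps for mass-spectrometry
search-engine results.

## The problem

Proteomics search engines report identified peptides as text tables, each in
its own dialect and modification notation, and rarely offer sequence-level
visualization. Questions like *which regions of this antibody are presented
by MHC-II across a donor panel?* (MAPPs immunopeptidomics) or *how does PTM
coverage of vimentin differ between conditions?* require placing every
identified peptide onto its parent protein, rolling quantities up to residue
resolution, and comparing conditions side by side. pepcover does exactly
that, for outputs of PEAKS, Spectronaut, MSFragger, Comet, DIA-NN, Skyline,
and MaxQuant, plus the standardized mzTab and mzIdentML formats.

## The method

1. **Normalize** — each engine's table is mapped onto one canonical record
   schema (`record_id, source_file, <condition fields>, modified_sequence,
   stripped_sequence, psm, intensity, area, charge`). Multiple files are read
   at once, each carrying user-assigned condition labels (donor, antibody,
   timepoint, ...).
2. **Strip & extract PTMs** — modification annotations, terminal markers,
   and flanking residues (`K.PEPS[79.9663]TIDE.R`) are removed per a
   per-dialect grammar; each modification becomes one PTM record with a
   1-based position in the stripped peptide.
3. **Map** — peptides are placed on target sequences with degeneracy-aware
   matching. Each residue expands to a class of acceptable target residues:
   N↔B, D↔B, E↔Z, Q↔Z, I↔L, and X wildcards on either side, so
   `NDEQIL` becomes the pattern `[NBX][DBX][EZX][QZX][ILX][ILX]`. All
   (overlapping) match positions are reported with 1-based inclusive
   coordinates, and matches are annotated with overlapping
   domain/CDR/mutation regions.
4. **Quantify** — per residue position and condition group: PSM-weighted
   occurrence counts (weight 1 where an engine reports no PSM column), or
   intensity / peak-area sums over unique peptides spanning the position.
5. **Render** — one heatmap row per group over the full target length,
   chains/targets side by side, domain separators at half-integer residue
   edges, CDR/mutation overlays, PTM tick marks above the band, PSM in
   greyscale and intensity/area in white-to-blue, with global or per-facet
   color normalization. A sidecar TSV of the exact plotted matrix accompanies
   every figure.

## Worked example

Generate a synthetic ground-truthed MaxQuant project and run the pipeline:

```sh
pepcover fixtures --platform maxquant -n 8 --seed 42 --outdir demo
```

```python
import pepcover as pc

records = pc.read_results(["demo/maxquant_results.txt"], "maxquant",
                          [{"donor": "D1"}])
records = pc.strip_table(records, platform="maxquant")
targets = pc.load_targets("demo/targets.fasta")
regions = pc.load_regions("demo/regions.tsv")

result = pc.match_peptides(records, targets)
print("records:", len(records), " matches:", len(result.matches),
      " unmatched:", result.n_unmatched)

quant = pc.quantify_positions(result.matches, records, metric="psm",
                              group_by=["donor"])
print(quant.head(4).to_string(index=False))
print(pc.coverage_summary(quant, targets).to_string(index=False))
```

prints

```
records: 20  matches: 20  unmatched: 0
target_id donor  position metric  value
     TGT1    D1         4    psm    5.0
     TGT1    D1         5    psm    5.0
     TGT1    D1         6    psm    5.0
     TGT1    D1         7    psm    5.0
target_id donor  covered  fraction  max_value
     TGT1    D1       57  0.633333  7.0
```

All 8 planted peptides (20 PSM occurrences) map back to their planted
coordinates; residues 4–7 are spanned by occurrences totalling a PSM count
of 5; 57 of the 90 target residues (63%) are covered, and the deepest
position is covered by 7 PSMs. The same pipeline runs end-to-end from the
shell:

```sh
pepcover run --input demo/maxquant_results.txt -p maxquant -c donor=D1 \
    --targets demo/targets.fasta --regions demo/regions.tsv \
    --metric psm --metric intensity -g donor --outdir out
```

which writes `records.tsv`, `matches.tsv`, `quant_psm.tsv`,
`quant_intensity.tsv`, and a stacked PSM/intensity heatmap
`coverage.png` with its `coverage.matrix.tsv` sidecar.

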