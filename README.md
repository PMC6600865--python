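# tfkit

Data structures and workflows for transcription-factor (TF) bioinformatics.

TFs are proteins that bind DNA, typically near promoters, and modulate
transcription. Working with them computationally is complicated by a
multiplicity of resources that do not share a nomenclature: motif-model
catalogs key TFs by IDs like `T004843_1.02` (CISBP) or model names like
`AHR_HUMAN.H11MO.0.A` (HOCOMOCO), target gene-set collections encode TF
identity inside underscore-delimited set names (`GGGNNTTTCC_NFKB_Q6_01`),
binding-affinity predictions live in coordinate-indexed score tracks, and
GWAS catalogs report mapped genes per trait as free-ish text. `tfkit` gives
each of these a typed container and the joins between them, keyed throughout
on the HGNC gene symbol.

What it provides:

- **TF catalogs** (`tfkit.catalog`) — a `TFCatalog` holds a catalog's native
  identifiers plus a metadata table with an obligatory `HGNC` column.
  Loaders for CISBP-schema, HOCOMOCO-schema, and direct-GO-annotation
  tables; HGNC universes; exact membership-signature overlap counts across
  catalogs; distinct-TF class-frequency tables; and a parser for TFClass
  subfamily suffixes (`"HOX-related factors{3.1.1}"` → label + `3.1.1`).
- **Target gene sets** (`tfkit.genesets`) — GMT read/write with lossless
  round-trips, the c3/TFT set-name grammar (motif token, gene token,
  qualifiers), heuristic HGNC matching (exact, then trailing-digit
  stripping), identifier remapping (e.g. Entrez → symbol), and per-TF target
  unions.
- **Binding tracks and peaks** (`tfkit.binding`) — interval queries over
  position-sorted scored-BED tracks (tabix-indexed via pysam, with an
  equivalent linear-scan path), FIMO-style p-values reported as
  `-log10(p)`, per-file/per-interval reductions, TF-family annotation of
  track metadata, ENCODE narrowPeak parsing, and per-experiment peak
  retrieval through a cell-line × TF registry. Coordinates are 0-based
  half-open internally; the CLI accepts 1-based inclusive regions.
- **GWAS joins** (`tfkit.gwas`) — which catalogued TFs are direct mapped
  genes for a trait (`direct_hits`), and which traits are reported for the
  targets of a TF (`top_traits_of_targets`), as plain record tabulations.
- **Synthetic fixtures** (`tfkit.synthetic`) — deterministic generators for
  every input dialect with planted, exactly-known answers, so everything
  runs and tests offline.
- **CLI** (`tfkit`) — `catalog`, `targets`, `binding`, `gwas`, and
  `fixtures` subcommands, each a thin serialization of a library call.

## Worked example

```python
from tfkit import (GenomicInterval, harvest_scores, parse_tfclass_label,
                   parse_tft_name)
from tfkit.synthetic import make_track_set

# 1. The target-set name grammar
p = parse_tft_name("GGGNNTTTCC_NFKB_Q6_01", {"YY1", "MTF1"})
print((p.motif_token, p.gene_token, p.qualifier_tokens, p.match_kind))
# ('GGGNNTTTCC', 'NFKB', ['Q6', '01'], 'unknown')

# 2. TFClass subfamily suffixes on class strings
lab = parse_tfclass_label("More than 3 adjacent zinc finger factors{2.3.3}")
print((lab.label, lab.subfamily_id))
# ('More than 3 adjacent zinc finger factors', '2.3.3')

# 3. Harvest binding scores in a genomic window across a track set
tracks, truths, catalog = make_track_set("demo_tracks", seed=0, n_files=4,
                                         sites_per_file=300)
window = GenomicInterval("chr17", 38_077_000, 38_084_000)
table = harvest_scores(tracks, window, catalog=catalog)
print(table.head(3).to_string(index=False))
```

prints

```
chrom    start      end   motif_id  neglog10p   HGNC Family_Name
chr17 38077827 38077839 M1000_1.02   0.017571 TF0001     C2H2 ZF
chr17 38078138 38078150 M1000_1.02   5.386810 TF0001     C2H2 ZF
chr17 38079306 38079318 M1000_1.02   1.717947 TF0001     C2H2 ZF
```

The first line says the set name decomposes into a 10-base IUPAC motif
token, the gene token `NFKB`, and two version qualifiers — and that `NFKB`
is a vintage label matching no current HGNC symbol (`match_kind='unknown'`),
which is exactly what a curator needs to know. The harvest table is
plot-ready: each row is one predicted binding site in the window, with the
FIMO-style p-value transformed to `-log10(p)` (so 5.39 ≈ p = 4·10⁻⁶) and
the track's TF and family attached from the catalog.

The same workflows are available from the shell, e.g.

```sh
tfkit fixtures make demo --seed 1
tfkit catalog overlap demo/cisbp.tsv demo/hocomoco.tsv -k cisbp -k hocomoco
tfkit gwas direct-hits demo/gwas.tsv "Synthetic trait A" --catalog-path demo/cisbp.tsv
```

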