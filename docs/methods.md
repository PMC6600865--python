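# Methods

This note records the conventions, heuristics, and numerical choices behind
`tfkit`, and what the synthetic fixtures do and do not establish.

## The harmonization model

The package treats the HGNC gene symbol as the cross-catalog key for TF
identity. A `TFCatalog` is a pair (native identifiers, metadata table with
an obligatory `HGNC` column): native IDs are whatever a source uses (motif
model IDs, model names, symbols), and duplicates among them are expected —
motif-model catalogs routinely attach several models to one gene, so record
count and unique-symbol count are different statistics and both are
reported.

Symbol comparison is exact and case-sensitive after stripping surrounding
whitespace. No alias or history expansion is attempted at the catalog level:
catalogs disagree enough that silent aliasing would manufacture overlap.
Blank or missing HGNC entries are excluded from a catalog's universe but
retained in the metadata rows; `hgnc_universe(..., with_report=True)`
returns the excluded count.

**Overlap counts.** For catalogs C₁…Cₖ with universes U₁…Uₖ, every symbol
in ⋃Uᵢ has exactly one membership signature (the subset of catalogs
containing it). The overlap table lists a count per possible non-empty
signature, so Σ counts = |⋃Uᵢ| by construction; this conservation is
asserted in tests and recomputed by the acceptance script. The computation
is a per-symbol enumeration — with catalog universes in the 10²–10⁴ range
there is nothing to optimize.

**Class frequencies** count *distinct* TFs per class (a TF appearing in
five motif-model rows of one class counts once). Ordering is descending by
count with ties broken by class string ascending, a deterministic choice
where the field's tables only specify "by frequency".

**TFClass suffixes.** HOCOMOCO class strings may end in `{x.y.z}` with one
to three dot-separated non-negative integers, the subfamily ID in the
TFClass hierarchy of DNA-binding domains. The parser splits that suffix;
brace content that is not a dotted numeric ID (e.g. `{abc}`, four or more
components) is kept as part of a plain label and flagged `malformed` with a
warning, rather than rejected — class strings are curator text, not a
formal grammar. For well-formed labels, `label + "{" + subfamily_id + "}"`
reproduces the input byte-for-byte.

## The target-set name grammar

c3/TFT set names are underscore-delimited token strings mixing motifs,
gene labels, and version qualifiers. Tokens are classified in order:

1. the first token of length ≥ 6 drawn wholly from the IUPAC nucleotide
   codes `ACGTURYSWKMBDHVN` is the motif token;
2. tokens matching `Q\d+`, `\d+`, or a single letter are qualifiers;
3. the leftmost remaining token is the gene candidate; any further
   non-qualifier tokens also become qualifiers.

The length-6 threshold keeps gene-like symbols (`MYC`, `SOX2`) from being
absorbed as motifs; observed motif tokens in real collections are length 9+.
Every string parses (degenerate results are flagged via `match_kind`), and
re-joining the classified tokens in original order reproduces the input —
an invariant fuzz-tested over 1,000 random token strings.

Gene matching against a supplied symbol universe is deliberately a simple,
replaceable heuristic: exact case-insensitive lookup (`exact`), then a
retry after stripping trailing digits (`close`, so `PAX41` would fall back
to `PAX4` if only the latter exists, while `STAT5B` present in the universe
stays `exact`). Vintage labels with no current symbol (`NFKAPPAB`,
`NFKB`) and the literal token `UNKNOWN` report `match_kind='unknown'`;
resolving them would require manual curation, which is out of scope. Users
needing alias tables can pre-expand the universe they pass in.

GMT I/O deduplicates members within a line on read (real files contain
repeats), records per-set duplicate counts in the collection's `report`,
and writes UTF-8 with LF endings; write→read→write is byte-stable.
Identifier remapping drops unmapped members (counts reported) and can only
shrink sets.

## Binding tracks and peaks

Internal coordinates are 0-based half-open everywhere; BED inputs are read
as-is under that convention, and the CLI converts 1-based inclusive region
strings once at the boundary. The overlap predicate is "at least one shared
base", matching tabix semantics; abutting half-open intervals do not
overlap.

The scored-BED dialect is fixed as (chrom, start, end, motif_id, score,
strand, pvalue) with a per-track-set configurable column map
(`ScoredBedColumns`), since scored-track dialects in the wild anchor only
position and p-value columns reliably.

Two query paths exist by design: `query_track` uses a tabix index (pysam)
when a `.tbi` sibling is present, and otherwise — or when the index is
corrupt, with a warning — falls back to `scan_track_linear`, a full-file
scan. The scan is also the independent oracle: tests and the acceptance
script assert record-for-record equality between the paths across hundreds
of random intervals. Results are sorted by (start, end, motif_id).

Scores are reported as −log10 of the match p-value. A p-value recorded as
exactly 0 is mapped to the cap 400 and flagged (`capped=True`): the cap is
far above any finite single-test value that occurs in practice and keeps
downstream tables free of infinities. −log10(p) is monotone decreasing in
p and non-negative on (0, 1].

Family annotation joins a track's HGNC symbol to the *first* occurrence of
that symbol in the catalog (catalogs repeat symbols across motif models;
first-row metadata is taken as representative). Peak retrieval returns one
group per registry experiment, including empty groups and groups whose file
is missing (`available=False`), so absence of signal is distinguishable
from absence of data.

## GWAS joins

`MAPPED_GENE` fields are split on the delimiters `"; "`, `", "`, and
`" - "` (the dialects seen in EBI exports; configurable). A bare hyphen is
not a delimiter, so `HLA-DRB1` survives intact. Trait matching is exact and
case-sensitive by default (an `--ignore-case` CLI flag relaxes it).

`direct_hits` intersects a trait's mapped genes with a catalog universe;
rows are unique per symbol, ordered by first appearance in the catalog, and
carry the family of the symbol's first catalog row. `top_traits_of_targets`
remaps the collection to symbols if needed, unions the targets of all sets
naming the TF, keeps records with ≥ 1 mapped gene in that set, and counts
*records* per trait — a record with two target genes counts once. Trait
counts are sorted alphabetically, and Σ counts = number of hit records
(asserted). No enrichment statistics are computed: the output is a
tabulation, and significance is a separate modelling question.

## Synthetic data

All fixtures are generated by `tfkit.synthetic` with `numpy`'s
`default_rng`; a fixed seed yields byte-identical files. Planted structure
is the point: overlap suites assign each symbol exactly one membership
signature; target collections are built from (motif, gene, qualifier)
templates; tracks store their in-memory site tables so ground-truth hit
counts come from a computation independent of file parsing; GWAS tables
embed known trait→gene links among noise records. Track p-values are drawn
log-uniformly over [10⁻⁸, 1] so −log10 scores spread evenly across [0, 8].

Default problem sizes (catalog snapshots of 50 rows / 40 symbols, 12-set
collections, 16-track sets of a few hundred sites, registries of 4 cell
lines) are chosen so a full suite regenerates in well under a second while
every code path — duplicates, blanks, unknowns, empty regions — is
exercised; the acceptance script scales selected measurements up (200
random intervals, 1,000 fuzzed names, an 11-signature/720-symbol overlap
suite).

What the fixtures do **not** emulate: spatial autocorrelation of motif
scores, linkage disequilibrium among GWAS variants, real catalog sizes, or
the curatorial messiness of real symbol vocabularies beyond the planted
cases. Green tests therefore certify the bookkeeping — parsing, joins,
interval arithmetic, conservation laws — not biological conclusions drawn
from real snapshots. Statistics tied to particular public snapshot releases
can be reproduced by pointing the loaders and CLI at those files once they
are available locally.

## Known limitations

- No alias/ortholog expansion of HGNC symbols; harmonization of class
  terminology across catalogs is out of scope.
- The gene-token heuristic merges versioned set names onto one TF and will
  not resolve pre-HGNC vintage labels.
- Remote (URL/S3) track access is represented only as file references;
  retrieval is the caller's concern.
- Figures are not rendered; the package emits their underlying tables.
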