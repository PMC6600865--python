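"""Interval queries over genome-wide binding-affinity tracks and ChIP-seq peaks.

Two representations of putative TF binding are supported:

* **Scored tracks** — position-sorted BED-like files of motif-scan scores
  (one file per motif model, FIMO-style), each row carrying a match p-value.
  Scores are harvested from a genomic window and reported as ``-log10(p)``.
  Files may be plain text or bgzip-compressed with a tabix index; an indexed
  query and a naive linear scan return identical record sets, and the linear
  scan doubles as the fallback when no usable index is present.

* **ChIP-seq peaks** — ENCODE-style narrowPeak (BED6+4) files, one per
  experiment, addressed through a registry of (cell line, TF, file) rows.

All internal coordinates are 0-based half-open; the overlap predicate is
"any shared base", matching tabix semantics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
import pysam

from .catalog import HGNC_COLUMN, TFCatalog
from .errors import FormatError, SchemaError

#: -log10(p) assigned to p-values recorded as exactly zero; keeps downstream
#: tables finite while remaining clearly out-of-band
NEGLOG10P_CAP = 400.0


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class ScoredSite:
    """One motif-scan hit: location, motif tag, strand, and match p-value."""

    interval: GenomicInterval
    motif_id: str
    strand: str
    pvalue: float
    neglog10p: float = field(init=False)
    capped: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.pvalue}")
        if self.pvalue == 0.0:
            object.__setattr__(self, "neglog10p", NEGLOG10P_CAP)
            object.__setattr__(self, "capped", True)
        else:
            object.__setattr__(self, "neglog10p", -math.log10(self.pvalue))
            object.__setattr__(self, "capped", False)


@dataclass(frozen=True)
class ScoredBedColumns:
    """0-based column indices of the scored-BED dialect.

    Default layout: chrom, start, end, motif_id, score, strand, pvalue.
    """

    chrom: int = 0
    start: int = 1
    end: int = 2
    motif_id: int = 3
    strand: int = 5
    pvalue: int = 6


DEFAULT_COLUMNS = ScoredBedColumns()


def _site_from_fields(fields: Sequence[str], cols: ScoredBedColumns) -> ScoredSite:
    return ScoredSite(
        interval=GenomicInterval(
            fields[cols.chrom], int(fields[cols.start]), int(fields[cols.end])
        ),
        motif_id=fields[cols.motif_id],
        strand=fields[cols.strand],
        pvalue=float(fields[cols.pvalue]),
    )


def scan_track_linear(
    file, interval: GenomicInterval, columns: ScoredBedColumns = DEFAULT_COLUMNS
) -> list[ScoredSite]:
    """Full-file scan returning all sites overlapping the interval.

    Reads plain or bgzip-compressed text line by line; serves both as the
    no-index fallback of :func:`query_track` and as its independent oracle
    in the test suite.
    """
    import gzip

    path = Path(file)
    opener = gzip.open if path.suffix == ".gz" else open
    hits: list[ScoredSite] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            site = _site_from_fields(fields, columns)
            if site.interval.overlaps(interval):
                hits.append(site)
    hits.sort(key=lambda s: (s.interval.start, s.interval.end, s.motif_id))
    return hits


def query_track(
    file,
    interval: GenomicInterval,
    columns: ScoredBedColumns = DEFAULT_COLUMNS,
) -> list[ScoredSite]:
    """All scored sites overlapping an interval, in ascending start order.

    Uses the tabix index when the file is bgzip-compressed and a ``.tbi``
    sibling exists; otherwise (or if the index is unusable) falls back to a
    linear scan.  A chromosome absent from the file yields an empty result.
    """
    path = Path(file)
    index = path.with_name(path.name + ".tbi")
    if path.suffix == ".gz" and index.exists():
        try:
            with pysam.TabixFile(str(path)) as tbx:
                if interval.chrom not in tbx.contigs:
                    return []
                hits = [
                    _site_from_fields(row.split("\t"), columns)
                    for row in tbx.fetch(interval.chrom, interval.start, interval.end)
                ]
            hits.sort(key=lambda s: (s.interval.start, s.interval.end, s.motif_id))
            return hits
        except (OSError, ValueError) as exc:
            warnings.warn(f"{path}: tabix query failed ({exc}); falling back to linear scan")
    return scan_track_linear(path, interval, columns)


@dataclass
class BindingTrackSet:
    """An ordered set of scored-track files with per-file motif/TF metadata.

    ``metadata`` has one row per file with obligatory columns ``Mtag``
    (motif-model tag, e.g. ``M0635_1``) and ``HGNC`` (associated gene
    symbol).  ``query_ranges`` optionally carries default query intervals.
    """

    files: list[str]
    metadata: pd.DataFrame
    query_ranges: list[GenomicInterval] = field(default_factory=list)
    columns: ScoredBedColumns = DEFAULT_COLUMNS

    def __post_init__(self) -> None:
        if len(self.files) != len(self.metadata):
            raise ValueError(
                f"{len(self.files)} files but {len(self.metadata)} metadata rows"
            )
        for col in ("Mtag", HGNC_COLUMN):
            if col not in self.metadata.columns:
                raise SchemaError(f"track-set metadata lacks column {col!r}")

    def __len__(self) -> int:
        return len(self.files)


def reduce_by_file(
    tracks: BindingTrackSet,
    intervals: Sequence[GenomicInterval] | None = None,
    map_fn: Callable[[list[ScoredSite]], object] | None = None,
) -> dict[str, list]:
    """Query every track at every interval; nested results file -> interval.

    Returns one entry per file in metadata order; each value is a list with
    one element per interval in input order, holding ``map_fn`` applied to
    the raw hit list (identity when ``map_fn`` is None).  An exception inside
    ``map_fn`` is re-raised with the file identity attached.
    """
    if intervals is None:
        intervals = tracks.query_ranges
    if not tracks.files or not intervals:
        raise ValueError("need at least one file and one interval")
    out: dict[str, list] = {}
    for f in tracks.files:
        per_interval = []
        for iv in intervals:
            hits = query_track(f, iv, tracks.columns)
            if map_fn is not None:
                try:
                    hits = map_fn(hits)
                except Exception as exc:
                    raise RuntimeError(f"map_fn failed on file {f!r}: {exc}") from exc
            per_interval.append(hits)
        out[str(f)] = per_interval
    return out


def annotate_family(
    tracks: BindingTrackSet, catalog: TFCatalog, family_column: str = "Family_Name"
) -> pd.DataFrame:
    """Copy of the track metadata with the catalog's TF-family label added.

    Each track's HGNC symbol is matched to its *first* occurrence in the
    catalog (catalogs list several motif models per gene; the first row's
    family is taken).  Unmatched symbols get a missing value.
    """
    if family_column not in catalog.hgnc_map.columns:
        raise SchemaError(
            f"catalog {catalog.name!r} lacks family column {family_column!r}"
        )
    first = (
        catalog.hgnc_map[[HGNC_COLUMN, family_column]]
        .drop_duplicates(subset=HGNC_COLUMN, keep="first")
        .set_index(HGNC_COLUMN)[family_column]
    )
    meta = tracks.metadata.copy()
    meta[family_column] = meta[HGNC_COLUMN].map(first)
    return meta


def harvest_scores(
    tracks: BindingTrackSet,
    interval: GenomicInterval,
    catalog: TFCatalog | None = None,
    family_column: str = "Family_Name",
) -> pd.DataFrame:
    """Concatenated per-file hits with ``neglog10p``, HGNC and family columns.

    This is the plot-ready table for displaying predicted binding affinity
    across TFs in a genomic window (e.g. the neighborhood of one gene).
    """
    if catalog is not None:
        meta = annotate_family(tracks, catalog, family_column)
    else:
        meta = tracks.metadata.copy()
        meta[family_column] = pd.NA
    rows = []
    for f, (_, mrow) in zip(tracks.files, meta.iterrows()):
        for site in query_track(f, interval, tracks.columns):
            rows.append(
                {
                    "chrom": site.interval.chrom,
                    "start": site.interval.start,
                    "end": site.interval.end,
                    "motif_id": site.motif_id,
                    "neglog10p": site.neglog10p,
                    HGNC_COLUMN: mrow[HGNC_COLUMN],
                    family_column: mrow[family_column],
                }
            )
    cols = ["chrom", "start", "end", "motif_id", "neglog10p", HGNC_COLUMN, family_column]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# narrowPeak / ENCODE registry


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record (BED6+4): interval, signal, and summit offset."""

    interval: GenomicInterval
    name: str
    score: int
    strand: str
    signal: float
    pvalue: float
    qvalue: float
    summit: int  # offset from interval start; -1 means not called


def read_narrowpeak(path) -> list[Peak]:
    """Read a 10-column ENCODE narrowPeak file into a list of peaks."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns, found {len(fields)}"
                )
            peaks.append(
                Peak(
                    interval=GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    name=fields[3],
                    score=int(fields[4]),
                    strand=fields[5],
                    signal=float(fields[6]),
                    pvalue=float(fields[7]),
                    qvalue=float(fields[8]),
                    summit=int(fields[9]),
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        p.interval.chrom, p.interval.start, p.interval.end,
                        p.name, p.score, p.strand,
                        p.signal, p.pvalue, p.qvalue, p.summit,
                    )
                )
                + "\n"
            )
    return path


@dataclass
class EncodeRegistry:
    """Registry of ChIP-seq experiments: one row per (cell line, TF, file)."""

    table: pd.DataFrame

    REQUIRED = ("cell_line", "tf_hgnc", "peak_file")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise SchemaError(f"registry lacks column {col!r}")
        if self.table.duplicated(subset=list(self.REQUIRED)).any():
            raise ValueError("registry rows must be unique on (cell_line, tf_hgnc, peak_file)")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "EncodeRegistry":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class ExperimentPeaks:
    """Peaks of one experiment restricted to a query region."""

    cell_line: str
    tf_hgnc: str
    peak_file: str
    peaks: list[Peak]
    available: bool = True


def peaks_in_region(
    registry: EncodeRegistry,
    tf: str,
    region: GenomicInterval,
    cell_lines: Iterable[str] | None = None,
) -> list[ExperimentPeaks]:
    """Per-experiment peak lists overlapping a region, for one TF.

    One result group per matching registry row (possibly with an empty peak
    list).  Experiments whose peak file is missing on disk are reported with
    ``available=False`` rather than silently dropped.  A TF absent from the
    registry yields an empty result with a warning.
    """
    rows = registry.table[registry.table["tf_hgnc"] == tf]
    if cell_lines is not None:
        rows = rows[rows["cell_line"].isin(set(cell_lines))]
    if rows.empty:
        warnings.warn(f"no registry experiments for TF {tf!r}")
        return []
    out: list[ExperimentPeaks] = []
    for _, row in rows.iterrows():
        pf = Path(row["peak_file"])
        if not pf.exists():
            out.append(ExperimentPeaks(row["cell_line"], tf, str(pf), [], available=False))
            continue
        hits = [p for p in read_narrowpeak(pf) if p.interval.overlaps(region)]
        out.append(ExperimentPeaks(row["cell_line"], tf, str(pf), hits))
    return out
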