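"""Synthetic fixtures with planted, exactly-known structure.

Every consumer module in the toolkit reads files in a public dialect
(catalog TSV, GMT, scored BED, narrowPeak, GWAS TSV).  The generators here
emit small instances of each dialect together with the ground-truth answers
the corresponding operations must reproduce — planted overlap signatures,
planted (motif, gene) name components, per-interval hit counts, planted
trait/target links — so the whole package builds and tests offline.

All generators are deterministic: a fixed seed yields byte-identical files.
Gene symbols are drawn from a synthetic namespace (``G0001``...; TF names
``TF01``...) plus a few real symbols used in documentation examples
(TFAP2B, YY1, MTF1, TP53) so those examples run verbatim.

What these fixtures deliberately do **not** emulate: spatial autocorrelation
of motif scores along the genome, linkage disequilibrium among GWAS SNPs,
and the true size of public catalogs.  Tests passing on them certify the
bookkeeping (parsing, joins, interval arithmetic), not biological realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .binding import (
    BindingTrackSet,
    EncodeRegistry,
    GenomicInterval,
    Peak,
    write_narrowpeak,
)
from .catalog import HGNC_COLUMN, TFCatalog
from .genesets import GeneSet, GeneSetCollection, write_gmt

#: real symbols used in the package's documentation examples
DOC_SYMBOLS = ("TFAP2B", "YY1", "MTF1", "TP53")

_FAMILIES = (
    "C2H2 ZF", "Homeodomain", "bHLH", "bZIP", "Forkhead",
    "Nuclear receptor", "Ets", "GATA", "STAT", "IRF",
)

_CLASS_STRINGS = (
    "More than 3 adjacent zinc finger factors{2.3.3}",
    "HOX-related factors{3.1.1}",
    "NK-related factors{3.1.2}",
    "Paired-related HD factors{3.1.3}",
    "Forkhead box (FOX) factors{3.3.1}",
    "Ets-related factors{3.5.2}",
    "Homeodomain",
)


def _symbols(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# catalogs


def make_catalog_suite(
    signature_counts: Mapping[tuple[str, ...], int],
    seed: int = 0,
) -> tuple[list[TFCatalog], pd.DataFrame]:
    """Catalogs whose HGNC-overlap structure is planted exactly.

    ``signature_counts`` maps a tuple of catalog names (the catalogs that
    contain a symbol) to the number of unique symbols with exactly that
    membership; every symbol is assigned to exactly one signature.  Returns
    the catalogs and the expected overlap table in the same shape
    :func:`tfkit.catalog.overlap_counts` produces.
    """
    names: list[str] = []
    for sig, count in signature_counts.items():
        if count < 0:
            raise ValueError(f"negative count for signature {sig}")
        if not sig:
            raise ValueError("empty signature (symbol in no catalog) is not allowed")
        for n in sig:
            if n not in names:
                names.append(n)
    rng = np.random.default_rng(seed)
    total = sum(signature_counts.values())
    pool = _symbols(total)
    rng.shuffle(pool)
    members: dict[str, list[str]] = {n: [] for n in names}
    expected_rows = []
    i = 0
    from itertools import product

    for sig, count in signature_counts.items():
        for sym in pool[i : i + count]:
            for n in sig:
                members[n].append(sym)
        i += count
    for bits in product([True, False], repeat=len(names)):
        if not any(bits):
            continue
        sig = tuple(n for n, b in zip(names, bits) if b)
        count = 0
        for key, c in signature_counts.items():
            if tuple(sorted(key)) == tuple(sorted(sig)):
                count += c
        expected_rows.append(dict(zip(names, bits)) | {"count": count})
    expected = pd.DataFrame(expected_rows)
    catalogs = []
    for n in names:
        syms = sorted(members[n])
        hgnc_map = pd.DataFrame(
            {
                HGNC_COLUMN: syms,
                "Family_Name": [_FAMILIES[j % len(_FAMILIES)] for j in range(len(syms))],
            }
        )
        catalogs.append(
            TFCatalog(name=n, native_ids=[f"{n}_{s}" for s in syms], hgnc_map=hgnc_map)
        )
    return catalogs, expected


def make_cisbp_snapshot(
    path,
    seed: int = 0,
    n_genes: int = 40,
    n_duplicate_rows: int = 10,
) -> tuple[Path, dict]:
    """A CISBP-schema snapshot: 28 columns, one row per motif model.

    Some genes receive a second motif model (duplicate ``TF_Name``), as in
    the real catalog.  Ground truth: row count, the unique-symbol set, and
    distinct-TF counts per family.
    """
    rng = np.random.default_rng(seed)
    genes = _symbols(n_genes, "TF")[: n_genes - len(DOC_SYMBOLS)] + list(DOC_SYMBOLS)
    families = [
        _FAMILIES[int(j)] for j in rng.integers(0, len(_FAMILIES), size=len(genes))
    ]
    rows = list(zip(genes, families))
    dup_idx = rng.choice(len(rows), size=min(n_duplicate_rows, len(rows)), replace=False)
    rows += [rows[int(j)] for j in sorted(dup_idx)]
    extra_cols = {f"X{k:02d}": ["na"] * len(rows) for k in range(1, 26)}
    df = pd.DataFrame(
        {
            "TF_ID": [f"T{i:06d}_1.02" for i in range(1, len(rows) + 1)],
            "TF_Name": [g for g, _ in rows],
            "Family_Name": [f for _, f in rows],
            **extra_cols,
        }
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    per_family = (
        df[["Family_Name", "TF_Name"]].drop_duplicates().groupby("Family_Name").size()
    )
    truth = {
        "n_rows": len(df),
        "unique_symbols": sorted(set(df["TF_Name"])),
        "family_distinct_counts": per_family.to_dict(),
    }
    return path, truth


def make_hocomoco_snapshot(path, seed: int = 0, n_rows: int = 20) -> tuple[Path, dict]:
    """A HOCOMOCO-schema snapshot: 9 columns, class strings planted verbatim."""
    rng = np.random.default_rng(seed)
    genes = _symbols(n_rows, "TF")
    classes = [
        _CLASS_STRINGS[int(j)]
        for j in rng.integers(0, len(_CLASS_STRINGS), size=n_rows)
    ]
    df = pd.DataFrame(
        {
            "Model": [f"{g}_HUMAN.H11MO.0.A" for g in genes],
            "Transcription factor": genes,
            "Model length": rng.integers(8, 22, size=n_rows),
            "Quality": ["A"] * n_rows,
            "Rank": range(n_rows),
            "Consensus": ["ACGT" * 3] * n_rows,
            "Class": classes,
            "Family": ["fam"] * n_rows,
            "Release": ["synthetic-sept2018-schema"] * n_rows,
        }
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path, {"n_rows": n_rows, "classes": classes}


def make_go_annotation(
    path, seed: int = 0, n_tf: int = 30, n_other: int = 70
) -> tuple[Path, dict]:
    """Two-column symbol/GO table; exactly ``n_tf`` symbols annotated to the
    TF-activity term GO:0003700, the rest to unrelated terms."""
    rng = np.random.default_rng(seed)
    tf_syms = _symbols(n_tf, "TF")
    other_syms = _symbols(n_other, "G")
    other_terms = ["GO:0005515", "GO:0003674", "GO:0016301"]
    rows = [(s, "GO:0003700") for s in tf_syms] + [
        (s, other_terms[int(j)])
        for s, j in zip(other_syms, rng.integers(0, len(other_terms), size=n_other))
    ]
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[int(i)] for i in order], columns=["SYMBOL", "GO_ID"])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path, {"tf_symbols": sorted(tf_syms)}


# ---------------------------------------------------------------------------
# gene sets


_MOTIF_ALPHA = "ACGTN"


def _random_motif(rng: np.random.Generator, length: int = 10) -> str:
    return "".join(_MOTIF_ALPHA[int(i)] for i in rng.integers(0, len(_MOTIF_ALPHA), length))


def make_tft_collection(
    path,
    seed: int = 0,
    n_sets: int = 12,
    members_per_set: tuple[int, int] = (5, 15),
    n_unknown: int = 2,
    id_type: str = "symbol",
) -> tuple[Path, pd.DataFrame]:
    """A GMT file of TF-target sets with planted name components.

    Set names follow the ``motif_gene_qualifier`` template (a random IUPAC
    motif for half the sets, the qualifiers drawn from {Q2, Q6, 01, C});
    ``n_unknown`` sets carry the literal gene token ``UNKNOWN``.  Ground
    truth: a table of (raw name, planted motif, planted gene).
    """
    rng = np.random.default_rng(seed)
    genes = _symbols(max(n_sets, 1), "TF")
    pool = _symbols(60, "G")
    rows = []
    sets: list[GeneSet] = []
    for i in range(n_sets):
        gene = "UNKNOWN" if i < n_unknown else genes[i]
        motif = _random_motif(rng) if i % 2 == 0 else None
        quals = [["Q2"], ["Q6"], ["01"], ["Q6", "01"], ["C"]][i % 5]
        tokens = ([motif] if motif else []) + [gene] + quals
        raw = "_".join(tokens)
        size = int(rng.integers(*members_per_set))
        members = [pool[int(j)] for j in rng.choice(len(pool), size=size, replace=False)]
        sets.append(GeneSet(name=raw, description=f"synthetic target set {i}",
                            members=members, id_type=id_type))
        rows.append({"raw": raw, "motif": motif, "gene": gene,
                     "members": list(sets[-1].members)})
    coll = GeneSetCollection(name="synthetic-tft", sets=sets, id_type=id_type)
    path = Path(path)
    write_gmt(coll, path)
    return path, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scored tracks


@dataclass
class TrackTruth:
    """A generated track plus its in-memory sites for oracle counting."""

    plain_path: Path
    indexed_path: Path | None
    sites: pd.DataFrame  # columns chrom, start, end, motif_id, score, strand, pvalue

    def hit_count(self, interval: GenomicInterval) -> int:
        """Ground-truth overlap count computed on the in-memory table."""
        s = self.sites
        mask = (
            (s["chrom"] == interval.chrom)
            & (s["start"] < interval.end)
            & (s["end"] > interval.start)
        )
        return int(mask.sum())


def make_scored_track(
    path,
    seed: int = 0,
    n_sites: int = 1000,
    chroms: Sequence[str] = ("chr17", "chr1"),
    pos_range: tuple[int, int] = (38_000_000, 38_100_000),
    site_len: int = 12,
    motif_id: str = "M0001_1.02",
    index: bool = True,
) -> TrackTruth:
    """A sorted scored-BED track; p-values log-uniform over [1e-8, 1].

    The log-uniform draw spreads ``-log10(p)`` evenly over [0, 8], which
    keeps plotting-table tests sensitive across the score range.  When
    ``index`` is true a bgzip + tabix sibling is written; it decompresses to
    the identical plain file.
    """
    rng = np.random.default_rng(seed)
    chrom = [chroms[int(i)] for i in rng.integers(0, len(chroms), size=n_sites)]
    start = rng.integers(pos_range[0], pos_range[1] - site_len, size=n_sites)
    pvals = 10.0 ** rng.uniform(-8, 0, size=n_sites)
    strands = ["+", "-"]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + site_len,
            "motif_id": motif_id,
            "score": 0,
            "strand": [strands[int(i)] for i in rng.integers(0, 2, size=n_sites)],
            "pvalue": [f"{p:.6g}" for p in pvals],
        }
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")
    indexed = None
    if index:
        gz = path.with_name(path.name + ".gz")
        pysam.tabix_compress(str(path), str(gz), force=True)
        pysam.tabix_index(str(gz), seq_col=0, start_col=1, end_col=2, force=True,
                          zerobased=True)
        indexed = gz
    sites = df.copy()
    sites["pvalue"] = sites["pvalue"].astype(float)
    return TrackTruth(plain_path=path, indexed_path=indexed, sites=sites)


def make_track_set(
    directory,
    seed: int = 0,
    n_files: int = 16,
    sites_per_file: int = 200,
    index: bool = True,
    **track_kwargs,
) -> tuple[BindingTrackSet, list[TrackTruth], TFCatalog]:
    """A multi-track set with Mtag/HGNC metadata and a family catalog.

    Mirrors the shape of a motif-score track collection: one file per motif
    model, metadata rows pairing each motif tag with its gene.  Also returns
    a small CISBP-style catalog assigning each gene a family, for annotation
    tests.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = _symbols(n_files, "TF")
    truths: list[TrackTruth] = []
    files: list[str] = []
    mtags: list[str] = []
    for i, gene in enumerate(genes):
        mtag = f"M{1000 + i}_1"
        tt = make_scored_track(
            directory / f"{mtag}.02sort.bed",
            seed=int(rng.integers(0, 2**31 - 1)),
            n_sites=sites_per_file,
            motif_id=f"{mtag}.02",
            index=index,
            **track_kwargs,
        )
        truths.append(tt)
        files.append(str(tt.indexed_path if index else tt.plain_path))
        mtags.append(mtag)
    metadata = pd.DataFrame({"Mtag": mtags, HGNC_COLUMN: genes})
    tracks = BindingTrackSet(files=files, metadata=metadata)
    families = [_FAMILIES[i % len(_FAMILIES)] for i in range(n_files)]
    catalog = TFCatalog(
        name="synthetic-cisbp",
        native_ids=[f"T{i:06d}_1.02" for i in range(n_files)],
        hgnc_map=pd.DataFrame({HGNC_COLUMN: genes, "Family_Name": families}),
    )
    return tracks, truths, catalog


# ---------------------------------------------------------------------------
# narrowPeak / registry


def make_encode_registry(
    directory,
    seed: int = 0,
    tf: str = "CEBPB",
    cell_lines: Sequence[str] = ("HepG2", "K562", "A549", "IMR90"),
    cluster: GenomicInterval = GenomicInterval("chr17", 38_077_000, 38_084_000),
    peaks_in_cluster: tuple[int, int] = (2, 6),
    background_peaks: int = 10,
) -> tuple[EncodeRegistry, dict[str, int]]:
    """Per-cell-line narrowPeak files with a planted peak cluster.

    Each cell line gets a known number of peaks inside ``cluster`` plus
    background peaks on another chromosome.  Ground truth: expected
    per-cell-line overlap counts for a query covering the cluster.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, int] = {}
    for cl in cell_lines:
        n_in = int(rng.integers(*peaks_in_cluster))
        peaks: list[Peak] = []
        width = 300
        for j in range(n_in):
            s = int(rng.integers(cluster.start, cluster.end - width))
            peaks.append(
                Peak(GenomicInterval(cluster.chrom, s, s + width), f"{cl}_in{j}",
                     500, ".", float(rng.uniform(2, 30)), -1.0, -1.0, width // 2)
            )
        for j in range(background_peaks):
            s = int(rng.integers(1_000_000, 2_000_000))
            peaks.append(
                Peak(GenomicInterval("chr9", s, s + width), f"{cl}_bg{j}",
                     200, ".", float(rng.uniform(2, 30)), -1.0, -1.0, -1)
            )
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        pf = directory / f"{tf}_{cl}.narrowPeak"
        write_narrowpeak(peaks, pf)
        rows.append({"cell_line": cl, "tf_hgnc": tf, "peak_file": str(pf)})
        truth[cl] = n_in
    return EncodeRegistry(pd.DataFrame(rows)), truth


# ---------------------------------------------------------------------------
# GWAS


def make_gwas_table(
    path,
    seed: int = 0,
    direct_links: Mapping[str, Sequence[str]] | None = None,
    target_links: Mapping[str, Mapping[str, int]] | None = None,
    n_noise: int = 10,
) -> tuple[Path, dict]:
    """A GWAS-catalog-style TSV with planted trait/gene links.

    ``direct_links`` maps trait -> TF symbols to plant as mapped genes
    (one record per symbol).  ``target_links`` maps trait -> {gene: n_records}
    for target-hit tabulation tests.  Noise records use genes (``NOISE``
    namespace) and traits that collide with nothing planted.  Ground truth:
    the planted structures echoed back, plus expected per-trait record
    counts for any gene subset via records in the file.
    """
    rng = np.random.default_rng(seed)
    direct_links = dict(direct_links or {})
    target_links = {t: dict(g) for t, g in (target_links or {}).items()}
    rows = []
    snp = 1

    def record(trait: str, gene_field: str) -> dict:
        nonlocal snp
        rec = {
            "DISEASE.TRAIT": trait,
            "MAPPED_GENE": gene_field,
            "SNPS": f"rs{snp:07d}",
            "CHR_ID": str(int(rng.integers(1, 23))),
            "CHR_POS": str(int(rng.integers(1, 2**27))),
        }
        snp += 1
        return rec

    for trait, genes in direct_links.items():
        for g in genes:
            rows.append(record(trait, g))
    for trait, gene_counts in target_links.items():
        for g, n in gene_counts.items():
            for _ in range(n):
                rows.append(record(trait, g))
    for i in range(n_noise):
        rows.append(record(f"Noise trait {i}", f"NOISE{i:03d}"))
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[int(i)] for i in order])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    truth = {
        "direct_links": {t: sorted(g) for t, g in direct_links.items()},
        "target_links": target_links,
        "n_records": len(df),
    }
    return path, truth


# ---------------------------------------------------------------------------
# full suite for the CLI


def make_fixture_suite(directory, seed: int = 0) -> dict:
    """Generate one of everything into a directory; write a manifest JSON.

    Used by ``tfkit fixtures make`` so every CLI command can be exercised
    offline.  Returns the manifest (paths + ground truths).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cisbp, cisbp_truth = make_cisbp_snapshot(directory / "cisbp.tsv", seed=seed)
    hoco, hoco_truth = make_hocomoco_snapshot(directory / "hocomoco.tsv", seed=seed)
    go, go_truth = make_go_annotation(directory / "go_annotation.tsv", seed=seed)
    gmt, tft_truth = make_tft_collection(directory / "tft.gmt", seed=seed)
    tracks, _, cat = make_track_set(directory / "tracks", seed=seed, n_files=4,
                                    sites_per_file=300)
    tracks.metadata.to_csv(directory / "tracks" / "metadata.tsv", sep="\t", index=False)
    registry, reg_truth = make_encode_registry(directory / "peaks", seed=seed)
    registry.table.to_csv(directory / "encode_registry.tsv", sep="\t", index=False)
    gwas, gwas_truth = make_gwas_table(
        directory / "gwas.tsv",
        seed=seed,
        direct_links={"Synthetic trait A": ["TF01", "TF02"]},
        target_links={"Synthetic trait B": {"G0001": 2, "G0002": 1}},
    )
    manifest = {
        "seed": seed,
        "files": {
            "cisbp": str(cisbp),
            "hocomoco": str(hoco),
            "go_annotation": str(go),
            "tft_gmt": str(gmt),
            "track_metadata": str(directory / "tracks" / "metadata.tsv"),
            "track_files": tracks.files,
            "encode_registry": str(directory / "encode_registry.tsv"),
            "gwas": str(gwas),
        },
        "truth": {
            "cisbp": cisbp_truth,
            "hocomoco": hoco_truth,
            "go": go_truth,
            "gwas": gwas_truth,
            "encode_cluster_counts": reg_truth,
        },
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
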