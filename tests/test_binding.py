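"""Interval queries: indexed vs linear scan, score transforms, peaks."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfkit import (
    BindingTrackSet,
    EncodeRegistry,
    FormatError,
    GenomicInterval,
    Peak,
    ScoredSite,
    SchemaError,
    annotate_family,
    harvest_scores,
    peaks_in_region,
    query_track,
    read_narrowpeak,
    reduce_by_file,
    scan_track_linear,
    write_narrowpeak,
)
from tfkit.binding import NEGLOG10P_CAP
from tfkit.catalog import TFCatalog


def _key(sites):
    return [
        (s.interval.chrom, s.interval.start, s.interval.end, s.motif_id, s.pvalue)
        for s in sites
    ]


class TestGenomicInterval:
    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ((0, 10), (10, 20), False),  # half-open: abutting does not overlap
            ((0, 10), (9, 20), True),
            ((5, 6), (0, 100), True),
            ((0, 10), (0, 10), True),
        ],
    )
    def test_half_open_overlap(self, a, b, expect):
        ia = GenomicInterval("chr1", *a)
        ib = GenomicInterval("chr1", *b)
        assert ia.overlaps(ib) is expect and ib.overlaps(ia) is expect

    def test_different_chrom_never_overlaps(self):
        assert not GenomicInterval("chr1", 0, 10).overlaps(
            GenomicInterval("chr2", 0, 10))


class TestScoredSite:
    def test_neglog10p_closed_form(self):
        s = ScoredSite(GenomicInterval("chr17", 100, 112), "M1", "+", 0.001)
        assert math.isclose(s.neglog10p, 3.0, abs_tol=1e-12)

    def test_zero_pvalue_capped_and_flagged(self):
        s = ScoredSite(GenomicInterval("chr17", 100, 112), "M1", "+", 0.0)
        assert s.neglog10p == NEGLOG10P_CAP and s.capped

    def test_monotone_decreasing_in_pvalue(self):
        ps = [1.0, 0.5, 1e-3, 1e-7]
        sites = [ScoredSite(GenomicInterval("c", 0, 1), "M", "+", p) for p in ps]
        scores = [s.neglog10p for s in sites]
        assert scores == sorted(scores)
        assert all(s >= 0 for s in scores)

    def test_out_of_range_pvalue_rejected(self):
        with pytest.raises(ValueError):
            ScoredSite(GenomicInterval("c", 0, 1), "M", "+", 1.5)


class TestQueryTrack:
    def test_upstream_interval_empty(self, scored_track):
        assert query_track(scored_track.indexed_path,
                           GenomicInterval("chr17", 1, 100)) == []

    def test_absent_chrom_empty_not_error(self, scored_track):
        assert query_track(scored_track.indexed_path,
                           GenomicInterval("chrZ", 1, 100)) == []

    def test_indexed_equals_linear_scan(self, scored_track):
        iv = GenomicInterval("chr17", 38_010_000, 38_050_000)
        via_index = query_track(scored_track.indexed_path, iv)
        via_scan = scan_track_linear(scored_track.plain_path, iv)
        assert _key(via_index) == _key(via_scan)
        assert via_index  # the window is inside the generated range

    def test_results_sorted_and_within_bounds(self, scored_track):
        iv = GenomicInterval("chr17", 38_020_000, 38_030_000)
        hits = query_track(scored_track.indexed_path, iv)
        starts = [s.interval.start for s in hits]
        assert starts == sorted(starts)
        assert all(s.interval.overlaps(iv) for s in hits)

    def test_ground_truth_counts(self, scored_track):
        iv = GenomicInterval("chr1", 38_000_000, 38_100_000)
        n = scored_track.hit_count(iv)
        assert len(query_track(scored_track.indexed_path, iv)) == n
        assert n == (scored_track.sites["chrom"] == "chr1").sum()

    def test_corrupt_index_falls_back_to_scan(self, scored_track, tmp_path):
        gz = tmp_path / "t.bed.gz"
        shutil.copy(scored_track.indexed_path, gz)
        (tmp_path / "t.bed.gz.tbi").write_bytes(b"not an index")
        iv = GenomicInterval("chr17", 38_010_000, 38_050_000)
        with pytest.warns(UserWarning, match="linear scan"):
            hits = query_track(gz, iv)
        assert _key(hits) == _key(scan_track_linear(scored_track.plain_path, iv))

    @settings(deadline=None, max_examples=40)
    @given(
        chrom=st.sampled_from(["chr17", "chr1", "chrX"]),
        start=st.integers(37_990_000, 38_110_000),
        width=st.integers(1, 60_000),
    )
    def test_indexed_query_equals_scan_oracle(self, scored_track, chrom, start,
                                              width):
        """Random intervals: the index and the naive scan agree exactly."""
        iv = GenomicInterval(chrom, start, start + width)
        assert _key(query_track(scored_track.indexed_path, iv)) == _key(
            scan_track_linear(scored_track.plain_path, iv))


class TestTrackSet:
    def test_metadata_shape_enforced(self):
        with pytest.raises(ValueError):
            BindingTrackSet(files=["a", "b"],
                            metadata=pd.DataFrame({"Mtag": ["M1"], "HGNC": ["A"]}))
        with pytest.raises(SchemaError):
            BindingTrackSet(files=["a"], metadata=pd.DataFrame({"Mtag": ["M1"]}))

    def test_sixteen_file_set_structure(self, track_set):
        tracks, truths, catalog = track_set
        assert len(tracks) == 16
        iv = GenomicInterval("chr17", 38_000_000, 38_020_000)
        out = reduce_by_file(tracks, [iv])
        assert list(out) == [str(f) for f in tracks.files]

    def test_reduce_by_file_equals_per_cell_queries(self, track_set):
        tracks, truths, _ = track_set
        sub = BindingTrackSet(files=tracks.files[:3],
                              metadata=tracks.metadata.iloc[:3])
        ivs = [
            GenomicInterval("chr17", 38_000_000, 38_030_000),
            GenomicInterval("chr1", 38_050_000, 38_070_000),
        ]
        out = reduce_by_file(sub, ivs)
        assert all(len(v) == 2 for v in out.values())
        for f, cells in out.items():
            for iv, cell in zip(ivs, cells):
                assert _key(cell) == _key(query_track(f, iv))

    def test_map_fn_applied_and_errors_name_file(self, track_set):
        tracks, _, _ = track_set
        sub = BindingTrackSet(files=tracks.files[:1],
                              metadata=tracks.metadata.iloc[:1])
        iv = GenomicInterval("chr17", 38_000_000, 38_100_000)
        out = reduce_by_file(sub, [iv], map_fn=len)
        assert out[str(sub.files[0])][0] == len(query_track(sub.files[0], iv))
        with pytest.raises(RuntimeError, match=str(sub.files[0])):
            reduce_by_file(sub, [iv], map_fn=lambda h: 1 / 0)


class TestAnnotateFamily:
    def test_first_occurrence_wins(self):
        tracks = BindingTrackSet(
            files=["f"], metadata=pd.DataFrame({"Mtag": ["M1"], "HGNC": ["TP53"]}))
        cat = TFCatalog("c", ["a", "b"], pd.DataFrame(
            {"HGNC": ["TP53", "TP53"], "Family_Name": ["p53", "p53-alt"]}))
        meta = annotate_family(tracks, cat)
        assert meta["Family_Name"].tolist() == ["p53"]

    def test_unmatched_symbol_missing(self):
        tracks = BindingTrackSet(
            files=["f"], metadata=pd.DataFrame({"Mtag": ["M1"], "HGNC": ["NOPE"]}))
        cat = TFCatalog("c", ["a"], pd.DataFrame(
            {"HGNC": ["TP53"], "Family_Name": ["p53"]}))
        assert annotate_family(tracks, cat)["Family_Name"].isna().all()

    def test_planted_families_recovered(self, track_set):
        tracks, _, catalog = track_set
        meta = annotate_family(tracks, catalog)
        expected = dict(zip(catalog.hgnc_map["HGNC"],
                            catalog.hgnc_map["Family_Name"]))
        for _, row in meta.iterrows():
            assert row["Family_Name"] == expected[row["HGNC"]]

    def test_harvest_table_columns(self, track_set):
        tracks, _, catalog = track_set
        iv = GenomicInterval("chr17", 38_000_000, 38_040_000)
        table = harvest_scores(tracks, iv, catalog=catalog)
        assert list(table.columns) == [
            "chrom", "start", "end", "motif_id", "neglog10p", "HGNC",
            "Family_Name"]
        assert len(table) > 0
        assert (table["neglog10p"] >= 0).all()


class TestNarrowPeak:
    def test_single_line_parse(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr17\t100\t200\tp1\t0\t.\t5.5\t-1\t-1\t50\n")
        peaks = read_narrowpeak(p)
        assert peaks[0].interval == GenomicInterval("chr17", 100, 200)
        assert peaks[0].summit == 50

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("")
        assert read_narrowpeak(p) == []

    def test_wrong_column_count_cites_line(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr17\t100\t200\n")
        with pytest.raises(FormatError, match=":1:"):
            read_narrowpeak(p)

    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        peaks = [
            Peak(GenomicInterval("chr2", int(s), int(s) + 150), f"p{i}", 100, ".",
                 float(f"{rng.uniform(1, 9):.4f}"), -1.0, -1.0, 75)
            for i, s in enumerate(rng.integers(0, 10**6, size=25))
        ]
        path = write_narrowpeak(peaks, tmp_path / "rt.narrowPeak")
        assert read_narrowpeak(path) == peaks


class TestPeaksInRegion:
    CLUSTER = GenomicInterval("chr17", 38_077_000, 38_084_000)

    def test_planted_cluster_counts(self, encode_fixture):
        registry, truth = encode_fixture
        groups = peaks_in_region(registry, "CEBPB", self.CLUSTER)
        assert len(groups) == 4
        for g in groups:
            assert len(g.peaks) == truth[g.cell_line]
            assert g.available

    def test_unused_chromosome_gives_empty_groups(self, encode_fixture):
        registry, _ = encode_fixture
        groups = peaks_in_region(registry, "CEBPB",
                                 GenomicInterval("chr21", 1, 10**6))
        assert len(groups) == 4 and all(not g.peaks for g in groups)

    def test_cell_line_filter(self, encode_fixture):
        registry, _ = encode_fixture
        groups = peaks_in_region(registry, "CEBPB", self.CLUSTER,
                                 cell_lines=["HepG2"])
        assert len(groups) == 1 and groups[0].cell_line == "HepG2"

    def test_absent_tf_warns_empty(self, encode_fixture):
        registry, _ = encode_fixture
        with pytest.warns(UserWarning):
            assert peaks_in_region(registry, "NOSUCH", self.CLUSTER) == []

    def test_missing_file_reported_not_dropped(self, encode_fixture, tmp_path):
        registry, _ = encode_fixture
        table = registry.table.copy()
        table.loc[table.index[0], "peak_file"] = str(tmp_path / "gone.narrowPeak")
        groups = peaks_in_region(EncodeRegistry(table), "CEBPB", self.CLUSTER)
        assert len(groups) == 4
        assert sum(not g.available for g in groups) == 1

    def test_counts_agree_with_bedtools(self, encode_fixture, tmp_path):
        """Independent oracle: bedtools intersect on the same files."""
        if shutil.which("bedtools") is None:
            pytest.skip("bedtools unavailable")
        registry, _ = encode_fixture
        q = tmp_path / "q.bed"
        q.write_text(f"{self.CLUSTER.chrom}\t{self.CLUSTER.start}\t{self.CLUSTER.end}\n")
        for g in peaks_in_region(registry, "CEBPB", self.CLUSTER):
            res = subprocess.run(
                ["bedtools", "intersect", "-u", "-a", g.peak_file, "-b", str(q)],
                capture_output=True, text=True, check=True)
            n_bedtools = len([l for l in res.stdout.splitlines() if l.strip()])
            assert len(g.peaks) == n_bedtools


class TestRegistry:
    def test_duplicate_rows_rejected(self):
        t = pd.DataFrame({"cell_line": ["K562"] * 2, "tf_hgnc": ["MAX"] * 2,
                          "peak_file": ["f"] * 2})
        with pytest.raises(ValueError):
            EncodeRegistry(t)

    def test_missing_column_rejected(self):
        with pytest.raises(SchemaError):
            EncodeRegistry(pd.DataFrame({"cell_line": ["K562"]}))
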