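"""Interval model, locus parsing and coverage arithmetic.

The coverage operations are checked against a per-base boolean-array
oracle on random genomes, and the published coordinate tables are used as
known-answer inputs.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancercnv import (
    FeatureSet,
    GenomeAssembly,
    Interval,
    LocusParseError,
    base_coverage,
    feature_coverage,
    merge,
    overlaps,
    parse_locus,
    read_bed,
    read_feature_table,
)
from enhancercnv.datasets import load_cnp_overlaps, load_dgv_indel_overlaps

from conftest import brute_force_masks, random_feature_set


class TestParseLocus:
    @pytest.mark.parametrize(
        "text,chrom,start,end",
        [
            # unicode ratio separator and en dash, as printed in browser strings
            ("chr16∶22684122–22685282", "chr16", 22684121, 22685282),
            ("chr16:22684122-22685282", "chr16", 22684121, 22685282),
            # thousands commas
            ("chr12:16,610,045–16,611,936", "chr12", 16610044, 16611936),
            ("chr9:159657-160780", "chr9", 159656, 160780),
        ],
    )
    def test_printed_dialects(self, text, chrom, start, end):
        iv = parse_locus(text)
        assert (iv.chrom, iv.start, iv.end) == (chrom, start, end)

    def test_printed_length_is_inclusive(self):
        # 1-based inclusive span 22684122..22685282 covers 1161 bases
        assert parse_locus("chr16:22684122-22685282").length == 1161

    @pytest.mark.parametrize(
        "bad",
        ["chr16:100-50", "chr16", "16:abc-200", "chr1:0-10", ":5-10"],
    )
    def test_malformed_strings_raise(self, bad):
        with pytest.raises(LocusParseError):
            parse_locus(bad)

    def test_unknown_chromosome_with_assembly(self, toy_assembly):
        with pytest.raises(LocusParseError, match="chrUn"):
            parse_locus("chrUn:5-10", assembly=toy_assembly)
        with pytest.raises(LocusParseError):
            parse_locus("chr1:900-2000", assembly=toy_assembly)

    @given(
        start=st.integers(min_value=1, max_value=10**8),
        length=st.integers(min_value=1, max_value=10**6),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, start, length):
        text = f"chr7:{start}-{start + length - 1}"
        iv = parse_locus(text)
        assert iv.to_locus_string() == text
        assert iv.length == length


class TestOverlaps:
    def test_published_enhancer_in_cnp(self):
        enh = parse_locus("chr16:22684122-22685282")
        cnp = parse_locus("chr16:22557932-22704521")
        assert overlaps(enh, cnp)

    def test_adjacency_is_not_overlap(self):
        a = parse_locus("chr1:1-100")
        b = parse_locus("chr1:101-200")
        assert not overlaps(a, b)

    def test_different_chromosomes(self):
        a = Interval("chr1", 0, 100)
        b = Interval("chr2", 0, 100)
        assert not overlaps(a, b)


class TestMerge:
    def test_overlapping_pair(self, toy_assembly):
        fs = FeatureSet([Interval("chr1", 0, 10), Interval("chr1", 5, 15)], toy_assembly)
        merged = merge(fs)
        assert [(f.start, f.end) for f in merged] == [(0, 15)]

    def test_disjoint_identity(self, toy_assembly):
        fs = FeatureSet([Interval("chr1", 0, 10), Interval("chr1", 20, 30)], toy_assembly)
        assert [(f.start, f.end) for f in merge(fs)] == [(0, 10), (20, 30)]

    def test_book_ended_intervals_are_joined(self, toy_assembly):
        fs = FeatureSet([Interval("chr1", 0, 5), Interval("chr1", 5, 9)], toy_assembly)
        assert [(f.start, f.end) for f in merge(fs)] == [(0, 9)]

    def test_published_indel_cluster_union(self, hg19):
        # the four overlapping Indels within enhancer hs1592 merge to two
        # blocks; union checked against the per-base oracle
        _, indels = load_dgv_indel_overlaps(hg19)
        cluster = FeatureSet(
            [f for f in indels if f.chrom == "chr20"], assembly=hg19, kind="indel"
        )
        assert len(cluster) == 4
        merged = merge(cluster)
        starts = np.array([f.start for f in cluster])
        ends = np.array([f.end for f in cluster])
        lo, hi = starts.min(), ends.max()
        mask = np.zeros(hi - lo, dtype=bool)
        for s, e in zip(starts, ends):
            mask[s - lo:e - lo] = True
        assert merged.merged_bases() == int(mask.sum())
        assert (merged[0].start, merged[-1].end) == (39462400, 39463626)

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(42)
        asm = GenomeAssembly("g", (("chr1", 2000),))
        fs = random_feature_set(rng, asm, 40, max_len=100)
        once = merge(fs)
        twice = merge(once)
        assert [(f.start, f.end) for f in once] == [(f.start, f.end) for f in twice]
        shuffled = FeatureSet(
            [fs[i] for i in rng.permutation(len(fs))], assembly=asm
        )
        assert [(f.start, f.end) for f in merge(shuffled)] == [
            (f.start, f.end) for f in once
        ]


class TestCoverage:
    def test_cnp_table_feature_coverage(self, hg19):
        enhancers, cnps = load_cnp_overlaps(hg19)
        fc = feature_coverage(enhancers, cnps)
        assert fc.count == 3
        assert fc.hit_ids == ["hs98", "hs628", "hs1108"]

    def test_indel_base_coverage_hs855(self, hg19):
        # Indel chr11:31989283-31989466 covers 184 of the 850 bases of hs855
        enh = FeatureSet([parse_locus("chr11:31989173-31990022", id="hs855")], hg19)
        indel = FeatureSet([parse_locus("chr11:31989283-31989466")], hg19)
        bc = base_coverage(enh, indel)
        assert (bc.covered_bases, bc.total_bases) == (184, 850)
        assert bc.fraction == pytest.approx(184 / 850)

    def test_identity_and_empty_cover(self, toy_assembly):
        fs = FeatureSet([Interval("chr1", 10, 60), Interval("chr2", 0, 30)], toy_assembly)
        assert base_coverage(fs, fs).fraction == 1.0
        empty = FeatureSet([], toy_assembly)
        assert feature_coverage(fs, empty).count == 0
        assert base_coverage(fs, empty).fraction == 0.0

    def test_cover_on_other_chromosome(self, toy_assembly):
        targets = FeatureSet([Interval("chr1", 10, 60)], toy_assembly)
        cover = FeatureSet([Interval("chr2", 10, 60)], toy_assembly)
        assert base_coverage(targets, cover).fraction == 0.0

    def test_assembly_mismatch_raises(self, toy_assembly, hg19):
        a = FeatureSet([Interval("chr1", 0, 10)], toy_assembly)
        b = FeatureSet([Interval("chr1", 0, 10)], hg19)
        with pytest.raises(ValueError, match="assembly mismatch"):
            feature_coverage(a, b)
        with pytest.raises(ValueError, match="assembly mismatch"):
            base_coverage(a, b)

    def test_duplicate_cover_counts_target_once(self, toy_assembly):
        targets = FeatureSet([Interval("chr1", 10, 60, id="t")], toy_assembly)
        cover = FeatureSet(
            [Interval("chr1", 0, 30), Interval("chr1", 20, 70)], toy_assembly
        )
        fc = feature_coverage(targets, cover)
        assert fc.count == 1
        assert len(fc.hits) == 2  # both pairs recorded

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_per_base_oracle(self, seed):
        """merge/base_coverage/feature_coverage equal the boolean-array oracle."""
        rng = np.random.default_rng(seed)
        asm = GenomeAssembly("g", (("chr1", 3000), ("chr2", 1500)))
        targets = random_feature_set(rng, asm, 25, max_len=120)
        cover = random_feature_set(rng, asm, 25, max_len=120)
        cover_mask = brute_force_masks(cover, asm)
        # merge
        assert merge(cover).merged_bases() == sum(int(m.sum()) for m in cover_mask.values())
        # base coverage
        bc = base_coverage(targets, cover)
        expect_covered = sum(
            int(cover_mask[f.chrom][f.start:f.end].sum()) for f in targets
        )
        assert bc.covered_bases == expect_covered
        assert bc.total_bases == targets.total_bases
        # feature coverage
        fc = feature_coverage(targets, cover)
        expect_count = sum(
            bool(cover_mask[f.chrom][f.start:f.end].any()) for f in targets
        )
        assert fc.count == expect_count
        assert fc.count <= len(targets)
        assert 0.0 <= bc.fraction <= 1.0

    def test_base_coverage_invariant_under_premerge(self):
        rng = np.random.default_rng(7)
        asm = GenomeAssembly("g", (("chr1", 2000),))
        targets = random_feature_set(rng, asm, 15, max_len=80)
        cover = random_feature_set(rng, asm, 30, max_len=80)
        assert base_coverage(targets, cover).covered_bases == base_coverage(
            targets, merge(cover)
        ).covered_bases


class TestFileIO:
    def test_read_feature_table_with_locus_column(self, tmp_path, hg19):
        path = tmp_path / "t.tsv"
        path.write_text(
            "id\tlocus\tgenes\nhs1\tchr1:101-200\tA-B\nhs2\tchr2:51-80\tC\n"
        )
        fs = read_feature_table(path, {"locus": "locus", "id": "id"}, assembly=hg19)
        assert len(fs) == 2
        assert fs[0].start == 100 and fs[0].end == 200
        assert fs[0].attrs["genes"] == "A-B"

    def test_missing_column_names_file(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(LocusParseError, match="missing column"):
            read_feature_table(path, {"locus": "locus"})

    def test_bad_row_reports_line_number(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("locus\nchr1:100-200\nchr1:300-250\n")
        with pytest.raises(LocusParseError, match="line 3"):
            read_feature_table(path, {"locus": "locus"})

    def test_empty_table(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("locus\tid\n")
        assert len(read_feature_table(path)) == 0

    def test_bed_is_half_open_passthrough(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t0\t100\tx\n")
        fs = read_bed(path)
        assert (fs[0].start, fs[0].end, fs[0].id) == (0, 100, "x")

    def test_bed_against_bedtools_merge(self, tmp_path, toy_assembly):
        """Cross-check merge against bedtools on a random BED."""
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        rng = np.random.default_rng(5)
        fs = random_feature_set(rng, toy_assembly, 30, max_len=60)
        bed = tmp_path / "in.bed"
        with bed.open("w") as fh:
            for f in sorted(fs, key=lambda f: (f.chrom, f.start)):
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
        out = subprocess.run(
            ["bedtools", "merge", "-i", str(bed)], capture_output=True, text=True, check=True
        ).stdout
        bedtools_intervals = [
            (l.split("\t")[0], int(l.split("\t")[1]), int(l.split("\t")[2]))
            for l in out.strip().splitlines()
        ]
        ours = [(f.chrom, f.start, f.end) for f in merge(fs)]
        # bedtools merges book-ended intervals by default; compare unions
        masks_ours = brute_force_masks(merge(fs), toy_assembly)
        masks_bt = {c: np.zeros(l, dtype=bool) for c, l in toy_assembly.chromosomes}
        for c, s, e in bedtools_intervals:
            masks_bt[c][s:e] = True
        for c in masks_ours:
            assert np.array_equal(masks_ours[c], masks_bt[c])
        assert len(ours) >= len(bedtools_intervals)
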