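"""Scan engine: CIGAR projection, quality filtering, locations, target mode."""

import re

import pysam
import pytest

from pepscan.quantify import aggregate
from pepscan.scan import (
    UNMAPPED,
    GenomicLocation,
    PeptideSet,
    ScanConfig,
    build_automaton,
    count_in_region,
    project_span,
    scan_records,
)
from pepscan.simulate import FixtureSpec, Planting, build_fixture

from _bruteforce import pairs_project

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
)


def make_read(pos=100, cigar="75M", seq_len=None, name="r1"):
    if seq_len is None:
        seq_len = sum(
            int(n)
            for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
            if op in "MIS=X"
        )
    a = pysam.AlignedSegment(header=HEADER)
    a.query_name = name
    a.query_sequence = "A" * seq_len
    a.flag = 0
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigarstring = cigar
    a.query_qualities = [40] * seq_len
    return a


class TestProjectSpan:
    def test_plain_match(self):
        loc = project_span(make_read(100, "75M"), (12, 39), "+")
        assert str(loc) == "chr1:113-139"
        assert loc.blocks == ((112, 139),)
        assert loc.span_length == 27

    def test_spliced_match_two_blocks(self):
        loc = project_span(make_read(100, "20M100N55M"), (12, 39), "+")
        assert str(loc) == "chr1:113-120|221-239"
        assert [e - s for s, e in loc.blocks] == [8, 19]

    def test_span_over_soft_clip_is_unmapped(self):
        loc = project_span(make_read(100, "5S70M"), (2, 29), "+")
        assert loc.is_unmapped

    def test_span_over_insertion_is_unmapped(self):
        loc = project_span(make_read(100, "20M3I52M"), (12, 39), "+")
        assert loc.is_unmapped

    def test_span_over_deletion_is_unmapped(self):
        loc = project_span(make_read(100, "20M2D55M"), (12, 39), "+")
        assert loc.is_unmapped

    def test_deletion_outside_span_is_harmless(self):
        loc = project_span(make_read(100, "50M2D25M"), (12, 39), "+")
        assert loc.blocks == ((112, 139),)

    def test_agrees_with_aligned_pairs_oracle(self):
        cases = [
            (100, "75M", (0, 27)),
            (100, "20M100N55M", (12, 39)),
            (100, "10M50N10M50N55M", (3, 30)),
            (100, "5S70M", (2, 29)),
            (100, "20M3I52M", (12, 39)),
            (100, "20M2D55M", (12, 39)),
            (100, "50M2D25M", (12, 39)),
            (200, "30M1000N45M", (27, 54)),
        ]
        for pos, cigar, span in cases:
            rec = make_read(pos, cigar)
            assert project_span(rec, span, "+") == pairs_project(rec, *span, "+")


class TestPeptideSet:
    def test_il_duplicates_merged_ids_preserved(self):
        peps = PeptideSet(
            [("p1", "SILKGETAW"), ("p2", "SLLKGETAW")], il_equivalent=True
        )
        assert len(peps) == 1
        assert peps.ids[0] == ("p1", "p2")

    def test_length_and_alphabet_validation(self):
        with pytest.raises(ValueError):
            PeptideSet([("p", "SHORT")])  # length 5 < 7
        with pytest.raises(ValueError):
            PeptideSet([("p", "PEPTIDEX1")])
        with pytest.raises(ValueError):
            PeptideSet([])


@pytest.fixture(scope="module")
def planted(tmp_path_factory):
    spec = FixtureSpec(
        seed=3,
        background_reads=60,
        plantings=(
            Planting("MAKWTEDHC", "IGR", copies=3),
            Planting("WHTECDKRA", "IGR", copies=2, quality=20),  # filtered
            Planting("CEDWHAKRT", "unmapped", copies=2),
        ),
    )
    return build_fixture(spec, tmp_path_factory.mktemp("planted"))


class TestScanRecords:
    def test_planted_counts_recovered(self, planted):
        peps = PeptideSet(["MAKWTEDHC", "WHTECDKRA", "CEDWHAKRT"])
        res = scan_records(str(planted.bam), build_automaton(peps), peps)
        assert res.total_records == planted.denominator
        by_pep = {}
        for m in res.matches:
            by_pep.setdefault(peps.keys[m.entry], []).append(m)
        assert len(by_pep["MAKWTEDHC"]) == 3
        assert all(not m.location.is_unmapped for m in by_pep["MAKWTEDHC"])
        assert "WHTECDKRA" not in by_pep  # Q20 27-mer span: p_err ≈ 0.237 > 0.05
        assert len(by_pep["CEDWHAKRT"]) == 2
        assert all(m.location is UNMAPPED or m.location.is_unmapped
                   for m in by_pep["CEDWHAKRT"])

    def test_mapped_blocks_sum_to_span_length(self, default_fixture):
        truth = default_fixture.truth
        peps = PeptideSet(sorted(truth["peptide"]))
        res = scan_records(str(default_fixture.bam), build_automaton(peps), peps)
        for m in res.matches:
            if not m.location.is_unmapped:
                assert m.location.span_length == 3 * len(peps.keys[m.entry])

    def test_fastq_source_counts_match_bam_totals(self, planted):
        peps = PeptideSet(["MAKWTEDHC", "CEDWHAKRT"])
        bam_res = scan_records(str(planted.bam), build_automaton(peps), peps)
        fq_res = scan_records(str(planted.fastq), build_automaton(peps), peps)
        assert fq_res.total_records == bam_res.total_records
        for entry in range(len(peps)):
            n_bam = sum(1 for m in bam_res.matches if m.entry == entry)
            n_fq = sum(1 for m in fq_res.matches if m.entry == entry)
            assert n_fq == n_bam
        assert all(m.location.is_unmapped for m in fq_res.matches)

    def test_raising_threshold_recovers_low_quality_matches(self, planted):
        peps = PeptideSet(["WHTECDKRA"])
        cfg = ScanConfig(error_threshold=0.5)
        res = scan_records(str(planted.bam), build_automaton(peps), peps, cfg)
        assert len(res.matches) == 2


class TestTargetMode:
    def test_counts_match_scan_at_truth_locus(self, planted):
        row = planted.truth[planted.truth.peptide == "MAKWTEDHC"].iloc[0]
        loc = GenomicLocation.parse(row.location, strand=row.strand)
        n, rphm = count_in_region(str(planted.bam), "MAKWTEDHC", loc)
        assert n == 3
        assert rphm == pytest.approx(3 / planted.denominator * 1e8)

    def test_other_locus_counts_zero(self, planted):
        other = GenomicLocation("chr1", "+", ((5000, 5027),))
        n, _ = count_in_region(str(planted.bam), "MAKWTEDHC", other)
        assert n == 0

    def test_unknown_chromosome_rejected(self, planted):
        bad = GenomicLocation("chr99", "+", ((100, 127),))
        with pytest.raises(ValueError):
            count_in_region(str(planted.bam), "MAKWTEDHC", bad)


def test_thread_counts_do_not_change_results(planted):
    peps = PeptideSet(["MAKWTEDHC", "CEDWHAKRT"])
    aut = build_automaton(peps)
    results = []
    for threads in (1, 2, 8):
        res = scan_records(str(planted.bam), aut, peps,
                           ScanConfig(threads=threads, batch_size=16))
        lc, summ = aggregate(res.matches, res.total_records, peps)
        results.append((res.total_records, lc, summ))
    assert results[0] == results[1] == results[2]
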