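"""Deterministic synthetic fixtures: genome, gene models, reads, truth.

The generator emits a small random reference genome, a GENCODE-dialect GTF
with gene models designed to trigger every annotation category, and a
coordinate-sorted indexed BAM (plus FASTQ) whose reads carry planted
peptide-coding sequences with known copy numbers. A truth table records,
for every planting, the exact location, the planted read count, the count
expected after quality filtering, and the expected annotation category —
so the scan engine, quantifier and annotator can all be verified exactly.

Exactness is enforced by construction: after planting, the whole genome is
six-frame translated and scanned for the query peptides, and every emitted
read is screened so that background reads contain no query peptide in any
frame and planted reads contain exactly their own peptide once.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .automaton import AhoCorasick
from .quantify import RPHM_SCALE
from .scan import UNMAPPED, GenomicLocation
from .seqcore import (
    STANDARD_CODE,
    collapse_il,
    reverse_complement,
    span_error_probability,
    translate,
)

__all__ = [
    "Planting",
    "FixtureSpec",
    "Reference",
    "Fixture",
    "GenerationError",
    "make_reference",
    "simulate_reads",
    "build_fixture",
    "default_spec",
]

_NT = np.frombuffer(b"ACGT", dtype="S1")

# Gene-model layout on chr1 (0-based half-open). GENEA is a 4-exon coding
# gene on '+', GENEB a 2-exon lncRNA on '+', GENEC a single-exon coding
# gene on '-'. chr2 and later chromosomes carry no genes.
_GENEA_EXONS = [(1000, 1300), (2000, 2300), (3000, 3300), (4000, 4300)]
_GENEA_CDS = [(1100, 1300), (2000, 2300), (3000, 3300), (4000, 4100)]
_GENEB_EXONS = [(6000, 6300), (6500, 6800)]
_GENEC_EXON = (8000, 9000)
_GENEC_CDS = (8100, 8898)
_MIN_CHR1 = 9500


class GenerationError(RuntimeError):
    """Raised when a fixture cannot be generated without collisions."""


@dataclass(frozen=True)
class Planting:
    """One planted peptide occurrence.

    ``category`` selects the designed locus: an annotation category
    (``IF``, ``OOF``, ``UTR``, ``ncRNA``, ``IR``, ``asRNA``, ``ES``,
    ``ASS`` on chr1's gene models, ``IGR`` in a gene-free region) or
    ``unmapped`` for reads carrying the coding sequence but no alignment.
    ``quality`` is the uniform Phred score of the planted reads; the
    expected post-filter count follows from it and the error threshold.
    """

    peptide: str
    category: str = "IGR"
    copies: int = 4
    strand: str = "+"
    quality: int = 40
    chrom: Optional[str] = None  # generic (IGR) plantings only


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    chrom_sizes: tuple[tuple[str, int], ...] = (("chr1", 12000), ("chr2", 8000))
    read_length: int = 76
    background_reads: int = 200
    background_quality: int = 35
    plantings: tuple[Planting, ...] = ()
    il_equivalent: bool = False
    error_threshold: float = 0.05
    odd_cigar_reads: int = 12  # background reads exercising S/D/N CIGARs


@dataclass
class PlantedLocus:
    planting: Planting
    location: GenomicLocation  # UNMAPPED for unmapped plantings
    coding_nt: str  # nucleotides as they read along the peptide (5'->3')


@dataclass
class Reference:
    genome: dict[str, str]
    gtf_text: str
    loci: list[PlantedLocus]
    spec: FixtureSpec


@dataclass
class Fixture:
    """Paths and ground truth of one generated dataset."""

    fasta: Path
    gtf: Path
    bam: Path
    fastq: Path
    truth: pd.DataFrame
    denominator: int
    reference: Reference


def default_spec(seed: int = 0) -> FixtureSpec:
    """A compact fixture touching all nine annotation categories,
    a spliced location, an unmapped pool and a quality-filtered planting."""
    return FixtureSpec(
        seed=seed,
        plantings=(
            Planting("MLLTEDVKW", "IF", copies=4),
            Planting("KTWDNAYEH", "OOF", copies=3),
            Planting("RQSPHTEVW", "UTR", copies=3),
            Planting("YHACNDTEK", "ncRNA", copies=3),
            Planting("WDDCMRHGY", "IR", copies=3),
            Planting("EYKHQCNMR", "asRNA", copies=3),
            Planting("HNCWTYEDA", "ES", copies=3),
            Planting("CAYHRQWEN", "ASS", copies=3),
            Planting("DHTENKYAW", "IGR", copies=4),
            Planting("MGWHEDCRK", "IF", strand="-", copies=3),
            Planting("NEYAWTHCK", "unmapped", copies=2),
            Planting("QWHYDCENR", "IGR", copies=3, quality=20),  # filtered out
        ),
    )


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise GenerationError(msg)


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """A random coding sequence for ``peptide`` under the standard code."""
    synonyms: dict[str, list[str]] = {}
    for codon, aa in STANDARD_CODE.codon_to_aa.items():
        synonyms.setdefault(aa, []).append(codon)
    for aa in synonyms:
        synonyms[aa].sort()
    return "".join(
        synonyms[aa][rng.integers(0, len(synonyms[aa]))] for aa in peptide
    )


class _SlotAllocator:
    """Deterministic, collision-checked locus assignment."""

    def __init__(self, spec: FixtureSpec) -> None:
        self.spec = spec
        self.sizes = dict(spec.chrom_sizes)
        self.counters: dict[str, int] = {}
        self.reserved: dict[str, list[tuple[int, int]]] = {}
        free = [c for c in self.sizes if c != "chr1"]
        _require(bool(free), "need at least one gene-free chromosome for IGR loci")
        self.free_chroms = free
        self.free_cursor = {c: 500 for c in free}

    def _reserve(self, chrom: str, start: int, end: int) -> None:
        for s, e in self.reserved.get(chrom, []):
            if start < e and s < end:
                raise GenerationError(
                    f"planted loci collide on {chrom}: [{start},{end}) vs [{s},{e})"
                )
        self.reserved.setdefault(chrom, []).append((start, end))

    def _slot(self, category: str, base: int, step: int, limit: int) -> int:
        k = self.counters.get(category, 0)
        self.counters[category] = k + 1
        pos = base + k * step
        _require(pos < limit, f"too many {category} plantings for the gene model")
        return pos

    def _phase_adjust(self, s: int, want_mod: int) -> int:
        while s % 3 != want_mod:
            s += 1
        return s

    def allocate(self, planting: Planting, span_nt: int) -> GenomicLocation:
        cat = planting.category
        R = self.spec.read_length
        if cat == "unmapped":
            return UNMAPPED
        if cat == "IGR" or cat not in (
            "IF", "OOF", "UTR", "ncRNA", "IR", "asRNA", "ES", "ASS",
        ):
            _require(cat == "IGR", f"unknown planting category {cat!r}")
            chrom = planting.chrom or self.free_chroms[
                self.counters.get("_igr_rr", 0) % len(self.free_chroms)
            ]
            self.counters["_igr_rr"] = self.counters.get("_igr_rr", 0) + 1
            start = self.free_cursor[chrom]
            spacing = R + 50
            _require(
                start + span_nt + R < self.sizes[chrom],
                f"chromosome {chrom} too small for all generic plantings",
            )
            self.free_cursor[chrom] = start + spacing
            self._reserve(chrom, start, start + span_nt)
            return GenomicLocation(chrom, planting.strand,
                                   ((start, start + span_nt),))
        _require(self.sizes.get("chr1", 0) >= _MIN_CHR1,
                 "chr1 must be at least 9500 bp for the gene-model layout")
        if cat == "IF" and planting.strand == "-":
            s = self._phase_adjust(self._slot("IF-", 8400, 80, 8898 - span_nt), 0)
            loc = (s, s + span_nt)
        elif cat == "IF":
            # GENEA exon 2; coding phase 0 requires start % 3 == 0
            s = self._phase_adjust(self._slot("IF", 2010, 80, 2300 - span_nt), 0)
            loc = (s, s + span_nt)
        elif cat == "OOF":
            # GENEA exon 3; start % 3 == 0 gives coding phase 2 (out of frame)
            s = self._phase_adjust(self._slot("OOF", 3010, 80, 3300 - span_nt), 0)
            loc = (s, s + span_nt)
        elif cat == "UTR":
            k = self.counters.get("UTR", 0)
            self.counters["UTR"] = k + 1
            _require(k < 2, "at most two UTR plantings supported")
            s = 1005 if k == 0 else 4110
            _require(span_nt <= 90, "UTR planting longer than the UTR")
            loc = (s, s + span_nt)
        elif cat == "ncRNA":
            s = self._slot("ncRNA", 6050, 80, 6300 - span_nt)
            loc = (s, s + span_nt)
        elif cat == "IR":
            s = self._slot("IR", 1400, 80, 1990 - span_nt)
            loc = (s, s + span_nt)
        elif cat == "asRNA":
            _require(planting.strand == "+", "asRNA plantings use the + strand")
            s = self._slot("asRNA", 8110, 80, 8390 - span_nt)
            loc = (s, s + span_nt)
        elif cat == "ES":
            k = self.counters.get("ES", 0)
            self.counters["ES"] = k + 1
            _require(k < 1, "one ES planting supported per fixture")
            a = span_nt // 2
            b = span_nt - a
            blocks = ((2300 - a, 2300), (4000, 4000 + b))
            for s_, e_ in blocks:
                self._reserve("chr1", s_, e_)
            return GenomicLocation("chr1", "+", blocks)
        elif cat == "ASS":
            k = self.counters.get("ASS", 0)
            self.counters["ASS"] = k + 1
            _require(k < 1, "one ASS planting supported per fixture")
            a = span_nt // 2
            b = span_nt - a
            blocks = ((2100 - a, 2100), (3050, 3050 + b))
            for s_, e_ in blocks:
                self._reserve("chr1", s_, e_)
            return GenomicLocation("chr1", "+", blocks)
        self._reserve("chr1", loc[0], loc[1])
        return GenomicLocation("chr1", planting.strand, (loc,))


def _gtf_line(chrom, source, ftype, start0, end0, strand, frame, attrs) -> str:
    attr_s = " ".join(f'{k} "{v}";' for k, v in attrs)
    return (
        f"{chrom}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t"
        f"{frame}\t{attr_s}\n"
    )


def _build_gtf() -> str:
    lines = []

    def gene(gid, chrom, strand, start, end, biotype):
        lines.append(
            _gtf_line(chrom, "sim", "gene", start, end, strand, ".",
                      [("gene_id", gid), ("gene_type", biotype)])
        )

    def tx(gid, tid, chrom, strand, start, end, biotype):
        lines.append(
            _gtf_line(chrom, "sim", "transcript", start, end, strand, ".",
                      [("gene_id", gid), ("transcript_id", tid),
                       ("transcript_type", biotype)])
        )

    def feat(ftype, gid, tid, chrom, strand, start, end, frame="."):
        lines.append(
            _gtf_line(chrom, "sim", ftype, start, end, strand, frame,
                      [("gene_id", gid), ("transcript_id", tid)])
        )

    gene("GENEA", "chr1", "+", 1000, 4300, "protein_coding")
    tx("GENEA", "TXA", "chr1", "+", 1000, 4300, "protein_coding")
    for s, e in _GENEA_EXONS:
        feat("exon", "GENEA", "TXA", "chr1", "+", s, e)
    prev = 0
    for s, e in _GENEA_CDS:
        frame = (3 - prev % 3) % 3
        feat("CDS", "GENEA", "TXA", "chr1", "+", s, e, str(frame))
        prev += e - s
    gene("GENEB", "chr1", "+", 6000, 6800, "lncRNA")
    tx("GENEB", "TXB", "chr1", "+", 6000, 6800, "lncRNA")
    for s, e in _GENEB_EXONS:
        feat("exon", "GENEB", "TXB", "chr1", "+", s, e)
    gene("GENEC", "chr1", "-", *_GENEC_EXON, "protein_coding")
    tx("GENEC", "TXC", "chr1", "-", *_GENEC_EXON, "protein_coding")
    feat("exon", "GENEC", "TXC", "chr1", "-", *_GENEC_EXON)
    feat("CDS", "GENEC", "TXC", "chr1", "-", *_GENEC_CDS, "0")
    return "".join(lines)


def _validate_peptides(spec: FixtureSpec) -> None:
    keys = []
    for p in spec.plantings:
        _require(3 * len(p.peptide) <= spec.read_length,
                 f"read length {spec.read_length} cannot span {p.peptide}")
        keys.append(collapse_il(p.peptide) if spec.il_equivalent else p.peptide)
    uniq = sorted(set(keys))
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            if a in b or b in a:
                raise GenerationError(
                    f"peptides {a!r} and {b!r} nest; truth counts would be ambiguous"
                )


def _scan_text_counts(aut: AhoCorasick, text: str) -> dict[int, int]:
    counts: dict[int, int] = {}
    for _, idx in aut.iter_matches(text):
        counts[idx] = counts.get(idx, 0) + 1
    return counts


def _genome_occurrences(
    genome: dict[str, str], aut: AhoCorasick, il: bool
) -> dict[int, int]:
    total: dict[int, int] = {}
    for seq in genome.values():
        for rev in (False, True):
            for frame in (0, 1, 2):
                text = translate(seq, frame, rev)
                if il:
                    text = collapse_il(text)
                for idx, n in _scan_text_counts(aut, text).items():
                    total[idx] = total.get(idx, 0) + n
    return total


def make_reference(spec: FixtureSpec) -> Reference:
    """Generate the genome, GTF and planted loci for ``spec``.

    Deterministic: the same spec (seed included) yields byte-identical
    FASTA and GTF content. The genome is screened so that each planted
    peptide's coding sequence occurs in six-frame translation exactly at
    its planted loci and the query peptides occur nowhere else; codon
    choices are re-randomized (bounded retries) on collision.
    """
    _validate_peptides(spec)
    keys = [collapse_il(p.peptide) if spec.il_equivalent else p.peptide
            for p in spec.plantings]
    aut = AhoCorasick(sorted(set(keys))) if keys else None
    key_index = {k: i for i, k in enumerate(aut.patterns)} if aut else {}

    for attempt in range(20):
        rng = np.random.default_rng((spec.seed, attempt))
        genome = {
            chrom: "".join(
                np.char.decode(rng.choice(_NT, size=size), "ascii")
            )
            for chrom, size in spec.chrom_sizes
        }
        alloc = _SlotAllocator(spec)
        mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
        loci: list[PlantedLocus] = []
        expected: dict[int, int] = {}
        ok = True
        for planting in spec.plantings:
            span_nt = 3 * len(planting.peptide)
            loc = alloc.allocate(planting, span_nt)
            coding = _reverse_translate(planting.peptide, rng)
            loci.append(PlantedLocus(planting, loc, coding))
            if loc.is_unmapped:
                continue
            genomic_nt = coding if loc.strand == "+" else reverse_complement(coding)
            offset = 0
            for s, e in loc.blocks:
                mutable[loc.chrom][s:e] = genomic_nt[offset:offset + (e - s)].encode()
                offset += e - s
            if len(loc.blocks) == 1:
                idx = key_index[collapse_il(planting.peptide)
                                if spec.il_equivalent else planting.peptide]
                expected[idx] = expected.get(idx, 0) + 1
        genome = {c: b.decode("ascii") for c, b in mutable.items()}
        if aut is None:
            break
        if _genome_occurrences(genome, aut, spec.il_equivalent) == expected:
            ok = True
            break
        ok = False
    else:
        raise GenerationError("could not place plantings without collisions")
    if aut is not None and not ok:  # pragma: no cover
        raise GenerationError("could not place plantings without collisions")
    return Reference(genome=genome, gtf_text=_build_gtf(), loci=loci, spec=spec)


def _read_screen_ok(
    aut: Optional[AhoCorasick], seq: str, il: bool,
    expect: Optional[int],
) -> bool:
    """True if the read's six-frame translations contain exactly the
    expected peptide (``expect`` index, once) and nothing else."""
    if aut is None:
        return True
    found: dict[int, int] = {}
    for rev in (False, True):
        for frame in (0, 1, 2):
            text = translate(seq, frame, rev)
            if il:
                text = collapse_il(text)
            for idx, n in _scan_text_counts(aut, text).items():
                found[idx] = found.get(idx, 0) + n
    if expect is None:
        return not found
    return found == {expect: 1}


def simulate_reads(spec: FixtureSpec, reference: Reference, out_dir) -> Fixture:
    """Emit FASTA, GTF, sorted+indexed BAM, gzipped FASTQ and the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng((spec.seed, 10_000))
    genome = reference.genome
    R = spec.read_length

    fasta_path = out / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    gtf_path = out / "annotation.gtf"
    gtf_path.write_text(reference.gtf_text)

    keys = [collapse_il(p.peptide) if spec.il_equivalent else p.peptide
            for p in spec.plantings]
    aut = AhoCorasick(sorted(set(keys))) if keys else None
    key_index = {k: i for i, k in enumerate(aut.patterns)} if aut else {}

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": n} for c, n in spec.chrom_sizes],
        }
    )
    ref_ids = {c: i for i, (c, _) in enumerate(spec.chrom_sizes)}
    records: list[pysam.AlignedSegment] = []

    def new_read(name, seq, qual, flag=0, chrom=None, pos=None, cigar=None):
        a = pysam.AlignedSegment(header=header)
        a.query_name = name
        a.query_sequence = seq
        a.flag = flag
        if chrom is None:
            a.reference_id = -1
            a.reference_start = -1
            a.mapping_quality = 0
        else:
            a.reference_id = ref_ids[chrom]
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
        a.query_qualities = [qual] * len(seq)
        return a

    # planted reads
    for p_idx, pl in enumerate(reference.loci):
        planting = pl.planting
        key = (collapse_il(planting.peptide) if spec.il_equivalent
               else planting.peptide)
        expect = key_index[key]
        span_nt = 3 * len(planting.peptide)
        if pl.location.is_unmapped:
            for i in range(planting.copies):
                for _ in range(50):
                    pad_total = R - span_nt
                    left = int(rng.integers(0, pad_total + 1))
                    pads = "".join(
                        np.char.decode(rng.choice(_NT, size=pad_total), "ascii")
                    )
                    seq = pads[:left] + pl.coding_nt + pads[left:]
                    if _read_screen_ok(aut, seq, spec.il_equivalent, expect):
                        break
                else:
                    raise GenerationError("unmapped read screening failed")
                records.append(
                    new_read(f"um{p_idx}_{i}", seq, planting.quality, flag=4)
                )
            continue
        loc = pl.location
        blocks = loc.blocks
        chrom_seq = genome[loc.chrom]
        for i in range(planting.copies):
            flag = 16 if i % 2 else 0
            if len(blocks) == 1:
                s, e = blocks[0]
                lo = max(0, e - R)
                hi = min(s, len(chrom_seq) - R)
                _require(lo <= hi, "read cannot span planted locus")
                g0 = lo + int((i * 7) % (hi - lo + 1))
                seq = chrom_seq[g0:g0 + R]
                rec = new_read(
                    f"pl{p_idx}_{i}", seq, planting.quality, flag=flag,
                    chrom=loc.chrom, pos=g0, cigar=f"{R}M",
                )
            else:
                (b1s, b1e), (b2s, b2e) = blocks
                pad = min(10 + 3 * i, b1s)  # deterministic tiling
                g0 = b1s - pad
                left_len = b1e - g0
                right_len = R - left_len
                _require(right_len >= b2e - b2s,
                         "read cannot span spliced planting")
                gap = b2s - b1e
                seq = chrom_seq[g0:b1e] + chrom_seq[b2s:b2s + right_len]
                rec = new_read(
                    f"pl{p_idx}_{i}", seq, planting.quality, flag=flag,
                    chrom=loc.chrom, pos=g0,
                    cigar=f"{left_len}M{gap}N{right_len}M",
                )
            if not _read_screen_ok(aut, rec.query_sequence,
                                   spec.il_equivalent, expect):
                raise GenerationError(
                    f"planted read for {planting.peptide} carries extra matches"
                )
            records.append(rec)

    # background reads, including a few with soft clips, deletions, splices
    chroms = [c for c, _ in spec.chrom_sizes]
    sizes = dict(spec.chrom_sizes)
    n_odd = min(spec.odd_cigar_reads, spec.background_reads)
    n_plain = spec.background_reads - n_odd
    bg_q = spec.background_quality

    def random_bg(i: int, maker) -> None:
        for _ in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            g0 = int(rng.integers(0, sizes[chrom] - R - 200))
            rec = maker(i, chrom, g0)
            if _read_screen_ok(aut, rec.query_sequence, spec.il_equivalent, None):
                records.append(rec)
                return
        raise GenerationError("background read screening failed repeatedly")

    for i in range(n_plain):
        random_bg(
            i,
            lambda i, chrom, g0: new_read(
                f"bg{i}", genome[chrom][g0:g0 + R], bg_q,
                chrom=chrom, pos=g0, cigar=f"{R}M",
            ),
        )
    for i in range(n_odd):
        kind = i % 3
        if kind == 0:  # soft-clipped prefix
            def maker(i, chrom, g0):
                clip = "".join(np.char.decode(rng.choice(_NT, size=10), "ascii"))
                seq = clip + genome[chrom][g0:g0 + (R - 10)]
                return new_read(f"odd{i}", seq, bg_q, chrom=chrom, pos=g0,
                                cigar=f"10S{R - 10}M")
        elif kind == 1:  # 5 bp deletion
            def maker(i, chrom, g0):
                seq = genome[chrom][g0:g0 + 30] + \
                    genome[chrom][g0 + 35:g0 + 35 + (R - 30)]
                return new_read(f"odd{i}", seq, bg_q, chrom=chrom, pos=g0,
                                cigar=f"30M5D{R - 30}M")
        else:  # 100 bp splice gap
            def maker(i, chrom, g0):
                seq = genome[chrom][g0:g0 + 20] + \
                    genome[chrom][g0 + 120:g0 + 120 + (R - 20)]
                return new_read(f"odd{i}", seq, bg_q, chrom=chrom, pos=g0,
                                cigar=f"20M100N{R - 20}M")
        random_bg(i, maker)

    # write sorted, indexed BAM and gzipped FASTQ
    unsorted = out / "reads.unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    bam_path = out / "reads.bam"
    pysam.sort("-o", str(bam_path), str(unsorted))
    os.unlink(unsorted)
    pysam.index(str(bam_path))
    fastq_path = out / "reads.fastq.gz"
    with gzip.open(fastq_path, "wt") as fq:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.query_qualities)
            fq.write(f"@{rec.query_name}\n{rec.query_sequence}\n+\n{qual}\n")

    denominator = len(records)
    truth = _truth_table(spec, reference, denominator)
    return Fixture(
        fasta=fasta_path,
        gtf=gtf_path,
        bam=bam_path,
        fastq=fastq_path,
        truth=truth,
        denominator=denominator,
        reference=reference,
    )


def _truth_table(
    spec: FixtureSpec, reference: Reference, denominator: int
) -> pd.DataFrame:
    rows = []
    for pl in reference.loci:
        planting = pl.planting
        span_nt = 3 * len(planting.peptide)
        err = span_error_probability([planting.quality] * span_nt)
        expected = planting.copies if err <= spec.error_threshold else 0
        rows.append(
            {
                "peptide": planting.peptide,
                "location": str(pl.location),
                "strand": pl.location.strand,
                "category": "" if pl.location.is_unmapped else planting.category,
                "planted_copies": planting.copies,
                "expected_count": expected,
                "expected_rphm": expected / denominator * RPHM_SCALE,
            }
        )
    return pd.DataFrame(rows)


def build_fixture(spec: FixtureSpec, out_dir) -> Fixture:
    """Convenience wrapper: reference + reads in one call."""
    return simulate_reads(spec, make_reference(spec), out_dir)


def synthetic_cohort(
    seed: int = 0,
    n_tumor: int = 10,
    n_nat: int = 10,
    n_ogtex: int = 300,
    n_mtec: int = 8,
    n_tsa: int = 50,
    n_taa: int = 50,
    n_tolerance: int = 100,
    n_broad: int = 300,
):
    """Peptide-by-sample RPHM cohort with planted prioritization labels.

    Four peptide classes with clear margins around the derived threshold:
    TSAs are expressed only in tumors; TAAs additionally appear above
    threshold in two oGTEx samples but far below their tumor maximum;
    tolerance-excluded peptides are high in NAT and mTEC; broad peptides
    are expressed in half of the oGTEx samples. TSA and tolerance peptides
    carry a low uniform normal-tissue signal (average RPHM 1), so the 1st
    percentile of per-peptide non-zero averages — the derived threshold —
    is exactly 1 and every planted margin is at least tenfold.

    Returns (tumor, nat, ogtex, mtec, peptide_meta, labels).
    """
    import pandas as pd

    from .prioritize import (
        STATUS_OGTEX,
        STATUS_TAA,
        STATUS_TOLERANCE,
        STATUS_TSA,
    )

    rng = np.random.default_rng((seed, 777))
    n = n_tsa + n_taa + n_tolerance + n_broad
    peptides = [f"PEP{i:05d}" for i in range(n)]
    labels = (
        [STATUS_TSA] * n_tsa
        + [STATUS_TAA] * n_taa
        + [STATUS_TOLERANCE] * n_tolerance
        + [STATUS_OGTEX] * n_broad
    )
    tumor = np.zeros((n, n_tumor))
    nat = np.zeros((n, n_nat))
    ogtex = np.zeros((n, n_ogtex))
    mtec = np.zeros((n, n_mtec))
    for i, label in enumerate(labels):
        tumor[i, rng.integers(0, n_tumor)] = 1000.0 + rng.uniform(0, 500)
        if label in (STATUS_TSA, STATUS_TOLERANCE):
            # below-threshold baseline in a couple of normal samples
            cols = rng.choice(n_ogtex, size=2, replace=False)
            ogtex[i, cols] = 1.0
        if label == STATUS_TAA:
            cols = rng.choice(n_ogtex, size=2, replace=False)
            ogtex[i, cols] = 100.0 + rng.uniform(0, 50)
        if label == STATUS_TOLERANCE:
            nat[i, rng.integers(0, n_nat)] = 100.0
            mtec[i, rng.integers(0, n_mtec)] = 100.0
        if label == STATUS_OGTEX:
            cols = rng.choice(n_ogtex, size=n_ogtex // 2, replace=False)
            ogtex[i, cols] = rng.uniform(50.0, 200.0, size=cols.size)

    def frame(arr, prefix):
        return pd.DataFrame(
            arr, index=peptides,
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        )

    meta = pd.DataFrame(
        {"mhc_class": "I", "length": 9}, index=pd.Index(peptides, name="peptide")
    )
    return (
        frame(tumor, "T"),
        frame(nat, "N"),
        frame(ogtex, "G"),
        frame(mtec, "M"),
        meta,
        pd.Series(labels, index=peptides, name="label"),
    )
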