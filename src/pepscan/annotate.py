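"""Annotate mode: classify peptide locations against a gene model.

Each mapped location is compared with a GTF-derived index (per-chromosome
interval trees over gene spans, with transcript/exon/CDS substructure) and
classified into one of nine categories:

* IF   — in-frame translation of an annotated coding sequence
* OOF  — within a CDS but in the wrong codon phase
* UTR  — within exons of a coding transcript, overlapping 5'/3' UTR
* ncRNA — within exons of a non-coding transcript
* IR   — overlapping an intron of a sense-strand transcript
* asRNA — overlapping gene(s) on the opposite strand only
* ES   — spliced span skipping at least one whole annotated exon
* ASS  — spliced span using an unannotated (alternative) splice site
* IGR  — no overlapping gene (intergenic)

Ambiguous overlaps yield multiple calls; empirical penalty scores
(IF = 0, ES/ASS = 15, UTR/OOF = 20, ncRNA = 30, IR = 60, asRNA = 120,
IGR = 240) rank them, lower being the more plausible origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .scan import GenomicLocation

__all__ = [
    "PENALTIES",
    "CATEGORY_ORDER",
    "AnnotationCall",
    "Transcript",
    "Gene",
    "GtfIndex",
    "build_gtf_index",
    "classify_location",
    "best_annotation",
    "annotate_table",
]

PENALTIES: dict[str, int] = {
    "IF": 0,
    "ES": 15,
    "ASS": 15,
    "UTR": 20,
    "OOF": 20,
    "ncRNA": 30,
    "IR": 60,
    "asRNA": 120,
    "IGR": 240,
}

#: Tie-break order when penalties are equal.
CATEGORY_ORDER = ["IF", "ES", "ASS", "UTR", "OOF", "ncRNA", "IR", "asRNA", "IGR"]
_ORDER_INDEX = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class AnnotationCall:
    category: str
    penalty: int
    gene_id: str
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in PENALTIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.penalty != PENALTIES[self.category]:
            raise ValueError(
                f"penalty {self.penalty} does not match table value for "
                f"{self.category}"
            )


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    cds: list[tuple[int, int]] = field(default_factory=list)
    cds_frame: int = 0  # phase of the 5'-most CDS segment

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: list[Transcript] = field(default_factory=list)


class GtfIndex:
    """Per-chromosome interval trees over gene spans with substructure."""

    def __init__(self, genes: Sequence[Gene]) -> None:
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span overlaps [start, end) (0-based half-open)."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        hits = sorted({iv.data for iv in tree.overlap(start, end)})
        return [self.genes[g] for g in hits]


def _attr(feature, *names: str) -> Optional[str]:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def build_gtf_index(gtf_path: str) -> GtfIndex:
    """Parse a GENCODE-dialect GTF into a :class:`GtfIndex`.

    Coordinates are converted from the GTF's 1-based inclusive convention
    to 0-based half-open internally.
    """
    _validate_gtf(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    genes: dict[str, Gene] = {}
    for f in db.features_of_type("gene"):
        gid = _attr(f, "gene_id")
        genes[gid] = Gene(
            gene_id=gid,
            chrom=f.seqid,
            strand=f.strand,
            start=f.start - 1,
            end=f.end,
            biotype=_attr(f, "gene_type", "gene_biotype") or "protein_coding",
        )
    transcripts: dict[str, Transcript] = {}
    for f in db.features_of_type("transcript"):
        tid = _attr(f, "transcript_id")
        gid = _attr(f, "gene_id")
        tx = Transcript(
            transcript_id=tid,
            gene_id=gid,
            strand=f.strand,
            biotype=_attr(f, "transcript_type", "transcript_biotype")
            or genes[gid].biotype,
        )
        transcripts[tid] = tx
        genes[gid].transcripts.append(tx)
    for f in db.features_of_type("exon"):
        transcripts[_attr(f, "transcript_id")].exons.append((f.start - 1, f.end))
    for f in db.features_of_type("CDS"):
        tx = transcripts[_attr(f, "transcript_id")]
        tx.cds.append((f.start - 1, f.end))
        frame = f.frame if f.frame not in (None, ".") else "0"
        # remember the phase of the 5'-most CDS segment
        if not hasattr(tx, "_cds_frames"):
            tx._cds_frames = []  # type: ignore[attr-defined]
        tx._cds_frames.append((f.start - 1, f.end, int(frame)))  # type: ignore[attr-defined]
    for tx in transcripts.values():
        tx.exons.sort()
        tx.cds.sort()
        frames = getattr(tx, "_cds_frames", None)
        if frames:
            frames.sort()
            tx.cds_frame = frames[0][2] if tx.strand == "+" else frames[-1][2]
    return GtfIndex(list(genes.values()))


def _validate_gtf(gtf_path: str) -> None:
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{lineno}: fewer than 9 GTF columns")
            ftype, attrs = fields[2], fields[8]
            if "gene_id" not in attrs:
                raise ValueError(f"{gtf_path}:{lineno}: missing gene_id attribute")
            if ftype in ("transcript", "exon", "CDS") and "transcript_id" not in attrs:
                raise ValueError(
                    f"{gtf_path}:{lineno}: missing transcript_id attribute"
                )


def _tx_coord(tx: Transcript, gpos: int) -> Optional[int]:
    """Transcript coordinate of genomic base ``gpos`` (None if intronic)."""
    if tx.strand == "+":
        offset = 0
        for s, e in tx.exons:
            if s <= gpos < e:
                return offset + (gpos - s)
            offset += e - s
        return None
    offset = 0
    for s, e in reversed(tx.exons):
        if s <= gpos < e:
            return offset + (e - 1 - gpos)
        offset += e - s
    return None


def _block_tx_interval(
    tx: Transcript, block: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """Transcript-coordinate interval of a fully exonic block, else None."""
    s, e = block
    for xs, xe in tx.exons:
        if xs <= s and e <= xe:
            a = _tx_coord(tx, s if tx.strand == "+" else e - 1)
            return (a, a + (e - s))
    return None


def _cds_tx_interval(tx: Transcript) -> Optional[tuple[int, int]]:
    if not tx.cds:
        return None
    if tx.strand == "+":
        start_g = tx.cds[0][0]
        end_g = tx.cds[-1][1] - 1
    else:
        start_g = tx.cds[-1][1] - 1
        end_g = tx.cds[0][0]
    a = _tx_coord(tx, start_g)
    b = _tx_coord(tx, end_g)
    if a is None or b is None:
        return None
    return (a + tx.cds_frame, b + 1)


def _classify_transcript(tx: Transcript, loc: GenomicLocation) -> str:
    """Category of ``loc`` with respect to one sense-strand transcript."""
    tx_blocks = [_block_tx_interval(tx, b) for b in loc.blocks]
    if any(b is None for b in tx_blocks):
        return "IR"
    # order blocks along transcript direction
    order = range(len(loc.blocks))
    if tx.strand == "-":
        order = reversed(order)
    ordered = [(loc.blocks[i], tx_blocks[i]) for i in order]
    junction_breaks = []
    for (gb1, tb1), (gb2, tb2) in zip(ordered, ordered[1:]):
        if tb1[1] != tb2[0]:
            junction_breaks.append((gb1, gb2))
    if not junction_breaks:
        span = (ordered[0][1][0], ordered[-1][1][1])
        if not tx.is_coding:
            return "ncRNA"
        return _coding_category(tx, span)
    # at least one junction deviates from the annotated splice structure
    exon_starts = {s for s, _ in tx.exons}
    exon_ends = {e for _, e in tx.exons}
    all_es = True
    for gb1, gb2 in junction_breaks:
        left, right = (gb1, gb2) if gb1[0] <= gb2[0] else (gb2, gb1)
        donor_ok = left[1] in exon_ends
        acceptor_ok = right[0] in exon_starts
        gap = (left[1], right[0])
        skips_exon = any(gap[0] <= s and e <= gap[1] for s, e in tx.exons)
        if not (donor_ok and acceptor_ok and skips_exon):
            all_es = False
    return "ES" if all_es else "ASS"


def _coding_category(tx: Transcript, span_tx: tuple[int, int]) -> str:
    cds = _cds_tx_interval(tx)
    if cds is None:
        return "ncRNA"
    if cds[0] <= span_tx[0] and span_tx[1] <= cds[1]:
        return "IF" if (span_tx[0] - cds[0]) % 3 == 0 else "OOF"
    return "UTR"


def classify_location(index: GtfIndex, loc: GenomicLocation) -> list[AnnotationCall]:
    """All annotation calls for one mapped location.

    One call per overlapping gene: for a sense-strand gene the
    lowest-penalty category over its transcripts, for an antisense gene an
    asRNA call. No overlapping gene yields a single IGR call.
    """
    if loc.is_unmapped:
        raise ValueError("cannot annotate an unmapped location")
    genes = index.overlapping(loc.chrom, loc.start, loc.end)
    # a gene must be touched by at least one block, not only by the
    # intron gap of a spliced location
    genes = [
        g
        for g in genes
        if any(s < g.end and g.start < e for s, e in loc.blocks)
    ]
    if not genes:
        return [AnnotationCall("IGR", PENALTIES["IGR"], gene_id="")]
    calls: list[AnnotationCall] = []
    for gene in genes:
        if gene.strand != loc.strand:
            calls.append(
                AnnotationCall("asRNA", PENALTIES["asRNA"], gene_id=gene.gene_id)
            )
            continue
        best: Optional[tuple[int, int, str, str]] = None
        for tx in gene.transcripts:
            cat = _classify_transcript(tx, loc)
            rank = (PENALTIES[cat], _ORDER_INDEX[cat], cat, tx.transcript_id)
            if best is None or rank < best:
                best = rank
        if best is None:  # gene without transcripts: treat span as intronic
            calls.append(AnnotationCall("IR", PENALTIES["IR"], gene_id=gene.gene_id))
        else:
            calls.append(
                AnnotationCall(
                    best[2], PENALTIES[best[2]], gene_id=gene.gene_id,
                    transcript_id=best[3],
                )
            )
    return calls


def best_annotation(calls: Sequence[AnnotationCall]) -> AnnotationCall:
    """Lowest-penalty call; ties broken by category order, then gene id."""
    if not calls:
        raise ValueError("no annotation calls")
    return min(
        calls, key=lambda c: (c.penalty, _ORDER_INDEX[c.category], c.gene_id)
    )


def annotate_table(index: GtfIndex, table: pd.DataFrame) -> pd.DataFrame:
    """Annotate a genomic-level table (adds category/penalty/gene columns).

    Rows with the unmapped location "." receive empty annotation fields.
    """
    cats, pens, gids, tids = [], [], [], []
    for _, row in table.iterrows():
        if row["location"] == ".":
            cats.append("")
            pens.append("")
            gids.append("")
            tids.append("")
            continue
        loc = GenomicLocation.parse(row["location"], strand=row["strand"])
        best = best_annotation(classify_location(index, loc))
        cats.append(best.category)
        pens.append(best.penalty)
        gids.append(best.gene_id)
        tids.append(best.transcript_id or "")
    out = table.copy()
    out["category"] = cats
    out["penalty"] = pens
    out["gene_id"] = gids
    out["transcript_id"] = tids
    return out
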