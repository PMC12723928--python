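"""Scan and target modes: match peptides against translated reads.

The scan engine streams BAM or FASTQ records, translates each eligible
record in the frames implied by the library strandedness, matches the
translations against an Aho-Corasick automaton over the query peptides,
filters matches by the aggregate sequencing-error probability of the
matched coding span, and projects surviving matches through the read's
CIGAR onto genomic coordinates. Target mode restricts the same pipeline to
reads fetched from a region of interest and counts only matches that
project exactly onto a given location.
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from .automaton import AhoCorasick
from .seqcore import (
    AMINO_ACIDS,
    collapse_il,
    frames_for,
    span_error_probability,
    translate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideSet",
    "GenomicLocation",
    "UNMAPPED",
    "MatchRecord",
    "ScanConfig",
    "ScanResult",
    "build_automaton",
    "scan_records",
    "project_span",
    "count_in_region",
]

# BAM CIGAR operation codes (SAM spec v1.6)
_CM, _CI, _CD, _CN, _CS, _CH, _CP, _CEQ, _CX = range(9)
_CONSUMES_QUERY = {_CM, _CI, _CS, _CEQ, _CX}
_CONSUMES_REF = {_CM, _CD, _CN, _CEQ, _CX}


@dataclass(frozen=True)
class GenomicLocation:
    """Stranded, possibly spliced genomic span of a peptide-coding region.

    ``blocks`` are 0-based half-open intervals in genomic order; they are
    serialized 1-based inclusive (``chrom:start-end`` with ``|`` between
    blocks of a spliced match). The unmapped location has ``chrom == "."``
    and no blocks.
    """

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.chrom == ".":
            if self.blocks:
                raise ValueError("unmapped location cannot have blocks")
        else:
            if not self.blocks:
                raise ValueError("mapped location requires blocks")
            for (s, e) in self.blocks:
                if e <= s:
                    raise ValueError(f"empty block {s}-{e}")
            for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
                if s2 < e1:
                    raise ValueError("blocks must be ordered and non-overlapping")

    @property
    def is_unmapped(self) -> bool:
        return self.chrom == "."

    @property
    def span_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def __str__(self) -> str:
        if self.is_unmapped:
            return "."
        parts = "|".join(f"{s + 1}-{e}" for s, e in self.blocks)
        return f"{self.chrom}:{parts}"

    @classmethod
    def parse(cls, text: str, strand: str = ".") -> "GenomicLocation":
        """Parse ``chrom:start-end[|start-end...]`` (1-based inclusive)."""
        if text == ".":
            return UNMAPPED
        chrom, _, rest = text.rpartition(":")
        if not chrom:
            raise ValueError(f"malformed location: {text!r}")
        blocks = []
        for part in rest.split("|"):
            s, _, e = part.partition("-")
            blocks.append((int(s.replace(",", "")) - 1, int(e.replace(",", ""))))
        return cls(chrom=chrom, strand=strand, blocks=tuple(blocks))


UNMAPPED = GenomicLocation(chrom=".", strand=".", blocks=())


class PeptideSet:
    """Query peptides with optional I/L equivalence.

    Sequences that coincide after the optional I/L collapse are merged
    into one entry; all original identifiers are preserved on the merged
    entry. Peptide lengths must fall within ``length_range``.
    """

    def __init__(
        self,
        peptides: Iterable[tuple[str, str]] | Iterable[str],
        il_equivalent: bool = False,
        length_range: tuple[int, int] = (7, 25),
    ) -> None:
        items: list[tuple[str, str]] = []
        for p in peptides:
            if isinstance(p, str):
                items.append((p, p))
            else:
                items.append((p[0], p[1]))
        if not items:
            raise ValueError("peptide set is empty")
        self.il_equivalent = il_equivalent
        self.length_range = length_range
        keys: list[str] = []
        self._key_to_entry: dict[str, int] = {}
        self.ids: list[tuple[str, ...]] = []
        self.sequences: list[str] = []
        lo, hi = length_range
        for pid, seq in items:
            seq = seq.strip().upper()
            bad = set(seq) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(
                    f"peptide {pid!r} has non-amino-acid characters: {sorted(bad)}"
                )
            if not (lo <= len(seq) <= hi):
                raise ValueError(
                    f"peptide {pid!r} length {len(seq)} outside [{lo}, {hi}]"
                )
            key = collapse_il(seq) if il_equivalent else seq
            if key in self._key_to_entry:
                idx = self._key_to_entry[key]
                if pid not in self.ids[idx]:
                    self.ids[idx] = self.ids[idx] + (pid,)
            else:
                self._key_to_entry[key] = len(keys)
                keys.append(key)
                self.ids.append((pid,))
                self.sequences.append(seq)
        self.keys = keys

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_file(cls, path: str, **kwargs) -> "PeptideSet":
        """Read peptides from plain text (one per line) or headered TSV.

        A TSV may have columns ``id`` and ``sequence`` (first two columns
        used if unnamed).
        """
        items: list[tuple[str, str]] = []
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise ValueError(f"no peptides in {path}")
        if "\t" in lines[0]:
            header = lines[0].split("\t")
            try:
                id_col = header.index("id")
                seq_col = header.index("sequence")
            except ValueError:
                id_col, seq_col = 0, 1
            for ln in lines[1:]:
                parts = ln.split("\t")
                items.append((parts[id_col], parts[seq_col]))
        else:
            for ln in lines:
                seq = ln.strip()
                items.append((seq, seq))
        return cls(items, **kwargs)


@dataclass(frozen=True)
class MatchRecord:
    """One quality-passing occurrence of a peptide in one read."""

    entry: int  # index into PeptideSet
    read_name: str
    location: GenomicLocation
    frame: int
    reverse: bool
    error_probability: float
    matched_nt: str = ""  # coding nucleotides; used to count unmapped variants


@dataclass
class ScanConfig:
    strandedness: str = "unstranded"
    error_threshold: float = 0.05
    threads: int = 1
    exclude_duplicates: bool = False
    batch_size: int = 2000


@dataclass
class ScanResult:
    matches: list[MatchRecord]
    total_records: int  # denominator for RPHM

    def __iter__(self) -> Iterator[MatchRecord]:
        return iter(self.matches)


def build_automaton(peps: PeptideSet) -> AhoCorasick:
    """Aho-Corasick automaton over the (optionally collapsed) peptide keys."""
    return AhoCorasick(peps.keys)


def project_span(
    alignment: pysam.AlignedSegment,
    read_nt_span: tuple[int, int],
    strand: str,
) -> GenomicLocation:
    """Project an interval on the stored read sequence onto the reference.

    Walks the CIGAR: M/=/X consume read and reference; D and N consume
    reference only; I and S consume read only. An N inside the span opens a
    new block (spliced match). A span overlapping any I or S segment, or
    interrupted by a D, has no codon-colinear genomic image and projects to
    the unmapped location.
    """
    qstart, qend = read_nt_span
    if alignment.is_unmapped:
        return UNMAPPED
    cigar = alignment.cigartuples
    if not cigar:
        raise ValueError(f"missing CIGAR for read {alignment.query_name}")
    qpos = 0
    rpos = alignment.reference_start
    blocks: list[list[int]] = []
    pending_split = False  # an N was seen between covered bases
    pending_broken = False  # a D was seen between covered bases
    for op, length in cigar:
        if op in (_CH, _CP):
            continue
        if op in (_CM, _CEQ, _CX):
            o_start = max(qpos, qstart)
            o_end = min(qpos + length, qend)
            if o_start < o_end:
                r_from = rpos + (o_start - qpos)
                r_to = rpos + (o_end - qpos)
                if blocks and pending_broken:
                    return UNMAPPED
                if blocks and not pending_split and blocks[-1][1] == r_from:
                    blocks[-1][1] = r_to
                else:
                    blocks.append([r_from, r_to])
                pending_split = pending_broken = False
            qpos += length
            rpos += length
        elif op in (_CI, _CS):
            if max(qpos, qstart) < min(qpos + length, qend):
                return UNMAPPED
            qpos += length
        elif op == _CD:
            if qstart < qpos < qend:
                pending_broken = True
            rpos += length
        elif op == _CN:
            if qstart < qpos < qend:
                pending_split = True
            rpos += length
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    covered = sum(e - s for s, e in blocks)
    if covered != qend - qstart:
        raise ValueError(
            f"span {read_nt_span} exceeds read length of {alignment.query_name}"
        )
    return GenomicLocation(
        chrom=alignment.reference_name,
        strand=strand,
        blocks=tuple(tuple(b) for b in blocks),
    )


@dataclass(frozen=True)
class _RecordView:
    """Fields of one sequencing record needed for matching."""

    name: str
    sequence: str
    qualities: Optional[tuple[int, ...]]
    is_mapped: bool
    is_reverse: bool
    orientation: str  # R1 / R2 / single
    segment: Optional[pysam.AlignedSegment]


def _view_bam(rec: pysam.AlignedSegment) -> _RecordView:
    if rec.is_paired:
        orient = "R1" if rec.is_read1 else "R2"
    else:
        orient = "single"
    quals = rec.query_qualities
    return _RecordView(
        name=rec.query_name,
        sequence=rec.query_sequence or "",
        qualities=tuple(quals) if quals is not None else None,
        is_mapped=not rec.is_unmapped,
        is_reverse=bool(rec.is_reverse and not rec.is_unmapped),
        orientation=orient,
        segment=rec,
    )


class _NaiveMatcher:
    """Single-pattern matcher with the automaton's reporting interface."""

    def __init__(self, pattern: str) -> None:
        self.patterns = [pattern]

    def iter_matches(self, text: str) -> Iterator[tuple[int, int]]:
        pat = self.patterns[0]
        start = text.find(pat)
        while start != -1:
            yield start + len(pat) - 1, 0
            start = text.find(pat, start + 1)


_warned_missing_quals = False


def _match_view(
    view: _RecordView,
    matcher,
    peps: PeptideSet,
    cfg: ScanConfig,
) -> list[MatchRecord]:
    global _warned_missing_quals
    seq = view.sequence
    if not seq or "=" in seq:
        return []
    pairs = frames_for(cfg.strandedness, view.orientation)
    if view.is_reverse:
        # stored sequence is reference-oriented; as-sequenced frames map to
        # stored frames with the orientation bit flipped
        pairs = {(f, not r) for f, r in pairs}
    out: list[MatchRecord] = []
    seen: set[tuple[int, GenomicLocation]] = set()
    n = len(seq)
    key_lengths = getattr(matcher, "pattern_lengths", None)
    if key_lengths is None:
        key_lengths = [len(k) for k in matcher.patterns]
    for frame, rev in sorted(pairs):
        text = translate(seq, frame, rev)
        if peps.il_equivalent:
            text = collapse_il(text)
        for end, pat_idx in matcher.iter_matches(text):
            plen = key_lengths[pat_idx]
            p = end - plen + 1
            if rev:
                q_from = n - (frame + 3 * (p + plen))
                q_to = n - (frame + 3 * p)
            else:
                q_from = frame + 3 * p
                q_to = frame + 3 * (p + plen)
            if view.qualities is None:
                if not _warned_missing_quals:
                    _warned_missing_quals = True
                    warnings.warn(
                        "records without base qualities: error filter not applied",
                        stacklevel=2,
                    )
                prob = 0.0
            else:
                prob = span_error_probability(view.qualities[q_from:q_to])
            if prob > cfg.error_threshold:
                continue
            if view.is_mapped and view.segment is not None:
                strand = "-" if rev else "+"
                loc = project_span(view.segment, (q_from, q_to), strand)
            else:
                loc = UNMAPPED
            dedup = (pat_idx, loc)
            if dedup in seen:
                continue
            seen.add(dedup)
            out.append(
                MatchRecord(
                    entry=pat_idx,
                    read_name=view.name,
                    location=loc,
                    frame=frame,
                    reverse=rev,
                    error_probability=prob,
                    matched_nt=seq[q_from:q_to],
                )
            )
    return out


def _iter_views(source, cfg: ScanConfig) -> Iterator[_RecordView]:
    """Yield eligible record views from a BAM/SAM path or FASTQ path."""
    if isinstance(source, pysam.AlignmentFile):
        handle = source
        close = False
    else:
        path = str(source)
        if path.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz")):
            with pysam.FastxFile(path) as fx:
                for entry in fx:
                    quals = entry.get_quality_array()
                    yield _RecordView(
                        name=entry.name,
                        sequence=entry.sequence.upper(),
                        qualities=tuple(quals) if quals is not None else None,
                        is_mapped=False,
                        is_reverse=False,
                        orientation="single",
                        segment=None,
                    )
            return
        handle = pysam.AlignmentFile(path, check_sq=False)
        close = True
    try:
        for rec in handle.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if cfg.exclude_duplicates and rec.is_duplicate:
                continue
            yield _view_bam(rec)
    finally:
        if close:
            handle.close()


def scan_records(
    source,
    automaton: AhoCorasick,
    peps: PeptideSet,
    cfg: ScanConfig | None = None,
) -> ScanResult:
    """Scan every eligible record in ``source`` for peptide matches.

    ``source`` is a path to a coordinate-sorted BAM/SAM, a FASTQ(.gz) path,
    or an open :class:`pysam.AlignmentFile`. Primary alignments and
    unmapped records are scanned; secondary and supplementary alignments
    are skipped so that a fragment never contributes twice at one location.
    ``total_records`` in the result is the RPHM denominator: the number of
    scanned records.

    Records are processed in fixed-size batches; with ``cfg.threads > 1``
    batches are dispatched to a thread pool and results merged in batch
    order, so output is identical for any thread count.
    """
    cfg = cfg or ScanConfig()
    matches: list[MatchRecord] = []
    total = 0

    def process_batch(batch: list[_RecordView]) -> list[MatchRecord]:
        out: list[MatchRecord] = []
        for view in batch:
            out.extend(_match_view(view, automaton, peps, cfg))
        return out

    views = _iter_views(source, cfg)
    if cfg.threads <= 1:
        for view in views:
            total += 1
            matches.extend(_match_view(view, automaton, peps, cfg))
    else:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            futures = []
            batch: list[_RecordView] = []
            for view in views:
                total += 1
                batch.append(view)
                if len(batch) >= cfg.batch_size:
                    futures.append(pool.submit(process_batch, batch))
                    batch = []
            if batch:
                futures.append(pool.submit(process_batch, batch))
            for fut in futures:
                matches.extend(fut.result())
    logger.info("scanned %d records, %d matches", total, len(matches))
    return ScanResult(matches=matches, total_records=total)


def count_total_records(bam_path: str, cfg: ScanConfig | None = None) -> int:
    """Count eligible records (primary + unmapped) in a BAM file."""
    cfg = cfg or ScanConfig()
    n = 0
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if cfg.exclude_duplicates and rec.is_duplicate:
                continue
            n += 1
    return n


def count_in_region(
    bam_path: str,
    peptide: str,
    location: GenomicLocation,
    cfg: ScanConfig | None = None,
    il_equivalent: bool = False,
    denominator: int | None = None,
) -> tuple[int, float]:
    """Target mode: count reads matching ``peptide`` exactly at ``location``.

    Fetches only reads overlapping the location (requires a BAM index),
    applies the same translation/quality pipeline as scan mode, and counts
    records whose match projects exactly onto the given blocks and strand.
    RPHM uses the whole-file record count as denominator; it is computed by
    a full pass when not supplied.
    """
    cfg = cfg or ScanConfig()
    if location.is_unmapped:
        raise ValueError("target mode requires a mapped location")
    key = collapse_il(peptide) if il_equivalent else peptide
    matcher = _NaiveMatcher(key)
    peps = PeptideSet(
        [(peptide, peptide)],
        il_equivalent=il_equivalent,
        length_range=(1, 100),
    )
    count = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if location.chrom not in bam.references:
            raise ValueError(f"unknown chromosome {location.chrom!r}")
        for rec in bam.fetch(location.chrom, location.start, location.end):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if cfg.exclude_duplicates and rec.is_duplicate:
                continue
            view = _view_bam(rec)
            for m in _match_view(view, matcher, peps, cfg):
                if (
                    m.location.chrom == location.chrom
                    and m.location.blocks == location.blocks
                    and (location.strand == "." or m.location.strand == location.strand)
                ):
                    count += 1
                    break
    if denominator is None:
        denominator = count_total_records(bam_path, cfg)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return count, count / denominator * 1e8
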