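"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's automaton and CIGAR-walking code:
matching is naive substring search over per-frame translations, and
genomic projection goes through pysam's aligned-pairs interface.
"""

from __future__ import annotations

import itertools

import pysam

from pepscan.scan import UNMAPPED, GenomicLocation
from pepscan.seqcore import (
    STANDARD_CODE,
    collapse_il,
    span_error_probability,
    translate,
)

_CD_OP, _CN_OP = 2, 3


def pairs_project(rec: pysam.AlignedSegment, qstart: int, qend: int,
                  strand: str) -> GenomicLocation:
    """Project a stored-read interval via get_aligned_pairs."""
    if rec.is_unmapped:
        return UNMAPPED
    need = qend - qstart
    emitted = 0
    split = broken = False
    blocks: list[list[int]] = []
    for q, r, op in rec.get_aligned_pairs(with_cigar=True):
        if q is not None and qstart <= q < qend:
            if r is None:  # insertion or soft clip inside the span
                return UNMAPPED
            if blocks and broken:
                return UNMAPPED
            if blocks and not split and blocks[-1][1] == r:
                blocks[-1][1] = r + 1
            else:
                blocks.append([r, r + 1])
            split = broken = False
            emitted += 1
        elif q is None and 0 < emitted < need:
            if op == _CD_OP:
                broken = True
            elif op == _CN_OP:
                split = True
    return GenomicLocation(rec.reference_name, strand,
                           tuple(tuple(b) for b in blocks))


def brute_force_scan(
    bam_path: str,
    peptides: list[str],
    il_equivalent: bool = False,
    error_threshold: float = 0.05,
) -> tuple[dict[tuple[str, str, str], int], dict[str, int], int]:
    """Translate every record in all six frames and search naively.

    Returns (per-(key, location, strand) counts, per-key totals,
    denominator). Unstranded protocol; keys are I/L-collapsed when
    requested.
    """
    keys = sorted({collapse_il(p) if il_equivalent else p for p in peptides})
    loc_counts: dict[tuple[str, str, str], int] = {}
    totals: dict[str, int] = {k: 0 for k in keys}
    denominator = 0
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            denominator += 1
            seq = rec.query_sequence
            if not seq:
                continue
            quals = rec.query_qualities
            seen: set[tuple[str, GenomicLocation]] = set()
            n = len(seq)
            for rev in (False, True):
                for frame in (0, 1, 2):
                    text = translate(seq, frame, rev)
                    if il_equivalent:
                        text = collapse_il(text)
                    for key in keys:
                        start = text.find(key)
                        while start != -1:
                            plen = len(key)
                            if rev:
                                q_from = n - (frame + 3 * (start + plen))
                                q_to = n - (frame + 3 * start)
                            else:
                                q_from = frame + 3 * start
                                q_to = frame + 3 * (start + plen)
                            prob = (
                                span_error_probability(quals[q_from:q_to])
                                if quals is not None
                                else 0.0
                            )
                            if prob <= error_threshold:
                                if rec.is_unmapped:
                                    loc = UNMAPPED
                                else:
                                    loc = pairs_project(
                                        rec, q_from, q_to,
                                        "-" if rev else "+",
                                    )
                                dkey = (key, loc)
                                if dkey not in seen:
                                    seen.add(dkey)
                                    lkey = (key, str(loc), loc.strand)
                                    loc_counts[lkey] = loc_counts.get(lkey, 0) + 1
                                    totals[key] += 1
                            start = text.find(key, start + 1)
    return loc_counts, totals, denominator


def enumerate_reverse_translations(peptide: str) -> set[str]:
    """Exhaustive reverse-translation set via codon-product enumeration.

    Every combination of synonymous codons is generated and verified to
    translate back to the peptide; for short peptides this is the full
    preimage of the translation map.
    """
    synonyms: dict[str, list[str]] = {}
    for codon, aa in STANDARD_CODE.codon_to_aa.items():
        synonyms.setdefault(aa, []).append(codon)
    out = set()
    for combo in itertools.product(*(synonyms[aa] for aa in peptide)):
        nt = "".join(combo)
        assert translate(nt) == peptide
        out.add(nt)
    return out
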