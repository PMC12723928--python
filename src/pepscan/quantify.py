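"""Aggregation of matches into genomic-level and peptide-level tables.

Raw match counts are normalized to the total scanned read count and
scaled by 1e8 to give reads per hundred million (RPHM). Two outputs are
produced: a genomic-level table with one row per (peptide, location) and a
peptide-level table with the total RPHM (summed over all locations) and
the single best-supported location.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .scan import UNMAPPED, GenomicLocation, MatchRecord, PeptideSet

__all__ = [
    "RPHM_SCALE",
    "LocationCount",
    "PeptideSummary",
    "aggregate",
    "select_best_location",
    "genomic_table",
    "peptide_table",
]

RPHM_SCALE = 1e8


@dataclass(frozen=True)
class LocationCount:
    """Raw count and RPHM of one peptide at one genomic location."""

    peptide_id: str
    location: GenomicLocation
    raw_count: int
    rphm: float
    n_unmapped_variants: int = 0


@dataclass(frozen=True)
class PeptideSummary:
    """Per-peptide totals and the highest-expressed location."""

    peptide_id: str
    total_count: int
    total_rphm: float
    best_location: GenomicLocation
    best_rphm: float


def _location_sort_key(loc: GenomicLocation) -> tuple:
    # unmapped rows sort last
    if loc.is_unmapped:
        return (1, "", (), "")
    return (0, loc.chrom, loc.blocks, loc.strand)


def select_best_location(counts: Sequence[LocationCount]) -> GenomicLocation:
    """Location with the maximal RPHM for one peptide.

    Ties are broken by (chrom, first block start, strand) order; the
    unmapped location is chosen only when no mapped location exists.
    """
    if not counts:
        raise ValueError("no locations")
    mapped = [c for c in counts if not c.location.is_unmapped]
    pool = mapped if mapped else list(counts)
    return min(
        pool, key=lambda c: (-c.rphm, c.location.chrom, c.location.blocks,
                             c.location.strand)
    ).location


def aggregate(
    matches: Iterable[MatchRecord],
    denominator: int,
    peps: PeptideSet,
    include_unmapped_in_total: bool = True,
) -> tuple[list[LocationCount], list[PeptideSummary]]:
    """Group matches by (peptide, location) and summarize per peptide.

    All unmapped matches of a peptide pool into a single "." row whose
    ``n_unmapped_variants`` counts distinct matched nucleotide sequences.
    Peptides without any match appear in the peptide-level output with
    count 0. The peptide total sums RPHM over all locations, including the
    unmapped pool unless ``include_unmapped_in_total`` is false.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    by_key: dict[tuple[int, GenomicLocation], int] = {}
    unmapped_variants: dict[int, set[str]] = {}
    for m in matches:
        loc = UNMAPPED if m.location.is_unmapped else m.location
        key = (m.entry, loc)
        by_key[key] = by_key.get(key, 0) + 1
        if loc.is_unmapped:
            unmapped_variants.setdefault(m.entry, set()).add(m.matched_nt)

    loc_counts: list[LocationCount] = []
    per_entry: dict[int, list[LocationCount]] = {}
    for (entry, loc), n in by_key.items():
        pid = ",".join(peps.ids[entry])
        lc = LocationCount(
            peptide_id=pid,
            location=loc,
            raw_count=n,
            rphm=n / denominator * RPHM_SCALE,
            n_unmapped_variants=len(unmapped_variants.get(entry, set()))
            if loc.is_unmapped
            else 0,
        )
        loc_counts.append(lc)
        per_entry.setdefault(entry, []).append(lc)

    loc_counts.sort(key=lambda c: (c.peptide_id, _location_sort_key(c.location)))

    summaries: list[PeptideSummary] = []
    for entry in range(len(peps)):
        pid = ",".join(peps.ids[entry])
        counts = per_entry.get(entry, [])
        if not counts:
            summaries.append(
                PeptideSummary(
                    peptide_id=pid,
                    total_count=0,
                    total_rphm=0.0,
                    best_location=UNMAPPED,
                    best_rphm=0.0,
                )
            )
            continue
        in_total = [
            c
            for c in counts
            if include_unmapped_in_total or not c.location.is_unmapped
        ]
        total_count = sum(c.raw_count for c in in_total)
        total_rphm = sum(c.rphm for c in in_total)
        best = select_best_location(counts)
        best_rphm = next(c.rphm for c in counts if c.location == best)
        summaries.append(
            PeptideSummary(
                peptide_id=pid,
                total_count=total_count,
                total_rphm=total_rphm,
                best_location=best,
                best_rphm=best_rphm,
            )
        )
    summaries.sort(key=lambda s: s.peptide_id)
    return loc_counts, summaries


def genomic_table(loc_counts: Sequence[LocationCount]) -> pd.DataFrame:
    """Genomic-level output: one row per (peptide, location)."""
    return pd.DataFrame(
        {
            "peptide": [c.peptide_id for c in loc_counts],
            "location": [str(c.location) for c in loc_counts],
            "strand": [c.location.strand for c in loc_counts],
            "raw_count": [c.raw_count for c in loc_counts],
            "rphm": [c.rphm for c in loc_counts],
            "n_unmapped_variants": [c.n_unmapped_variants for c in loc_counts],
        }
    )


def peptide_table(summaries: Sequence[PeptideSummary]) -> pd.DataFrame:
    """Peptide-level output: totals and best-supported location."""
    return pd.DataFrame(
        {
            "peptide": [s.peptide_id for s in summaries],
            "total_count": [s.total_count for s in summaries],
            "total_rphm": [s.total_rphm for s in summaries],
            "best_location": [str(s.best_location) for s in summaries],
            "best_strand": [s.best_location.strand for s in summaries],
            "best_rphm": [s.best_rphm for s in summaries],
        }
    )
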