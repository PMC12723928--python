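"""Genetic-code translation, frame handling, I/L equivalence and quality models.

Everything downstream of read scanning builds on four primitives defined
here: frame-wise translation of nucleotide sequences, the set of reading
frames implied by a library's strandedness, the isoleucine/leucine collapse
used when peptides come from de novo MS/MS sequencing (where I and L are
indistinguishable by mass), and the aggregate sequencing-error probability
of a matched coding span, used to filter unreliable matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Sequence

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "QualitySpan",
    "translate",
    "reverse_complement",
    "frames_for",
    "collapse_il",
    "span_error_probability",
    "count_coding_sequences",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Residues of the 20 proteinogenic amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code (NCBI translation table 1).

    Attributes
    ----------
    codon_to_aa
        Maps each of the 64 trinucleotides to an amino acid, or ``'*'``
        for the three stop codons.
    aa_to_codon_count
        Number of synonymous codons per amino acid (the degeneracy used to
        size a peptide's reverse-translation space).
    """

    codon_to_aa: dict[str, str] = field(default_factory=dict)
    aa_to_codon_count: dict[str, int] = field(default_factory=dict)

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        codon_to_aa = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_to_aa[stop] = "*"
        counts: dict[str, int] = {}
        for aa in codon_to_aa.values():
            counts[aa] = counts.get(aa, 0) + 1
        if len(codon_to_aa) != 64:  # pragma: no cover - sanity
            raise RuntimeError("genetic code table is incomplete")
        return cls(codon_to_aa=codon_to_aa, aa_to_codon_count=counts)

    def codon_count(self, aa: str) -> int:
        """Number of synonymous codons for amino acid ``aa``."""
        try:
            return self.aa_to_codon_count[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid: {aa!r}") from None


STANDARD_CODE = GeneticCode.standard()


@dataclass(frozen=True)
class QualitySpan:
    """Phred scores for the nucleotides encoding one matched peptide.

    The span covers exactly the coding bases of the match, so its length is
    three times the peptide length.
    """

    phred_scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(q < 0 for q in self.phred_scores):
            raise ValueError("Phred scores must be non-negative")
        if len(self.phred_scores) % 3 != 0:
            raise ValueError("coding span length must be a multiple of 3")


def reverse_complement(nt_seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return nt_seq.translate(_COMPLEMENT)[::-1]


def _validate_nt(nt_seq: str) -> None:
    invalid = set(nt_seq.upper()) - set("ACGTN")
    if invalid:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(invalid)}")


def translate(
    nt_seq: str,
    frame: int = 0,
    reverse: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Translate ``nt_seq`` in a single reading frame.

    If ``reverse`` is true the sequence is reverse-complemented first; the
    frame offset then applies to the reverse-complemented sequence. A
    trailing partial codon is dropped. Codons containing ``N`` translate to
    ``'X'`` and stop codons to ``'*'``; neither terminates translation, so
    the returned string always covers every complete codon. Query peptides
    contain neither ``X`` nor ``*``, hence a match can never span an
    ambiguous codon or a stop.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    _validate_nt(nt_seq)
    seq = nt_seq.upper()
    if reverse:
        seq = reverse_complement(seq)
    table = code.codon_to_aa
    end = len(seq) - (len(seq) - frame) % 3
    return "".join(
        table.get(seq[i : i + 3], "X") for i in range(frame, end, 3)
    )


def frames_for(
    strandedness: str, read_orientation: str = "single"
) -> set[tuple[int, bool]]:
    """Reading frames implied by the library protocol.

    Parameters
    ----------
    strandedness
        ``"unstranded"`` (translate all six frames), ``"forward"``
        (R1/single reads are sense) or ``"reverse"`` (R1 reads are
        antisense, as in dUTP protocols).
    read_orientation
        ``"R1"``, ``"R2"`` or ``"single"``. The second mate's frames are
        flipped relative to the first.

    Returns
    -------
    set of ``(frame, reverse)`` pairs to translate, relative to the read as
    sequenced.
    """
    if strandedness not in ("unstranded", "forward", "reverse"):
        raise ValueError(f"unknown strandedness: {strandedness!r}")
    if read_orientation not in ("R1", "R2", "single"):
        raise ValueError(f"unknown read orientation: {read_orientation!r}")
    if strandedness == "unstranded":
        return {(f, r) for f in (0, 1, 2) for r in (False, True)}
    sense = strandedness == "forward"
    if read_orientation == "R2":
        sense = not sense
    return {(f, not sense) for f in (0, 1, 2)}


def collapse_il(aa_seq: str) -> str:
    """Replace every isoleucine by leucine (idempotent).

    De novo MS/MS sequencing cannot distinguish I from L; collapsing both
    the queries and the translated reads onto L makes matching
    I/L-equivalent.
    """
    return aa_seq.replace("I", "L")


def span_error_probability(quals: QualitySpan | Sequence[int]) -> float:
    """Probability of at least one sequencing error in a matched span.

    With independent per-base error probabilities ``10**(-Q/10)``, the
    aggregate is ``1 - prod(1 - 10**(-Q_i/10))``. Matches whose span
    probability exceeds the configured threshold (default 0.05) are
    discarded by the scan engine.
    """
    scores = quals.phred_scores if isinstance(quals, QualitySpan) else tuple(quals)
    if len(scores) == 0:
        raise ValueError("empty quality span")
    p_ok = reduce(lambda acc, q: acc * (1.0 - 10.0 ** (-q / 10.0)), scores, 1.0)
    return 1.0 - p_ok


def count_coding_sequences(
    peptides: Iterable[str], code: GeneticCode = STANDARD_CODE
) -> int:
    """Total size of the reverse-translation space of a peptide set.

    For each peptide the number of nucleotide sequences translating to it
    is the product of synonymous-codon counts over its residues; the total
    is the sum over peptides. This is the quantity that makes
    reverse-translation-based matching infeasible for long (class II)
    peptides.
    """
    total = 0
    for pep in peptides:
        n = 1
        for aa in pep:
            n *= code.codon_count(aa)
        total += n
    return total
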