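# Methods

## Matching model

Query peptides (7–25 aa by default; class I peptides are typically
8–12 aa, class II 13–25 aa) are compiled into an Aho-Corasick automaton:
a trie over all peptides augmented with failure links (longest proper
suffix that is also a trie prefix) and merged output links. One pass over
a translated read reports every occurrence of every peptide — overlapping
and nested occurrences included — in O(max peptide length + read length +
matches). Each sequencing record is translated in the frames implied by
the library protocol: all six frames for unstranded data, three for
stranded (dUTP-style `reverse` protocols translate R1 antisense and R2
sense; `forward` the opposite). Translation uses the standard genetic
code (NCBI table 1) only; codons containing `N` translate to `X` and
stops to `*`, neither of which can occur in a query peptide, so a match
can never span an ambiguous codon or a stop — this is equivalent to
rejecting such codons without truncating the translation.

BAM records are matched on the stored (reference-oriented) sequence; for
a record flagged reverse-complemented, the as-sequenced frames map to
stored-sequence frames with the orientation bit flipped, and the genomic
strand of a match is `+` for forward-frame hits and `-` for
reverse-frame hits. Primary alignments and unmapped records are scanned;
secondary and supplementary alignments are skipped so a fragment never
contributes twice to one location. Duplicate-flagged reads are included
by default (peptide support should not depend on deduplication state);
`--exclude-duplicates` removes them. FASTQ input is treated as entirely
unmapped: peptide-level counts only.

## Quality filter

A match is kept only if the probability of at least one sequencing error
within the 3L bases encoding the matched peptide,
p = 1 − ∏ᵢ (1 − 10^(−Qᵢ/10)), is at most the threshold (default 0.05).
The span — not the whole read — is assessed: filtering on whole-read
quality would reject long, high-quality reads for errors far from the
match. Uniform Q30 passes a 9-mer span (p ≈ 0.027) but fails a 25-mer
span (p ≈ 0.072); uniform Q20 fails even a 9-mer (p ≈ 0.237). Records
without stored base qualities pass with a warning; absence of evidence
does not discard a match.

## Coordinate projection

A matched span on the read is projected through the CIGAR: M/=/X consume
read and reference, D and N consume reference only, I and S read only.
An N inside the span opens a new block, giving spliced multi-block
locations whose block lengths sum to 3L. A span overlapping an I or S
segment has no reference image and is reported at the unmapped location
(`.`); a span interrupted by a D is likewise treated as unmapped, because
a deletion breaks codon colinearity between read and reference and a
"location" spanning it would misstate the coding frame. Deletions and
clips outside the span are harmless. Locations are serialized 1-based
inclusive (`chrom:start-end`, blocks joined by `|`); internally all
coordinates are 0-based half-open.

## Quantification

RPHM = raw matched-read count / total scanned records × 10⁸. The
denominator is the number of scanned records (primary + unmapped) — reads,
not fragments; each mate counts once. Unmapped matches of a peptide pool
into a single `.` row whose `n_unmapped_variants` column counts distinct
matched nucleotide sequences. The peptide-level total sums RPHM over all
locations including the unmapped pool (it is expression evidence; a flag
excludes it), and the best location is the mapped location of maximal
RPHM, ties broken by (chromosome, first block start, strand); the
unmapped pool can be "best" only when nothing mapped. Within one record a
peptide is counted at most once per location, so nested automaton hits
cannot double-count. Records are processed in fixed-size batches merged
in input order, and all outputs are canonically sorted, so results are
byte-identical for any thread count.

## Annotation

The GTF (GENCODE dialect, parsed via gffutils) is indexed as
per-chromosome interval trees over gene spans with transcript/exon/CDS
substructure. A location is queried by its overall span; genes touched
only by an intron gap of a spliced location are dropped. With no
overlapping gene the call is IGR. Per overlapping gene, an
opposite-strand gene yields asRNA; a sense-strand gene is classified per
transcript and the lowest-penalty transcript call represents the gene:

* blocks not fully exonic → IR;
* fully exonic, junctions matching consecutive exons (equivalently,
  contiguous in transcript coordinates): non-coding transcript → ncRNA;
  coding transcript with the span inside the CDS → IF when the span's
  offset from the CDS start (adjusted by the first CDS segment's frame)
  is ≡ 0 mod 3, else OOF; span overlapping UTR → UTR;
* junction deviating from the annotated structure: if every deviant
  junction has both ends on annotated exon boundaries and skips at least
  one whole exon → ES, otherwise → ASS (one or no end on an annotated
  boundary — an alternative/novel splice site). This follows the
  standard splice-event taxonomy; the category definitions for ES/ASS
  are a design choice of this package.

Penalties are IF = 0, ES = ASS = 15, UTR = OOF = 20, ncRNA = 30, IR = 60,
asRNA = 120, IGR = 240; `best_annotation` takes the minimum, ties broken
by the category order IF < ES < ASS < UTR < OOF < ncRNA < IR < asRNA <
IGR, then gene id. IF carries penalty 0 as the unpenalized default. A
location over both a sense intron and an antisense exon yields both calls
(IR wins on penalty). Classification is invariant under splitting a block
at a non-junction point.

## Prioritization

Thresholds: per peptide, RPHM values across normal samples are averaged
over strictly positive entries (all-zero rows average 0); peptides are
stratified by (MHC class, length); the threshold is the 1st percentile of
the stratum's averages, using the linear-interpolation quantile (the
common default in scientific computing; no other definition is implied by
the procedure). Strata under 100 peptides fall back to the pooled
per-class percentile with a warning, since an extreme percentile of a
tiny group is unstable.

Cascade, in order, with "above threshold" always strict (>):

1. exclude unless the tumor maximum exceeds the stratum threshold
   (`excluded_low_tumor`);
2. exclude when more than ⌊f·N⌋ of N oGTEx samples are above threshold
   (f = 1% by default; with N = 2,303 this is the "more than 23 samples"
   rule) (`excluded_oGTEx_recurrent`);
3. exclude when any NAT or mTEC sample is above threshold — peripheral
   or central tolerance (`excluded_tolerance`);
4. TSA when strictly fewer than f·N oGTEx samples are above threshold
   (f = 0.1%; "fewer than 3 of 2,303");
5. else TAA when the tumor maximum exceeds the oGTEx maximum; otherwise
   the peptide is excluded as recurrent — this branch shares the
   `excluded_oGTEx_recurrent` label, since the reason is oGTEx expression
   comparable to tumor;
6. TSA/TAA peptides on a user-supplied protein-evidence exclusion list
   (e.g. genes with immunohistochemistry evidence in normal tissue)
   become `excluded_protein_evidence`. This list replaces any external
   protein-atlas lookup.

Cutoffs are recomputed from the fractions and the actual cohort size, so
the same rules apply to cohorts of any size. `evaluate_specificity` runs
the cascade on labeled positive/negative sets and reports the retained
and excluded fractions.

Single-cell scoring: per sample, the top 10% of detected peptides by
normalized abundance are kept; scProportion is the fraction of expressing
cells per cell type; peptides above 0.5 in at least one type are scored
by mCV = sample (n−1) standard deviation of per-type scProportions
divided by their median — a coefficient of variation with the median
replacing the mean ("median-centered"). A zero median with positive
spread scores +inf and ranks first. Gene-level mCV is the maximum over
the gene's peptides; the top 50 genes are returned by default. The exact
mCV formula and the "most abundant" normalization are design choices
documented here.

## Synthetic fixtures

The generator emulates exactly what the matcher consumes: a small random
genome (two chromosomes by default), a GTF with a 4-exon coding gene, a
2-exon lncRNA and a minus-strand coding gene laid out so that every
annotation category has a designed locus, and 76-bp single-end reads with
uniform Phred qualities, plain/spliced/soft-clipped/deletion-bearing
CIGARs and optional unmapped records carrying coding sequences. Planted
coding sequences are drawn by random synonymous-codon choice; the genome
is then six-frame translated and scanned so that each planted peptide
occurs exactly at its loci and nowhere else, every planted read contains
exactly its own peptide once, and background reads contain no query
peptide in any frame — truth counts are exact by construction, with
bounded deterministic retries on collision. Peptide sets in which one
(I/L-collapsed) peptide nests inside another are rejected because their
truth counts would be ambiguous. Reads must fully span a peptide-coding
region, so the read length must be at least 3× the longest peptide — the
matcher itself has the same reliance on fully spanning reads.

What the fixtures do **not** emulate: realistic error/indel models,
expression-level realism, fragment-length and paired-end structure,
polymorphism, or genome-scale repeat content. Passing tests therefore
demonstrate algorithmic correctness (counting, projection, filtering,
classification, cascade logic), not performance on real tissue data.

The labeled expression cohort (`synthetic_cohort`) plants four peptide
classes — tumor-only TSAs, TAAs above threshold in two oGTEx samples but
tumor-dominant, tolerance-excluded peptides high in NAT/mTEC, and broadly
expressed peptides in half the oGTEx samples — with at least tenfold
margins around the derived threshold (exactly 1 RPHM by construction).
Recovery is exact under these margins; the retained/excluded fractions on
the labeled sets are 100% by design, a scaled-down, clean-margin analogue
of the high retention/exclusion rates achievable on real viral/normal
pMHC sets.

## Problem sizes and numerical choices

The test suite and the acceptance script use fixtures of roughly 200–10,000
reads and up to ~340 query peptides (five datasets for the oracle
comparison), a 500-peptide labeled cohort with 300 oGTEx pseudo-samples,
and 10,000 Uniform(0, 200) averages for the threshold sanity check —
sizes chosen so every check runs in seconds while still exercising mixed
CIGARs, both strands, spliced and unmapped locations and all nine
annotation categories. All randomness is seeded; fixture generation is
integer-based and platform-independent, and identical seeds yield
byte-identical FASTA/GTF/truth outputs. Floating-point output is written
at full double precision with fixed column order.

## Known limitations

* RNA evidence is a proxy: a transcript hit does not guarantee antigen
  presentation, and peptides created post-transcriptionally (ribosomal
  frameshifts, substitutions, true proteasome splicing) have no RNA
  signature by construction.
* Matching is exact (after optional I/L collapse); no mismatch-tolerant
  search, realignment or variant calling.
* Only reads fully spanning the coding region count; short-read or
  shallow single-cell data lose sensitivity for long class II peptides.
* Spans over deletions are conservatively unmapped rather than projected.
* Alternative genetic codes and codon-usage weighting are out of scope.
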