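# pepscan

Fast matching of MHC class I/II peptide sequences against frame-translated
RNA-seq reads, with quality filtering, RPHM quantification, genomic
annotation, and a rule-based tumor-antigen prioritization workflow.

## Who this is for

Immunopeptidomics studies identify thousands of MHC-bound peptides (pMHCs)
by mass spectrometry, including many *non-reference* peptides absent from
the canonical proteome — products of untranslated regions, introns,
non-coding RNAs, antisense transcription, out-of-frame translation or
intergenic loci. Deciding which of these are genuinely tumor-specific
requires checking their RNA-level support across tumors and large normal
cohorts. Reverse-translating each peptide and aligning the coding
sequences is infeasible for long class II peptides: the number of coding
sequences for a peptide A₁…A_L is ∏ᵢ C(Aᵢ), where C is the
synonymous-codon count, and this grows exponentially with L (for the
9-mer `SAAADILLL` it is already 6·4·4·4·2·3·6·6·6 = 497,664).

`pepscan` goes the other way: it indexes the *peptides* with an
Aho-Corasick automaton and streams the *reads* through it. Every read is
translated in six frames (or three, for stranded libraries) and matched
against all query peptides simultaneously in
O(max peptide length + read length + number of matches) per read — so
runtime is essentially independent of peptide count and peptide length,
and reads carrying sample-specific variants or sequences absent from the
reference genome (viral, HLA) are matched directly.

## What it computes

* **scan mode** — every quality-passing occurrence of every peptide in a
  BAM (mapped *and* unmapped records) or FASTQ file. A match whose
  aggregate error probability over the 3L coding bases,
  1 − ∏ᵢ (1 − 10^(−Qᵢ/10)), exceeds 0.05 is discarded. Matched spans are
  projected through the CIGAR onto genomic coordinates (splice-aware,
  multi-block); counts are normalized to **RPHM** (reads per hundred
  million) = raw count / total read count × 10⁸. Outputs a genomic-level
  table (one row per peptide × location, `.` pooling unmapped evidence)
  and a peptide-level table (total RPHM summed over locations plus the
  best-supported location).
* **target mode** — the same count restricted to a given location, for
  quick re-quantification of a short list of characterized peptides in
  other samples.
* **annotate mode** — classifies each location against a GTF using
  per-chromosome interval trees into IF, OOF, UTR, ncRNA, IR, asRNA, ES,
  ASS or IGR, resolving multi-gene overlaps by empirical penalty scores
  (IF = 0, ES/ASS = 15, UTR/OOF = 20, ncRNA = 30, IR = 60, asRNA = 120,
  IGR = 240; lowest wins).
* **prioritize** — derives (MHC class, peptide length)-stratified RPHM
  thresholds from normal cohorts (1st percentile of per-peptide non-zero
  mean RPHM) and runs the TSA/TAA exclusion cascade over tumor, NAT,
  oGTEx and mTEC matrices. A single-cell scorer ranks peptides/genes by
  cell-type specificity (scProportion, median-centered CV).
* **simulate** — a deterministic fixture generator (genome, GTF, reads
  with planted peptide-coding sequences, ground-truth tables) used by the
  test suite and usable for your own validation.

## Worked example

Generate a fixture and scan it:

```bash
pepscan simulate --seed 11 --out-dir sim
cut -f1 sim/truth.tsv | tail -n +2 | sort > peptides.txt
pepscan scan --peptides peptides.txt --bam sim/reads.bam --out-prefix scan
pepscan annotate --gtf sim/annotation.gtf --input scan.genomic.tsv --out annotated.tsv
```

`scan.genomic.tsv` (first rows):

```
peptide	location	strand	raw_count	rphm	n_unmapped_variants
CAYHRQWEN	chr1:2088-2100|3051-3064	+	3	1265822.7848101265	0
DHTENKYAW	chr2:501-527	+	4	1687763.7130801687	0
EYKHQCNMR	chr1:8111-8137	+	3	1265822.7848101265	0
HNCWTYEDA	chr1:2288-2300|4001-4014	+	3	1265822.7848101265	0
```

Three reads support `CAYHRQWEN` at a spliced two-block location (the `|`
separates blocks; coordinates are 1-based inclusive); with 237 reads in
the file its RPHM is 3/237 × 10⁸ ≈ 1.27 × 10⁶. After annotation:

```
peptide	location	strand	raw_count	category	gene_id
CAYHRQWEN	chr1:2088-2100|3051-3064	+	3	ASS	GENEA
DHTENKYAW	chr2:501-527	+	4	IGR
EYKHQCNMR	chr1:8111-8137	+	3	asRNA	GENEC
HNCWTYEDA	chr1:2288-2300|4001-4014	+	3	ES	GENEA
KTWDNAYEH	chr1:3013-3039	+	3	OOF	GENEA
MGWHEDCRK	chr1:8401-8427	-	3	IF	GENEC
```

`CAYHRQWEN` uses an unannotated splice site inside GENEA (ASS), while
`HNCWTYEDA` skips a whole annotated exon (ES); `MGWHEDCRK` is an in-frame
product of the minus-strand gene GENEC. These calls match the generator's
truth table exactly, as do all counts.

The matches are searched with isoleucine and leucine treated as
interchangeable when `--il-equivalent` is set — de novo MS/MS sequencing
cannot distinguish the two residues.

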