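# Methods

## Coordinates and conventions

All coordinates are 1-based inclusive (GFF convention); BED I/O converts to
0-based half-open at the boundary. A cleavage coordinate is the last
transcribed nucleotide of the mRNA, not the first adenosine of the tail —
this centers the −10..+10 internal-priming window on the biologically
meaningful base and matches how cleavage sites are displayed on genome
tracks.

## Gene-model refinement

Each transcript's span is labeled per base (5'UTR / CDS / intron / 3'UTR;
UTRs are parsed from the annotation when present, else derived as exonic
sequence up-/downstream of the CDS). A gene's unique model takes the common
label where all transcripts agree and **AMB** where they disagree.
Coverage disagreement (a base inside the gene span but outside some
transcript's span) counts as disagreement: the purpose of AMB is to prevent
attributing one cleavage site to multiple transcript structures, and a base
absent from a transcript is exactly such a case. Alternative 5' starts are
treated symmetrically with 3' differences. Transcripts without any CDS are
treated as non-coding and their exonic bases mapped to 3'UTR for PAC
annotation (logged); a poly(A) site on a non-coding transcript behaves like
a 3'UTR site for every downstream statistic.

3' extension: genes with an annotated 3'UTR are extended by a fixed length
(default 120 nt, configurable — annotation pipelines differ in how far real
3'UTRs run past annotated ends, and ~100–150 nt recovers most of them
without swallowing neighbors); genes without one get the genome-wide average
annotated 3'UTR length (arithmetic mean, rounded half up). By default the
extension stops one base before the nearest downstream original gene span on
either strand, so one gene's extension cannot capture another gene's sites;
this truncation can be switched off. Extensions are clipped silently at
chromosome ends.

Position classification uses the strand-matched refined models only; where
two same-strand genes overlap, a gene whose original span covers the
position beats one reaching it only via its extension (ties break toward
the smaller model, then lexicographic gene id — deterministic). Positions
covered by no model are intergenic; an intergenic PAC is displayed through a
±250 nt "hypothetical gene" window around its site.

## Read processing

Quality filter: a FASTQ read is kept when ≥ 80% of bases reach Phred ≥ 20
(both configurable; Phred+33 only). FASTA input passes with a warning.

Stretch definition: walking inward from the read end, at most one
non-matching base is tolerated (leading offset included) and the stretch
ends at the last matching base before that budget is exhausted; it must
start within 3 nt of the end and contain ≥ 8 matching bases (all three
knobs configurable). This accepts the single sequencing error common inside
real homopolymer stretches while rejecting internal runs that merely sit
near the end. Library type (A vs T) is auto-detected by majority vote over
the first 10,000 reads; an exact tie or a stretch-free library is an error
rather than a silent guess. After trimming, reads shorter than 25 nt are
discarded.

Cleavage inference consumes SAM/BAM of the trimmed reads: only mapped
primary, non-supplementary alignments with MAPQ ≥ 10 (configurable) count
as unique. A-reads keep mRNA sense, so a forward alignment ends at the
cleavage site (tag strand +) and a reverse alignment starts there (strand
−); T-read conventions mirror.

## PAC calling

Internal priming is decided per tag coordinate before clustering, on the
sense-strand 21-nt window centered on the site: a run of ≥ 6 consecutive A,
or ≥ 7 A within any 10-nt sub-window, flags the site (strict readings of
"more than 5" / "more than 6"; both thresholds configurable). Windows are
clipped at chromosome ends.

Clustering is single-linkage chaining over distinct coordinates: the
cluster absorbs the next coordinate while the gap to its nearest member is
≤ 24 nt (configurable), i.e. two tags share a PAC iff connected by a chain
of gaps each ≤ 24 — order-independent and equal to connected components of
the gap graph, which the tests exploit as an oracle. Pooled clustering over
samples preserves per-sample counts, so every sample shares PAC boundaries.
The dominant site is the histogram argmax, ties broken toward the smallest
coordinate; PAC width is inclusive (end − start + 1); the region label is
decided at the dominant site only.

## APA statistics

**Trend test.** The s×k table (ordered groups × 3'UTR PACs sorted by
isoform length) is scored with row coordinates 1..s and column coordinates
L_j; the count-weighted Pearson correlation r yields M² = (n−1)r², referred
to χ² with 1 df — the classical trend statistic for ordered two-way tables,
identical to plain Pearson correlation on the n expanded unit observations.
For two groups this is the two-proportion trend test. Direction labels
(lengthening/shortening) are relative to the user-supplied group order,
which is reported. Replicates within a group are pooled by default; a
per-replicate mode (one row per sample) is available. Genes need ≥ 2 3'UTR
PACs, ≥ 2 groups with nonzero counts, non-constant lengths, and a minimum
total count (default 10); 3'UTR isoform length is measured as the dominant
site's transcription-direction offset from the gene's most proximal 3'UTR
PAC, which preserves the length ordering the statistic uses. Benjamini–
Hochberg adjustment is applied across genes.

**Switching detector.** Defaults D = 100 nt, N1 = 10, K = 2, N2 = 5,
α = 0.05, all exposed. A K-fold ratio with a zero denominator and positive
numerator counts as infinite (passes); 0:0 fails. Criterion 5 is Fisher's
exact test (two-sided, minimum-likelihood definition) on raw counts of the
two PACs summed within each group. All criteria use raw counts — the tests
are count-based; TPM exists for display and export only. With > 2 groups
each ordered pair is screened and the first passing pair reported.

**Signal scan.** AATAAA plus its 18 single-substitution hexamers (19
patterns), plus user patterns with IUPAC expansion; overlapping matches are
all reported, positions relative to the cleavage site.

## Simulator

The generator emulates PAT-seq: random 60-kb genome; seven genes from three
templates (single-transcript coding, coding without annotated 3'UTR, and a
four-transcript gene whose disagreements yield four AMB blocks); planted
cleavage sites with per-sample read counts covering a 3'UTR-lengthening
gene, a CDS↔3'UTR switching gene, AMB and fallback-extension sites, null
genes on both strands, and two adjacent intergenic sites; heterogeneity is
a discretized normal (sd 3 nt, clipped at 3σ); reads are the 40 nt of sense
sequence ending at the cleavage coordinate plus a 10–15 nt poly(A) tail,
substitution errors at 0.1%; decoy reads are primed on planted 8-A islets.
Truth SAM records where each trimmed read aligns, so cleavage inference is
tested without an aligner. Sense-strand adenosines are removed from a small
window around each planted site so that a read's poly(A) stretch is exactly
its tail and no genuine site can trip the internal-priming filter — real
3'UTRs are merely A-poor, not A-free, so recovery rates measured here are an
upper bound for A-rich genomes. The generator does not model indels,
realistic quality profiles, multi-mapping, or alignment errors.

Calibration experiments use direct multinomial count tables rather than
reads: 1,000 null genes (identical isoform proportions, 200 tags/group) for
the type-I error, and the planted shift (dominant isoform probability 0.8
vs 0.2, 200 tags/group) for power. These sizes keep the full suite and the
acceptance script in the seconds range while leaving the Monte-Carlo error
on a 5% rate near ±0.7%.

## Known limitations

* No probabilistic internal-priming model; the run/window rule is a hard
  filter.
* PAC region labels come from the dominant site only; a wide PAC spanning a
  boundary keeps a single label.
* The trend test's χ² reference is asymptotic; very low-count genes are
  excluded by the minimum-count rule rather than handled exactly.
* EST-style input is consumed as ordinary SAM alignments; no special EST
  handling.
* Differential expression and differential usage are delegated to external
  count-based tools; the package only formats their inputs.
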