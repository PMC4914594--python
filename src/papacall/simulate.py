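"""Self-contained synthetic PAT-seq datasets with ground truth.

The generator emits everything the pipeline consumes — a random toy genome,
a multi-transcript GFF3-style annotation, PAT-seq reads with heterogeneous
cleavage positions and poly(A)/(T) stretches, the intended alignments of the
trimmed reads as SAM text (so cleavage-site inference is testable without an
aligner), and truth tables of the planted sites.

Design of the synthetic data:

* cleavage microheterogeneity is a discretized normal around each planted
  site (default sigma 3 nt, clipped at 3 sigma);
* reads are the genomic sense sequence ending at the cleavage site plus a
  poly(A) tail, emitted either sense (A-reads) or reverse complemented
  (T-reads); substitution errors at a configurable rate;
* internal-priming decoys are A-rich islets written into intergenic
  sequence, with reads primed off the genomic adenosines, so decoy tags must
  be removed by the A-richness filter;
* windows around planted sites are kept free of sense-strand adenosines so a
  genuine site can never be confused with an internal-priming artifact and
  the poly(A) stretch of a read is exactly its tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from papacall.annotation_model import GenomeIndex, TranscriptModel, reverse_complement
from papacall.read_prep import PolyATag, RawRead

logger = logging.getLogger(__name__)


@dataclass
class PlantedPAC:
    """One true poly(A) site with per-sample read counts."""

    site: int  # 1-based cleavage coordinate (last transcribed base)
    chrom: str
    strand: str
    counts: Dict[str, int]  # sample -> number of reads
    gene_id: Optional[str] = None  # None for intergenic sites
    region: str = ""  # intended region label, for truth checking


@dataclass
class GeneSpec:
    gene_id: str
    start: int  # 1-based genomic start of the gene body
    strand: str
    template: str  # "coding" | "no_utr3" | "four_transcript"
    chrom: str = "Chr1"


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: Dict[str, int] = field(default_factory=lambda: {"Chr1": 60_000})
    genes: List[GeneSpec] = field(default_factory=list)
    planted: List[PlantedPAC] = field(default_factory=list)
    decoys: List[Tuple[str, int]] = field(default_factory=list)  # (chrom, islet start)
    decoy_reads_per_site: int = 20
    samples: Tuple[str, ...] = ("sample1", "sample2")
    read_type: str = "T"
    read_body_length: int = 40
    tail_length_range: Tuple[int, int] = (10, 15)
    cleavage_sd: float = 3.0
    error_rate: float = 0.001
    low_quality_fraction: float = 0.0
    decoy_islet_length: int = 8


# gene templates, all coordinates relative to the gene start (plus strand)
_TEMPLATES = {
    "coding": {
        "length": 1500,
        "transcripts": [
            {"exons": [(0, 499), (800, 1499)], "cds": [(100, 499), (800, 1299)]},
        ],
    },
    "no_utr3": {
        "length": 1000,
        "transcripts": [{"exons": [(0, 999)], "cds": [(100, 999)]}],
    },
    "four_transcript": {
        "length": 1600,
        "transcripts": [
            {
                "exons": [(0, 299), (400, 699), (800, 1099), (1200, 1599)],
                "cds": [(100, 299), (400, 699), (800, 1099), (1200, 1399)],
            },
            {  # skips exon 2 and starts later: AMB at (0,49) and (400,699)
                "exons": [(50, 299), (800, 1099), (1200, 1599)],
                "cds": [(100, 299), (800, 1099), (1200, 1399)],
            },
            {  # longer third exon: AMB at (1100,1150)
                "exons": [(0, 299), (400, 699), (800, 1150), (1200, 1599)],
                "cds": [(100, 299), (400, 699), (800, 1150), (1200, 1399)],
            },
            {  # shorter 3'UTR: coverage gap -> AMB at (1500,1599)
                "exons": [(0, 299), (400, 699), (800, 1099), (1200, 1499)],
                "cds": [(100, 299), (400, 699), (800, 1099), (1200, 1399)],
            },
        ],
    },
}


def template_length(template: str) -> int:
    return _TEMPLATES[template]["length"]


def default_config(seed: int = 0) -> SimulationConfig:
    """The standard simulated study: 7 genes, 2 samples, planted APA patterns.

    Includes a trend (3'UTR lengthening) gene, a CDS/3'UTR switching gene, a
    gene without an annotated 3'UTR, a four-transcript gene with AMB regions,
    null genes on both strands, two adjacent intergenic sites, and three
    internal-priming decoy islets.
    """
    chrom = "Chr1"
    genes = [
        GeneSpec("G001", 2001, "+", "coding", chrom),
        GeneSpec("G002", 8001, "-", "coding", chrom),
        GeneSpec("G003", 14001, "+", "no_utr3", chrom),
        GeneSpec("G004", 20001, "+", "four_transcript", chrom),
        GeneSpec("G005", 26001, "+", "coding", chrom),
        GeneSpec("G006", 32001, "-", "coding", chrom),
        GeneSpec("G007", 38001, "+", "coding", chrom),
    ]
    s1, s2 = "sample1", "sample2"
    planted = [
        # G001: 3'UTR lengthening in sample2 (proximal/distal usage flips)
        PlantedPAC(2001 + 1400, chrom, "+", {s1: 42, s2: 18}, "G001", "3UTR"),
        PlantedPAC(2001 + 1560, chrom, "+", {s1: 18, s2: 42}, "G001", "3UTR"),
        # G002: minus-strand null gene, equal usage
        PlantedPAC(8001 + 150, chrom, "-", {s1: 30, s2: 30}, "G002", "3UTR"),
        PlantedPAC(8001 - 60, chrom, "-", {s1: 30, s2: 30}, "G002", "3UTR"),
        # G003: no annotated 3'UTR; site in the average-length fallback extension
        PlantedPAC(14001 + 999 + 50, chrom, "+", {s1: 40, s2: 40}, "G003", "3UTR"),
        # G004: one PAC in an AMB block, one in the shared 3'UTR
        PlantedPAC(20001 + 550, chrom, "+", {s1: 25, s2: 25}, "G004", "AMB"),
        PlantedPAC(20001 + 1450, chrom, "+", {s1: 35, s2: 35}, "G004", "3UTR"),
        # G005: non-canonical switching, CDS PAC vs 3'UTR PAC reversing
        PlantedPAC(26001 + 1000, chrom, "+", {s1: 48, s2: 12}, "G005", "CDS"),
        PlantedPAC(26001 + 1450, chrom, "+", {s1: 12, s2: 48}, "G005", "3UTR"),
        # G006: minus-strand null gene
        PlantedPAC(32001 + 150, chrom, "-", {s1: 30, s2: 30}, "G006", "3UTR"),
        # G007: second trend gene, shortening in sample2
        PlantedPAC(38001 + 1400, chrom, "+", {s1: 18, s2: 42}, "G007", "3UTR"),
        PlantedPAC(38001 + 1560, chrom, "+", {s1: 42, s2: 18}, "G007", "3UTR"),
        # adjacent intergenic sites (separate PACs at the default 24-nt gap)
        PlantedPAC(46_000, chrom, "+", {s1: 10, s2: 40}, None, "intergenic"),
        PlantedPAC(46_047, chrom, "+", {s1: 30, s2: 25}, None, "intergenic"),
    ]
    decoys = [(chrom, 5_000), (chrom, 11_000), (chrom, 17_500)]
    return SimulationConfig(seed=seed, genes=genes, planted=planted, decoys=decoys)


# ---------------------------------------------------------------- genome


def _sanitize_zone(cfg: SimulationConfig, site: PlantedPAC) -> Tuple[int, int]:
    reach = int(np.ceil(3 * cfg.cleavage_sd)) + 12
    return site.site - reach, site.site + reach


def make_genome(cfg: SimulationConfig) -> Tuple[GenomeIndex, dict]:
    """Random genome with A-rich decoy islets and adenosine-free site zones.

    Returns the genome plus a truth record of decoy islet spans and the
    sanitized windows. A decoy islet overlapping a planted site's window is a
    configuration error.
    """
    rng = np.random.default_rng(cfg.seed)
    bases = np.array(list("ACGT"))
    seqs: Dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_lengths.items():
        seqs[chrom] = bases[rng.integers(0, 4, size=length)]

    zones = []
    for site in cfg.planted:
        lo, hi = _sanitize_zone(cfg, site)
        lo = max(1, lo)
        hi = min(cfg.chrom_lengths[site.chrom], hi)
        zones.append((site.chrom, site.strand, lo, hi))
        # sense-strand A would extend a read's poly(A) stretch or mimic
        # internal priming; replace with the other three bases
        banned = "A" if site.strand == "+" else "T"
        arr = seqs[site.chrom]
        repl = np.array([b for b in "ACGT" if b != banned])
        for pos in range(lo - 1, hi):
            if arr[pos] == banned:
                arr[pos] = repl[rng.integers(0, 3)]

    islets = []
    for chrom, start in cfg.decoys:
        end = start + cfg.decoy_islet_length - 1
        for zchrom, _strand, lo, hi in zones:
            if zchrom == chrom and start <= hi and end >= lo:
                raise ValueError(
                    f"decoy islet {chrom}:{start}-{end} overlaps a planted site window"
                )
        seqs[chrom][start - 1 : end] = "A"
        islets.append((chrom, start, end))

    genome = GenomeIndex({c: "".join(s) for c, s in seqs.items()})
    return genome, {"decoy_islets": islets, "sanitized_zones": zones}


# ---------------------------------------------------------------- annotation


def _mirror(ivs: Sequence[Tuple[int, int]], length: int) -> List[Tuple[int, int]]:
    return sorted((length - 1 - e, length - 1 - s) for s, e in ivs)


def make_annotation(cfg: SimulationConfig) -> Tuple[Dict[str, List[TranscriptModel]], dict]:
    """Transcript models for the configured genes, plus a truth record."""
    by_gene: Dict[str, List[TranscriptModel]] = {}
    truth = {}
    for gene in cfg.genes:
        template = _TEMPLATES[gene.template]
        length = template["length"]
        transcripts = []
        for i, t in enumerate(template["transcripts"], start=1):
            exons, cds = t["exons"], t["cds"]
            if gene.strand == "-":
                exons, cds = _mirror(exons, length), _mirror(cds, length)
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene.gene_id}.{i}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    exons=[(gene.start + s, gene.start + e) for s, e in exons],
                    cds=[(gene.start + s, gene.start + e) for s, e in cds],
                )
            )
        by_gene[gene.gene_id] = transcripts
        truth[gene.gene_id] = {
            "span": (gene.start, gene.start + length - 1),
            "strand": gene.strand,
            "template": gene.template,
        }
    return by_gene, truth


def write_gff3(by_gene: Dict[str, List[TranscriptModel]], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, transcripts in by_gene.items():
            chrom = transcripts[0].chrom
            strand = transcripts[0].strand
            lo = min(t.span[0] for t in transcripts)
            hi = max(t.span[1] for t in transcripts)
            fh.write(f"{chrom}\tsim\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={gene_id}\n")
            for t in transcripts:
                s, e = t.span
                fh.write(
                    f"{chrom}\tsim\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for xs, xe in t.exons:
                    fh.write(
                        f"{chrom}\tsim\texon\t{xs}\t{xe}\t.\t{strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for cs, ce in t.cds:
                    fh.write(
                        f"{chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\t"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------- reads


@dataclass
class SimulatedReads:
    reads: List[RawRead]
    truth_tags: List[PolyATag]  # one per non-decoy read, the planted coordinate
    sam_text: str  # intended alignments of the trimmed reads
    decoy_read_ids: List[str]
    summary: Dict[str, int]


def _apply_errors(rng, seq: str, rate: float, protect_tail: int = 2) -> str:
    """Uniform substitutions; the last bases before the tail stay intact so the
    poly(A) stretch boundary is exactly the cleavage site."""
    if rate <= 0 or len(seq) <= protect_tail:
        return seq
    arr = list(seq)
    n = len(arr) - protect_tail
    hits = np.where(rng.random(n) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(cfg: SimulationConfig) -> SimulatedReads:
    """Generate PAT-seq reads (and decoys) with per-read alignment truth.

    For each planted site, cleavage coordinates are drawn around the site
    (discretized normal, sd ``cleavage_sd``, clipped at 3 sigma); each read is
    the ``read_body_length`` nt of sense sequence ending at its coordinate
    plus a poly(A) tail, emitted per ``read_type``. Decoy reads are primed off
    genomic A-islets, so their apparent cleavage site sits just upstream of
    the islet. The SAM text records where each trimmed read aligns.
    """
    genome, genome_truth = make_genome(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    reads: List[RawRead] = []
    tags: List[PolyATag] = []
    sam_lines: List[str] = []
    decoy_ids: List[str] = []
    for chrom, length in cfg.chrom_lengths.items():
        sam_lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")

    clip = int(np.floor(3 * cfg.cleavage_sd))
    counter = 0

    def emit(chrom: str, strand: str, coord: int, sample: str, is_decoy: bool) -> None:
        nonlocal counter
        counter += 1
        rid = ("decoy" if is_decoy else "read") + f"_{counter:06d}_{sample}"
        body_len = cfg.read_body_length
        if strand == "+":
            lo, hi = coord - body_len + 1, coord
            if lo < 1:
                logger.warning("read at %s:%d clipped at chromosome start", chrom, coord)
                lo = 1
            body = genome.fetch(chrom, lo, hi, "+")
            ref_pos = lo
        else:
            lo, hi = coord, coord + body_len - 1
            if hi > cfg.chrom_lengths[chrom]:
                logger.warning("read at %s:%d clipped at chromosome end", chrom, coord)
                hi = cfg.chrom_lengths[chrom]
            body = genome.fetch(chrom, lo, hi, "-")
            ref_pos = lo
        body = _apply_errors(rng, body, cfg.error_rate)
        tail_len = int(rng.integers(cfg.tail_length_range[0], cfg.tail_length_range[1] + 1))
        sense = body + "A" * tail_len
        if cfg.read_type == "T":
            seq = reverse_complement(sense)
        else:
            seq = sense
        if cfg.low_quality_fraction > 0 and rng.random() < cfg.low_quality_fraction:
            qual = "#" * len(seq)  # Q2: fails the default quality filter
        else:
            qual = "I" * len(seq)
        reads.append(RawRead(rid, seq, qual))
        if is_decoy:
            decoy_ids.append(rid)
        else:
            tags.append(PolyATag(chrom, strand, coord, sample=sample, read_id=rid))
        # alignment of the trimmed body: A-reads align sense, T-reads antisense
        sense_is_forward = strand == "+"
        read_is_forward = sense_is_forward == (cfg.read_type == "A")
        flag = 0 if read_is_forward else 16
        ref_seq = body if sense_is_forward else reverse_complement(body)
        sam_lines.append(
            f"{rid}\t{flag}\t{chrom}\t{ref_pos}\t42\t{len(body)}M\t*\t0\t0\t"
            f"{ref_seq}\t{'I' * len(body)}"
        )

    for site in cfg.planted:
        for sample in cfg.samples:
            n = site.counts.get(sample, 0)
            if n == 0:
                continue
            offsets = np.clip(
                np.rint(rng.normal(0.0, cfg.cleavage_sd, size=n)).astype(int),
                -clip,
                clip,
            )
            for off in offsets:
                emit(site.chrom, site.strand, site.site + off, sample, is_decoy=False)

    for chrom, islet_start, _islet_end in genome_truth["decoy_islets"]:
        for sample in cfg.samples:
            per_sample = cfg.decoy_reads_per_site // len(cfg.samples)
            for _ in range(per_sample):
                # oligo(dT) anneals on the islet: apparent cleavage just upstream
                emit(chrom, "+", islet_start - 1, sample, is_decoy=True)

    summary = {
        "reads": len(reads),
        "truth_tags": len(tags),
        "decoy_reads": len(decoy_ids),
    }
    return SimulatedReads(reads, tags, "\n".join(sam_lines) + "\n", decoy_ids, summary)


# ---------------------------------------------------------------- count tables


def simulate_trend_tables(
    n_genes: int,
    n_per_group: int = 200,
    n_groups: int = 2,
    n_pacs: int = 2,
    proximal_probs: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> List[np.ndarray]:
    """Count tables for trend-test calibration.

    Under the null every group draws from the same isoform proportions
    (uniform by default). With ``proximal_probs`` (one probability of the
    proximal = shortest isoform per group, e.g. (0.8, 0.2)) a proportion
    shift is planted; the remaining mass is split evenly over the other
    isoforms.
    """
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_genes):
        rows = []
        for g in range(n_groups):
            if proximal_probs is None:
                p = np.full(n_pacs, 1.0 / n_pacs)
            else:
                p0 = proximal_probs[g]
                p = np.full(n_pacs, (1.0 - p0) / (n_pacs - 1))
                p[0] = p0
            rows.append(rng.multinomial(n_per_group, p))
        tables.append(np.array(rows))
    return tables


# ---------------------------------------------------------------- output


def write_dataset(cfg: SimulationConfig, outdir) -> Dict[str, str]:
    """Materialize a full dataset (FASTA/GFF3/FASTQ/SAM/BED/TSV) on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genome_truth = make_genome(cfg)
    by_gene, _ = make_annotation(cfg)
    sim = simulate_reads(cfg)

    paths = {k: str(outdir / v) for k, v in {
        "genome": "genome.fa",
        "annotation": "annotation.gff3",
        "reads": "reads.fastq",
        "alignments": "alignments.sam",
        "truth_tags": "truth_tags.bed",
        "truth_pacs": "truth_pacs.tsv",
    }.items()}

    with open(paths["genome"], "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 1, genome.lengths[chrom])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_gff3(by_gene, paths["annotation"])
    with open(paths["reads"], "w") as fh:
        for r in sim.reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
    with open(paths["alignments"], "w") as fh:
        fh.write(sim.sam_text)
    from papacall.read_prep import write_tag_bed

    write_tag_bed(sim.truth_tags, paths["truth_tags"])
    with open(paths["truth_pacs"], "w") as fh:
        fh.write("chrom\tstrand\tsite\tgene_id\tregion\t" + "\t".join(cfg.samples) + "\n")
        for site in cfg.planted:
            counts = "\t".join(str(site.counts.get(s, 0)) for s in cfg.samples)
            fh.write(
                f"{site.chrom}\t{site.strand}\t{site.site}\t{site.gene_id or '.'}\t"
                f"{site.region or '.'}\t{counts}\n"
            )
    return paths
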