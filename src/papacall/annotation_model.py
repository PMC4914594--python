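"""Refined gene models for poly(A)-site annotation.

A gene with several annotated transcripts has no single exon/intron/UTR
structure, so a cleavage site falling where transcripts disagree cannot be
attributed to one region. This module collapses a gene's transcripts into a
unique per-base model in which every base where the transcripts' structural
labels differ (or where only a subset of transcripts has coverage) is marked
AMB (ambiguous), and the 3' end is extended downstream — by a fixed length
when a 3'UTR is annotated, otherwise by the genome-wide average 3'UTR
length — so that authentic 3'UTR cleavage sites are not misclassified as
intergenic.

Coordinates are 1-based inclusive throughout (GFF convention); BED output is
converted at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

# per-base region codes
LBL_5UTR = 1
LBL_CDS = 2
LBL_INTRON = 3
LBL_3UTR = 4
LBL_AMB = 5
LBL_NONCODING = 6  # transcript without CDS; mapped to 3UTR in refined models

LABEL_NAMES = {
    LBL_5UTR: "5UTR",
    LBL_CDS: "CDS",
    LBL_INTRON: "intron",
    LBL_3UTR: "3UTR",
    LBL_AMB: "AMB",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One annotated transcript: exon and CDS structure on the genome."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]] = field(default_factory=list)
    utr5: List[Tuple[int, int]] = field(default_factory=list)
    utr3: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS {cs}-{ce} outside exons")
        if not self.utr3:
            self.utr3 = self._derive_utr(three_prime=True)
        if not self.utr5:
            self.utr5 = self._derive_utr(three_prime=False)

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def has_annotated_utr3(self) -> bool:
        return bool(self.cds) and bool(self.utr3)

    def utr3_length(self) -> int:
        return sum(e - s + 1 for s, e in self.utr3)

    def _derive_utr(self, three_prime: bool) -> List[Tuple[int, int]]:
        """Exonic bases strand-downstream (3') or -upstream (5') of the CDS."""
        if not self.cds:
            return []
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        # genomic side of the requested UTR
        right_side = (three_prime and self.strand == "+") or (
            not three_prime and self.strand == "-"
        )
        out: List[Tuple[int, int]] = []
        for s, e in self.exons:
            if right_side:
                lo = max(s, cds_hi + 1)
                if lo <= e:
                    out.append((lo, e))
            else:
                hi = min(e, cds_lo - 1)
                if s <= hi:
                    out.append((s, hi))
        return out

    def label_array(self, span_start: int, span_end: int) -> np.ndarray:
        """Per-base labels over [span_start, span_end]; 0 where not covered."""
        n = span_end - span_start + 1
        arr = np.zeros(n, dtype=np.uint8)
        lo, hi = self.span
        a = max(lo, span_start) - span_start
        b = min(hi, span_end) - span_start
        if a <= b:
            arr[a : b + 1] = LBL_INTRON  # transcript body default; exons overwrite
        base_exon = LBL_NONCODING if not self.cds else LBL_3UTR
        for s, e in self.exons:
            a, b = self._clip(s, e, span_start, span_end)
            if a is not None:
                arr[a : b + 1] = base_exon
        if self.cds:
            for spans, code in ((self.utr5, LBL_5UTR), (self.utr3, LBL_3UTR), (self.cds, LBL_CDS)):
                for s, e in spans:
                    a, b = self._clip(s, e, span_start, span_end)
                    if a is not None:
                        arr[a : b + 1] = code
        return arr

    @staticmethod
    def _clip(s: int, e: int, lo: int, hi: int):
        a, b = max(s, lo), min(e, hi)
        if a > b:
            return None, None
        return a - lo, b - lo


@dataclass
class RefinedGeneModel:
    """The unique per-base model of one gene after AMB merging and 3' extension."""

    gene_id: str
    chrom: str
    strand: str
    labels: np.ndarray  # uint8 codes over the extended span
    original_span: Tuple[int, int]
    extended_span: Tuple[int, int]
    extension_length: int
    annotated_3utr_present: bool

    def label_at(self, pos: int) -> Optional[str]:
        lo, hi = self.extended_span
        if not lo <= pos <= hi:
            return None
        return LABEL_NAMES[int(self.labels[pos - lo])]


class GenomeIndex:
    """Random access to genome sequence with strand-aware retrieval.

    Intervals are 1-based inclusive and clipped to [1, chromosome length];
    minus-strand requests return the reverse complement.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chromosomes(self) -> List[str]:
        return list(self._seqs)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = self.lengths[chrom]
        start, end = max(1, start), min(n, end)
        if start > end:
            return ""
        seq = self._seqs[chrom][start - 1 : end]
        return reverse_complement(seq) if strand == "-" else seq


def load_annotation(gff3_path: str) -> Dict[str, List[TranscriptModel]]:
    """Parse a GFF3 file into TranscriptModels grouped by gene id.

    One TranscriptModel per mRNA/transcript feature; genes without transcript
    children, and transcripts with unresolvable structure or unknown strand,
    are skipped with a warning.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        logger.warning("annotation %s contains no features", gff3_path)
        return {}
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for gene in db.features_of_type("gene"):
        transcripts: List[TranscriptModel] = []
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            if mrna.strand not in "+-":
                logger.warning("transcript %s has unknown strand; skipped", mrna.id)
                continue
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            if not exons:
                logger.warning("transcript %s has no exons; skipped", mrna.id)
                continue
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            utr5 = [
                (f.start, f.end) for f in db.children(mrna, featuretype="five_prime_UTR")
            ]
            utr3 = [
                (f.start, f.end) for f in db.children(mrna, featuretype="three_prime_UTR")
            ]
            transcripts.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    gene_id=gene.id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                    utr5=sorted(utr5),
                    utr3=sorted(utr3),
                )
            )
        if transcripts:
            by_gene[gene.id] = transcripts
        else:
            logger.warning("gene %s has no usable transcripts; skipped", gene.id)
    return by_gene


def average_utr3_length(transcripts: Iterable[TranscriptModel]) -> int:
    """Mean annotated 3'UTR length over coding transcripts, rounded half up."""
    lengths = [t.utr3_length() for t in transcripts if t.has_annotated_utr3]
    if not lengths:
        raise ValueError(
            "no transcript carries an annotated 3'UTR; supply fallback_extension_nt"
        )
    mean = sum(lengths) / len(lengths)
    return int(np.floor(mean + 0.5))


def _flatten(by_gene) -> List[TranscriptModel]:
    if isinstance(by_gene, dict):
        return [t for ts in by_gene.values() for t in ts]
    return list(by_gene)


def build_refined_models(
    transcripts_by_gene: Mapping[str, Sequence[TranscriptModel]],
    fixed_extension_nt: int = 120,
    fallback_extension_nt: Optional[int] = None,
    truncate_at_neighbors: bool = True,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> Dict[str, RefinedGeneModel]:
    """Collapse each gene's transcripts into a unique model and extend its 3' end.

    A base is AMB when the gene's transcripts disagree about its label or when
    only a subset of them covers it. The extension (labeled 3UTR) uses
    ``fixed_extension_nt`` downstream of genes with an annotated 3'UTR and
    ``fallback_extension_nt`` (default: genome-wide average 3'UTR length)
    otherwise. With ``truncate_at_neighbors`` the extension stops one base
    before the nearest downstream original gene span on either strand.
    """
    all_transcripts = _flatten(transcripts_by_gene)
    gene_spans: Dict[str, Tuple[str, str, int, int]] = {}
    for gene_id, ts in transcripts_by_gene.items():
        lo = min(t.span[0] for t in ts)
        hi = max(t.span[1] for t in ts)
        gene_spans[gene_id] = (ts[0].chrom, ts[0].strand, lo, hi)

    if fallback_extension_nt is None:
        needs_fallback = any(
            not any(t.has_annotated_utr3 for t in ts)
            for ts in transcripts_by_gene.values()
        )
        if needs_fallback:
            fallback_extension_nt = average_utr3_length(all_transcripts)

    # original spans per chromosome for neighbor truncation (strand-blind)
    spans_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, _strand, lo, hi in gene_spans.values():
        spans_by_chrom.setdefault(chrom, []).append((lo, hi))

    models: Dict[str, RefinedGeneModel] = {}
    for gene_id, ts in transcripts_by_gene.items():
        chrom, strand, lo, hi = gene_spans[gene_id]
        arrays = np.stack([t.label_array(lo, hi) for t in ts])
        arrays[arrays == LBL_NONCODING] = LBL_3UTR
        if len(ts) == 1:
            merged = arrays[0].copy()
        else:
            merged = arrays[0].copy()
            disagree = (arrays != merged[None, :]).any(axis=0)
            merged[disagree] = LBL_AMB
        if (merged == 0).any():
            # defensive: span is the union of transcript spans so 0 cannot remain
            raise AssertionError(f"{gene_id}: uncovered bases in gene span")

        has_utr3 = any(t.has_annotated_utr3 for t in ts)
        ext = fixed_extension_nt if has_utr3 else int(fallback_extension_nt or 0)

        if truncate_at_neighbors and ext > 0:
            if strand == "+":
                nearest = min(
                    (s for s, e in spans_by_chrom[chrom] if s > hi), default=None
                )
                if nearest is not None:
                    ext = min(ext, max(0, nearest - 1 - hi))
            else:
                nearest = max(
                    (e for s, e in spans_by_chrom[chrom] if e < lo), default=None
                )
                if nearest is not None:
                    ext = min(ext, max(0, lo - 1 - nearest))
        if chrom_lengths is not None and chrom in chrom_lengths:
            if strand == "+":
                ext = min(ext, chrom_lengths[chrom] - hi)
            else:
                ext = min(ext, lo - 1)
        ext = max(0, ext)

        pad = np.full(ext, LBL_3UTR, dtype=np.uint8)
        if strand == "+":
            labels = np.concatenate([merged, pad])
            extended = (lo, hi + ext)
        else:
            labels = np.concatenate([pad, merged])
            extended = (lo - ext, hi)
        models[gene_id] = RefinedGeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            labels=labels,
            original_span=(lo, hi),
            extended_span=extended,
            extension_length=ext,
            annotated_3utr_present=has_utr3,
        )
    return models


class ModelIndex:
    """Interval index over refined gene models for position classification."""

    def __init__(
        self,
        models: Mapping[str, RefinedGeneModel] | Iterable[RefinedGeneModel],
        chromosomes: Optional[Iterable[str]] = None,
    ):
        if isinstance(models, Mapping):
            models = models.values()
        self.models = list(models)
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._chroms = set(chromosomes) if chromosomes is not None else None
        for m in self.models:
            lo, hi = m.extended_span
            key = (m.chrom, m.strand)
            self._trees.setdefault(key, IntervalTree()).addi(lo, hi + 1, m)
            if self._chroms is not None and m.chrom not in self._chroms:
                raise KeyError(f"model {m.gene_id} on unknown chromosome {m.chrom!r}")

    def known_chrom(self, chrom: str) -> bool:
        if self._chroms is not None:
            return chrom in self._chroms
        return any(c == chrom for c, _ in self._trees)

    def classify(self, chrom: str, strand: str, pos: int) -> Tuple[str, Optional[str]]:
        if not self.known_chrom(chrom):
            raise KeyError(f"unknown chromosome {chrom!r}")
        tree = self._trees.get((chrom, strand))
        hits = [iv.data for iv in tree.at(pos)] if tree is not None else []
        if not hits:
            return "intergenic", None
        # a gene whose original span covers the position beats extension-only hits
        originals = [m for m in hits if m.original_span[0] <= pos <= m.original_span[1]]
        chosen = min(
            originals or hits, key=lambda m: (m.extended_span[1] - m.extended_span[0], m.gene_id)
        )
        return chosen.label_at(pos), chosen.gene_id


def classify_position(
    models, chrom: str, strand: str, pos: int
) -> Tuple[str, Optional[str]]:
    """Region label of a 1-based genomic position on the given strand.

    ``models`` may be a prebuilt :class:`ModelIndex` (preferred in loops) or
    any collection of RefinedGeneModels. Positions covered by no strand-matched
    model are intergenic.
    """
    index = models if isinstance(models, ModelIndex) else ModelIndex(models)
    return index.classify(chrom, strand, pos)


def hypothetical_gene(
    site: int, flank_nt: int = 250, chrom_length: Optional[int] = None
) -> Tuple[int, int]:
    """Display interval (site - flank, site + flank) around an intergenic site.

    Intergenic regions can span tens of kilobases, so an intergenic cleavage
    site is given a fixed symmetric window that stands in for a gene model.
    Clipped to the chromosome when its length is known.
    """
    lo = max(1, site - flank_nt)
    hi = site + flank_nt
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def export_sequences(
    genome: GenomeIndex,
    pacs: Optional[Sequence] = None,
    models: Optional[Mapping[str, RefinedGeneModel]] = None,
    mode: str = "site_flank",
    upstream_nt: int = 50,
    downstream_nt: int = 50,
    region: Optional[str] = None,
    annotation_version: str = "extended",
):
    """Strand-aware FASTA records around PACs or over gene spans.

    Modes: ``site_flank`` — window [-upstream, +downstream] around each PAC's
    dominant cleavage site (site base included); ``pac_span`` — each PAC's own
    span, optionally restricted to a region label; ``gene`` — whole gene spans
    under the original or extended annotation. Minus-strand sequences are
    reverse complemented.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    if mode in ("site_flank", "pac_span"):
        if pacs is None:
            raise ValueError(f"mode {mode!r} requires pacs")
        for pac in pacs:
            if region is not None and pac.region != region:
                continue
            if mode == "site_flank":
                site = pac.dominant_site
                if pac.strand == "+":
                    lo, hi = site - upstream_nt, site + downstream_nt
                else:
                    lo, hi = site - downstream_nt, site + upstream_nt
            else:
                lo, hi = pac.start, pac.end
            seq = genome.fetch(pac.chrom, lo, hi, pac.strand)
            header = f"{pac.name} {pac.chrom}:{lo}-{hi}({pac.strand}) region={pac.region}"
            records.append(
                SeqRecord(Seq(seq), id=pac.name, description=header)
            )
    elif mode == "gene":
        if models is None:
            raise ValueError("mode 'gene' requires models")
        for gene_id, m in models.items():
            lo, hi = (
                m.extended_span if annotation_version == "extended" else m.original_span
            )
            seq = genome.fetch(m.chrom, lo, hi, m.strand)
            header = f"{gene_id} {m.chrom}:{lo}-{hi}({m.strand}) version={annotation_version}"
            records.append(SeqRecord(Seq(seq), id=gene_id, description=header))
    else:
        raise ValueError(f"unknown export mode {mode!r}")
    if not records:
        logger.warning("sequence export selected no records")
    return records


def write_refined_gff3(models: Mapping[str, RefinedGeneModel], path: str) -> None:
    """Write refined models as GFF3; AMB blocks are typed ``sequence_conflict``."""
    type_map = {
        LBL_5UTR: "five_prime_UTR",
        LBL_CDS: "CDS",
        LBL_INTRON: "intron",
        LBL_3UTR: "three_prime_UTR",
        LBL_AMB: "sequence_conflict",
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, m in models.items():
            lo, hi = m.extended_span
            fh.write(
                f"{m.chrom}\tpapacall\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={gene_id};extension={m.extension_length}\n"
            )
            # run-length encode the label array into typed child features
            labels = m.labels
            start = 0
            for i in range(1, len(labels) + 1):
                if i == len(labels) or labels[i] != labels[start]:
                    fh.write(
                        f"{m.chrom}\tpapacall\t{type_map[int(labels[start])]}\t"
                        f"{lo + start}\t{lo + i - 1}\t.\t{m.strand}\t.\tParent={gene_id}\n"
                    )
                    start = i
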