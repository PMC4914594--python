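"""Read preparation for poly(A)-tag sequencing.

PAT-seq evidence of a cleavage event is an oligo(dT)-primed read that carries
the poly(A) tail remnant either as a T-stretch at the 5' end (T-reads, the
reverse complement of the mRNA 3' end) or as an A-stretch at the 3' end
(A-reads, sense orientation). This module quality-filters reads, finds and
trims the stretches, auto-detects which kind a library contains, and converts
alignments of the trimmed reads into poly(A) tags (PATs): single-read
observations of a cleavage coordinate.

The cleavage coordinate is taken as the last transcribed base of the mRNA,
not the first base of the poly(A) tail.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Tuple

logger = logging.getLogger(__name__)


@dataclass
class RawRead:
    id: str
    sequence: str
    quality: Optional[str] = None  # Phred+33

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")


@dataclass
class TrimmedRead:
    id: str
    sequence: str
    stretch_type: str  # "A" or "T"
    stretch_length: int
    original_length: int
    quality: Optional[str] = None


@dataclass(frozen=True)
class PolyATag:
    """One cleavage-site observation from one uniquely mapped read."""

    chrom: str
    strand: str
    coord: int  # 1-based position of the last transcribed nucleotide
    sample: str = ""
    read_id: str = ""


@dataclass
class TrimSummary:
    input: int = 0
    no_stretch: int = 0
    too_short: int = 0
    kept: int = 0

    def conserved(self) -> bool:
        return self.input == self.no_stretch + self.too_short + self.kept


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path) -> Iterator[RawRead]:
    """Stream FASTA or FASTQ (optionally gzipped) as RawReads."""
    from Bio import SeqIO

    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        fmt = "fastq" if first == "@" else "fasta"
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield RawRead(rec.id, str(rec.seq).upper(), qual)


def quality_filter(
    reads: Iterable[RawRead],
    min_quality: int = 20,
    min_percent: float = 80.0,
    counts: Optional[dict] = None,
) -> Iterator[RawRead]:
    """Keep reads in which >= min_percent of bases reach Phred >= min_quality.

    FASTA reads (no qualities) pass unchanged; a warning is emitted once.
    Malformed quality strings reject the read. When ``counts`` is given it
    accumulates {"input", "kept", "failed", "no_quality"}.
    """
    warned = False
    for read in reads:
        if counts is not None:
            counts["input"] = counts.get("input", 0) + 1
        if read.quality is None:
            if not warned:
                logger.warning("reads lack quality strings; quality filter skipped")
                warned = True
            if counts is not None:
                counts["no_quality"] = counts.get("no_quality", 0) + 1
            yield read
            continue
        try:
            quals = [ord(c) - 33 for c in read.quality]
            if any(q < 0 or q > 93 for q in quals):
                raise ValueError("phred value out of range")
        except ValueError:
            if counts is not None:
                counts["failed"] = counts.get("failed", 0) + 1
            continue
        good = sum(q >= min_quality for q in quals)
        if 100.0 * good / len(quals) >= min_percent:
            if counts is not None:
                counts["kept"] = counts.get("kept", 0) + 1
            yield read
        elif counts is not None:
            counts["failed"] = counts.get("failed", 0) + 1


def find_stretch(
    read: RawRead | TrimmedRead | str,
    end: str,
    base: str,
    min_stretch: int = 8,
    max_mismatch: int = 1,
    anchor: int = 3,
) -> Optional[Tuple[int, int]]:
    """Locate an end-anchored homopolymer stretch.

    Walks inward from the given read end, tolerating up to ``max_mismatch``
    non-matching bases (leading offset included); the stretch ends at the last
    matching base before the budget is exhausted. Reported when it contains at
    least ``min_stretch`` matching bases and starts within ``anchor`` bases of
    the end. Returns the (start, end) indices (0-based inclusive, in read
    orientation) of the span to trim, or None.
    """
    seq = read if isinstance(read, str) else read.sequence
    if min_stretch < 1:
        raise ValueError("min_stretch must be >= 1")
    n = len(seq)
    order = range(n) if end == "5prime" else range(n - 1, -1, -1)
    mismatches = 0
    last_match = None
    first_match = None
    matched = 0
    for i in order:
        if seq[i] == base:
            last_match = i
            if first_match is None:
                first_match = i
            matched += 1
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
    if last_match is None or first_match is None:
        return None
    # matches past the final matching base do not count; recount within span
    if end == "5prime":
        span = (0, last_match)
        anchored = first_match < anchor
    else:
        span = (last_match, n - 1)
        anchored = (n - 1 - first_match) < anchor
    matched_in_span = sum(
        1 for i in range(span[0], span[1] + 1) if seq[i] == base
    )
    if not anchored or matched_in_span < min_stretch:
        return None
    return span


def detect_read_type(
    reads: Iterable[RawRead],
    min_stretch: int = 8,
    sample_size: int = 10_000,
) -> str:
    """Auto-detect whether a library is T-reads or A-reads.

    Counts qualifying 5' T-stretches vs 3' A-stretches over the first
    ``sample_size`` reads and returns the majority type. A tie or a library
    with no stretches at all raises: the caller must specify the type.
    """
    n_t = n_a = n = 0
    for read in reads:
        if n >= sample_size:
            break
        n += 1
        if find_stretch(read, "5prime", "T", min_stretch) is not None:
            n_t += 1
        if find_stretch(read, "3prime", "A", min_stretch) is not None:
            n_a += 1
    if n == 0:
        raise ValueError("no reads to sample")
    if n_t == 0 and n_a == 0:
        raise ValueError("no read carries an A or T stretch; specify the read type")
    if n_t == n_a:
        raise ValueError(
            f"ambiguous library: {n_t} T-stretch vs {n_a} A-stretch reads; "
            "specify the read type explicitly"
        )
    return "T" if n_t > n_a else "A"


def trim_reads(
    reads: Iterable[RawRead],
    read_type: str,
    min_stretch: int = 8,
    min_len: int = 25,
    max_mismatch: int = 1,
    anchor: int = 3,
    summary: Optional[TrimSummary] = None,
) -> Iterator[TrimmedRead]:
    """Trim the poly(A)/(T) stretch off each read; drop unusable reads.

    Reads without a qualifying stretch, and reads shorter than ``min_len``
    after trimming, are discarded and counted in ``summary``.
    """
    if read_type not in ("A", "T"):
        raise ValueError("read_type must be 'A' or 'T'")
    end = "5prime" if read_type == "T" else "3prime"
    for read in reads:
        if summary is not None:
            summary.input += 1
        span = find_stretch(read, end, read_type, min_stretch, max_mismatch, anchor)
        if span is None:
            if summary is not None:
                summary.no_stretch += 1
            continue
        s, e = span
        if read_type == "T":
            trimmed_seq = read.sequence[e + 1 :]
            trimmed_qual = read.quality[e + 1 :] if read.quality else None
        else:
            trimmed_seq = read.sequence[:s]
            trimmed_qual = read.quality[:s] if read.quality else None
        if len(trimmed_seq) < min_len:
            if summary is not None:
                summary.too_short += 1
            continue
        if summary is not None:
            summary.kept += 1
        yield TrimmedRead(
            id=read.id,
            sequence=trimmed_seq,
            stretch_type=read_type,
            stretch_length=e - s + 1,
            original_length=len(read.sequence),
            quality=trimmed_qual,
        )


def infer_cleavage_site(
    aln,
    read_type: str,
    sample: str = "",
    min_mapq: int = 10,
    chrom_lengths=None,
) -> Optional[PolyATag]:
    """Convert one alignment of a trimmed read into a poly(A) tag.

    Only unique primary alignments count (mapped, not secondary or
    supplementary, MAPQ >= ``min_mapq``). An A-read keeps the mRNA sense: on
    the genome + strand the cleavage site is the alignment's reference end and
    the tag is on +; reverse-complement alignment puts the site at the
    reference start on -. T-reads are the reverse complement of the mRNA, so
    the conventions mirror.
    """
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
        return None
    if aln.mapping_quality < min_mapq:
        return None
    chrom = aln.reference_name
    if chrom_lengths is not None and chrom not in chrom_lengths:
        raise KeyError(f"alignment on unknown chromosome {chrom!r}")
    ref_start = aln.reference_start + 1  # pysam is 0-based
    ref_end = aln.reference_end  # exclusive 0-based == inclusive 1-based
    forward = not aln.is_reverse
    if read_type == "A":
        if forward:
            coord, strand = ref_end, "+"
        else:
            coord, strand = ref_start, "-"
    elif read_type == "T":
        if forward:
            coord, strand = ref_start, "-"
        else:
            coord, strand = ref_end, "+"
    else:
        raise ValueError("read_type must be 'A' or 'T'")
    return PolyATag(
        chrom=chrom, strand=strand, coord=coord, sample=sample, read_id=aln.query_name
    )


def tags_from_alignments(
    path, read_type: str, sample: str = "", min_mapq: int = 10
) -> List[PolyATag]:
    """Read a SAM/BAM file and return the poly(A) tags of its unique alignments."""
    import pysam

    tags = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for aln in fh:
            tag = infer_cleavage_site(
                aln, read_type, sample=sample, min_mapq=min_mapq, chrom_lengths=lengths
            )
            if tag is not None:
                tags.append(tag)
    return tags


def write_tag_bed(tags: Iterable[PolyATag], path) -> None:
    """Write tags as 6-column BED (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.chrom}\t{t.coord - 1}\t{t.coord}\t{t.read_id}\t1\t{t.strand}\n")


def read_tag_bed(path, sample: str = "") -> List[PolyATag]:
    tags = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name, _score, strand = fields[:6]
            if int(end) != int(start) + 1:
                raise ValueError("tag BED intervals must be single-base")
            tags.append(
                PolyATag(
                    chrom=chrom,
                    strand=strand,
                    coord=int(end),
                    sample=sample,
                    read_id=name,
                )
            )
    return tags


def write_trimmed(reads: Iterable[TrimmedRead], path) -> int:
    """Write trimmed reads as FASTQ when qualities are present, else FASTA."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            if r.quality is not None:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
            else:
                fh.write(f">{r.id}\n{r.sequence}\n")
            n += 1
    return n
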