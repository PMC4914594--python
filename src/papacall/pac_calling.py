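"""Poly(A)-site cluster (PAC) calling.

Cleavage positions observed by individual poly(A) tags scatter over a few
bases around a preferred site (microheterogeneity). Tags are therefore
clustered with a snowball rule — a cluster keeps growing while the next
distinct coordinate lies within a maximum gap (default 24 nt) of its nearest
member, i.e. single-linkage chaining — after discarding tags that look like
internal-priming artifacts: sites whose surrounding genomic sequence is
A-rich enough that the oligo(dT) primer could have annealed to genomic
adenosines rather than a real poly(A) tail.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from papacall.annotation_model import GenomeIndex, ModelIndex, classify_position
from papacall.read_prep import PolyATag

logger = logging.getLogger(__name__)


@dataclass
class PAC:
    """A poly(A) site cluster with its per-coordinate tag histogram."""

    chrom: str
    strand: str
    start: int
    end: int
    histogram: Dict[int, int]  # coordinate -> tag count
    sample_counts: Dict[str, int] = field(default_factory=dict)
    region: str = ""
    gene_id: Optional[str] = None

    @property
    def total(self) -> int:
        return sum(self.histogram.values())

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def dominant_site(self) -> int:
        return dominant_site(self)

    @property
    def dominant_count(self) -> int:
        return self.histogram[self.dominant_site]

    @property
    def name(self) -> str:
        return f"PAC:{self.total}@{self.dominant_site}"

    @property
    def is_intergenic(self) -> bool:
        return self.region == "intergenic"


def is_internal_priming(
    genome: GenomeIndex,
    chrom: str,
    strand: str,
    site: int,
    flank: int = 10,
    min_run: int = 6,
    min_window_count: int = 7,
    window: int = 10,
) -> bool:
    """True when the sequence around a putative site is A-rich.

    The sense-strand sequence of the window [site-flank, site+flank] (21 nt by
    default, site base included, reverse complemented on the minus strand) is
    flagged when it contains a run of >= ``min_run`` consecutive A, or any
    ``window``-nt stretch with >= ``min_window_count`` A. Such sites are likely
    oligo(dT) mispriming on genomic adenosines, not genuine cleavage sites.
    """
    seq = genome.fetch(chrom, site - flank, site + flank, strand)
    run = 0
    for c in seq:
        run = run + 1 if c == "A" else 0
        if run >= min_run:
            return True
    if len(seq) >= window:
        count = sum(1 for c in seq[:window] if c == "A")
        if count >= min_window_count:
            return True
        for i in range(window, len(seq)):
            count += (seq[i] == "A") - (seq[i - window] == "A")
            if count >= min_window_count:
                return True
    else:
        if sum(1 for c in seq if c == "A") >= min_window_count:
            return True
    return False


def filter_internal_priming(
    tags: Iterable[PolyATag], genome: GenomeIndex, **kwargs
) -> Tuple[List[PolyATag], int]:
    """Drop tags at internally primed coordinates; returns (kept, n_removed).

    Applied per tag coordinate before clustering. Decisions are cached per
    (chrom, strand, coordinate) since many tags share a coordinate.
    """
    cache: Dict[Tuple[str, str, int], bool] = {}
    kept, removed = [], 0
    for t in tags:
        key = (t.chrom, t.strand, t.coord)
        if key not in cache:
            cache[key] = is_internal_priming(genome, t.chrom, t.strand, t.coord, **kwargs)
        if cache[key]:
            removed += 1
        else:
            kept.append(t)
    return kept, removed


def snowball_cluster(
    tags: Sequence[PolyATag], max_dist: int = 24
) -> List[PAC]:
    """Cluster tags of one chromosome strand into PACs by snowball chaining.

    Distinct coordinates are walked in order; the cluster keeps absorbing the
    next coordinate while it lies within ``max_dist`` of the cluster's current
    nearest member, so two tags share a PAC iff they are connected by a chain
    of gaps each <= ``max_dist``.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if not tags:
        return []
    chroms = {(t.chrom, t.strand) for t in tags}
    if len(chroms) > 1:
        raise ValueError("snowball_cluster expects tags of one chromosome strand")
    chrom, strand = next(iter(chroms))

    hist: Counter = Counter()
    samples: Dict[int, Counter] = defaultdict(Counter)
    for t in tags:
        hist[t.coord] += 1
        samples[t.coord][t.sample] += 1

    coords = sorted(hist)
    pacs: List[PAC] = []
    cluster = [coords[0]]
    for c in coords[1:]:
        if c - cluster[-1] <= max_dist:
            cluster.append(c)
        else:
            pacs.append(_make_pac(chrom, strand, cluster, hist, samples))
            cluster = [c]
    pacs.append(_make_pac(chrom, strand, cluster, hist, samples))
    return pacs


def _make_pac(chrom, strand, coords, hist, samples) -> PAC:
    sample_counts: Counter = Counter()
    for c in coords:
        sample_counts.update(samples[c])
    return PAC(
        chrom=chrom,
        strand=strand,
        start=coords[0],
        end=coords[-1],
        histogram={c: hist[c] for c in coords},
        sample_counts=dict(sample_counts),
    )


def dominant_site(pac: PAC) -> int:
    """Coordinate with the most tags; ties go to the smallest coordinate."""
    if not pac.histogram:
        raise ValueError("empty PAC histogram")
    return min(pac.histogram, key=lambda c: (-pac.histogram[c], c))


def annotate_pac(pac: PAC, models) -> PAC:
    """Attach the region label and host gene decided at the dominant site."""
    label, gene_id = classify_position(models, pac.chrom, pac.strand, pac.dominant_site)
    pac.region = label
    pac.gene_id = gene_id
    return pac


def annotate_pacs(pacs: Iterable[PAC], models) -> List[PAC]:
    index = models if isinstance(models, ModelIndex) else ModelIndex(models)
    return [annotate_pac(p, index) for p in pacs]


def merge_samples(
    tags_by_sample: Mapping[str, Sequence[PolyATag]] | Iterable[Tuple[str, Sequence[PolyATag]]],
    max_dist: int = 24,
) -> List[PAC]:
    """Cluster the pooled tags of several samples, keeping per-sample counts.

    Clustering runs once on the pooled coordinates so every sample shares the
    same PAC boundaries; each PAC records how many tags each sample
    contributed (zero-count samples stay listed). Accepts a mapping or
    (label, tags) pairs; a duplicated sample label across inputs is rejected.
    """
    items = list(tags_by_sample.items()) if isinstance(tags_by_sample, Mapping) \
        else list(tags_by_sample)
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicated sample label")
    pooled: List[PolyATag] = []
    for label, tags in items:
        for t in tags:
            pooled.append(
                PolyATag(t.chrom, t.strand, t.coord, sample=label, read_id=t.read_id)
            )
    pacs: List[PAC] = []
    by_cs: Dict[Tuple[str, str], List[PolyATag]] = defaultdict(list)
    for t in pooled:
        by_cs[(t.chrom, t.strand)].append(t)
    for key in sorted(by_cs):
        pacs.extend(snowball_cluster(by_cs[key], max_dist=max_dist))
    for pac in pacs:
        for label in labels:
            pac.sample_counts.setdefault(label, 0)
    return pacs


def call_pacs(
    tags: Iterable[PolyATag],
    genome: Optional[GenomeIndex] = None,
    models=None,
    max_dist: int = 24,
    ip_kwargs: Optional[dict] = None,
) -> Tuple[List[PAC], dict]:
    """Full calling chain: internal-priming filter -> clustering -> annotation.

    Returns (PACs sorted by position, report counts). The genome is required
    for the internal-priming filter and the models for annotation; either may
    be None to skip that step.
    """
    tags = list(tags)
    report = {"tags_in": len(tags), "internal_priming": 0}
    if genome is not None:
        tags, removed = filter_internal_priming(tags, genome, **(ip_kwargs or {}))
        report["internal_priming"] = removed
    report["tags_kept"] = len(tags)
    by_sample: Dict[str, List[PolyATag]] = defaultdict(list)
    for t in tags:
        by_sample[t.sample].append(t)
    pacs = merge_samples(by_sample, max_dist=max_dist) if tags else []
    if models is not None:
        annotate_pacs(pacs, models)
    report["pacs"] = len(pacs)
    pacs.sort(key=lambda p: (p.chrom, p.start, p.strand))
    return pacs, report


# ---------------------------------------------------------------- I/O

PAC_TSV_COLUMNS = ["pac_id", "chrom", "strand", "start", "end", "dominant", "region", "gene_id"]


def write_pac_tsv(pacs: Sequence[PAC], path, samples: Optional[Sequence[str]] = None) -> None:
    """PAC table as TSV with one count column per sample."""
    if samples is None:
        seen = []
        for p in pacs:
            for s in p.sample_counts:
                if s not in seen:
                    seen.append(s)
        samples = seen
    with open(path, "w") as fh:
        fh.write("\t".join(PAC_TSV_COLUMNS + ["total"] + list(samples)) + "\n")
        for p in pacs:
            row = [
                p.name,
                p.chrom,
                p.strand,
                str(p.start),
                str(p.end),
                str(p.dominant_site),
                p.region or ".",
                p.gene_id or ".",
                str(p.total),
            ] + [str(p.sample_counts.get(s, 0)) for s in samples]
            fh.write("\t".join(row) + "\n")


def read_pac_tsv(path) -> List[PAC]:
    """Read a PAC table written by :func:`write_pac_tsv` (or user-supplied)."""
    pacs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fixed = len(PAC_TSV_COLUMNS) + 1
        samples = header[fixed:]
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            start, end, dominant = int(f[3]), int(f[4]), int(f[5])
            counts = {s: int(v) for s, v in zip(samples, f[fixed:])}
            total = int(f[8])
            # per-coordinate histogram is not stored in the TSV; put all mass
            # at the dominant site so width/dominant invariants still hold
            hist = {dominant: total}
            if start != dominant:
                hist[start] = 0
            if end != dominant:
                hist[end] = 0
            pacs.append(
                PAC(
                    chrom=f[1],
                    strand=f[2],
                    start=start,
                    end=end,
                    histogram=hist,
                    sample_counts=counts,
                    region=f[6] if f[6] != "." else "",
                    gene_id=f[7] if f[7] != "." else None,
                )
            )
    return pacs


def write_pac_histogram_tsv(pacs: Sequence[PAC], path) -> None:
    with open(path, "w") as fh:
        fh.write("pac_id\tchrom\tstrand\tcoord\tcount\n")
        for p in pacs:
            for coord in sorted(p.histogram):
                fh.write(f"{p.name}\t{p.chrom}\t{p.strand}\t{coord}\t{p.histogram[coord]}\n")


def write_pac_bed12(pacs: Sequence[PAC], path) -> None:
    """BED12-like track with one block per cleavage coordinate."""
    with open(path, "w") as fh:
        for p in pacs:
            coords = sorted(p.histogram)
            starts = ",".join(str(c - p.start) for c in coords)
            sizes = ",".join("1" for _ in coords)
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.name}\t{min(1000, p.total)}\t"
                f"{p.strand}\t{p.dominant_site - 1}\t{p.dominant_site}\t0\t"
                f"{len(coords)}\t{sizes}\t{starts}\n"
            )
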