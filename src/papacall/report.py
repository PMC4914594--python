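"""Run reports: read fate, base composition and hexamers around cleavage sites.

A healthy poly(A)-site library shows the canonical nucleotide profile around
the cleavage site (U-rich upstream, A-rich just downstream of the poly(A)
signal) and AATAAA-family hexamers enriched in the ~50 nt upstream; these
summaries let a user sanity-check a run without external tools.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from papacall.annotation_model import GenomeIndex
from papacall.pac_calling import PAC


def nucleotide_composition(
    genome: GenomeIndex, pacs: Sequence[PAC], flank: int = 50
) -> pd.DataFrame:
    """Per-position base frequencies in [-flank, +flank] around dominant sites.

    Position 0 is the cleavage site, negative positions upstream in the
    transcript sense. Rows sum to 1 where sequence was available.
    """
    positions = list(range(-flank, flank + 1))
    counts = {pos: Counter() for pos in positions}
    for pac in pacs:
        site = pac.dominant_site
        if pac.strand == "+":
            seq = genome.fetch(pac.chrom, site - flank, site + flank, "+")
            offset = max(0, flank - (site - 1))
        else:
            seq = genome.fetch(pac.chrom, site - flank, site + flank, "-")
            offset = max(0, flank - (genome.lengths[pac.chrom] - site))
        for i, base in enumerate(seq):
            counts[positions[i + offset]][base] += 1
    rows = []
    for pos in positions:
        total = sum(counts[pos].values())
        rows.append(
            {
                "position": pos,
                **{
                    b: (counts[pos][b] / total if total else 0.0)
                    for b in "ACGT"
                },
                "n": total,
            }
        )
    return pd.DataFrame(rows)


def top_hexamers(
    genome: GenomeIndex,
    pacs: Sequence[PAC],
    window: Tuple[int, int] = (-50, -1),
    top_n: int = 10,
) -> List[Tuple[str, int]]:
    """Most frequent hexamers in the given window upstream of dominant sites."""
    counter: Counter = Counter()
    for pac in pacs:
        site = pac.dominant_site
        if pac.strand == "+":
            seq = genome.fetch(pac.chrom, site + window[0], site + window[1], "+")
        else:
            seq = genome.fetch(pac.chrom, site - window[1], site - window[0], "-")
        for i in range(len(seq) - 5):
            counter[seq[i : i + 6]] += 1
    return counter.most_common(top_n)


def parse_groups(text: str) -> Dict[str, List[str]]:
    """Parse a sample-group config: one ``group=sample1,sample2`` line each."""
    groups: Dict[str, List[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed group line: {line!r}")
        name, samples = line.split("=", 1)
        name = name.strip()
        if name in groups:
            raise ValueError(f"duplicate group {name!r}")
        groups[name] = [s.strip() for s in samples.split(",") if s.strip()]
        if not groups[name]:
            raise ValueError(f"group {name!r} has no samples")
    if not groups:
        raise ValueError("no groups defined")
    return groups
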