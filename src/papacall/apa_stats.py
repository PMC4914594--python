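"""Statistics for alternative polyadenylation between conditions.

Two bespoke tests operate on PAC count tables:

* a 3'UTR lengthening/shortening trend test — for a gene with k PACs in its
  3'UTR observed in s sample groups, the s x k count table is scored with row
  coordinates 1..s (group order) and column coordinates the 3'UTR isoform
  lengths; the count-weighted Pearson correlation r measures linear trend and
  M2 = (n - 1) r**2 is referred to chi-square with 1 df (the classical trend
  statistic for singly/doubly ordered tables). r > 0 with groups ordered
  (group1, group2, ...) means longer isoforms gain weight along that order.

* a non-canonical APA-site switching detector — for each gene the two
  most-supported PACs (PA1, PA2, not both in the 3'UTR) are screened with
  five criteria: minimum distance, minimum gene-level support, reciprocal
  >K-fold dominance reversal between two groups, a minimum count difference
  in each switching library, and a significant Fisher's exact test on the
  2 x 2 table of PA1/PA2 counts in the two groups.

Utility exports produce gene x sample and per-gene numbered PAC x sample
count matrices for external differential-expression / differential-usage
tools, TPM normalization, Benjamini-Hochberg adjustment, and poly(A)-signal
(AATAAA and 1-nt variants) scanning.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- matrices


def pac_count_frame(pacs: Sequence, samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """PAC x sample raw count DataFrame (rows indexed by PAC name)."""
    if samples is None:
        seen: List[str] = []
        for p in pacs:
            for s in p.sample_counts:
                if s not in seen:
                    seen.append(s)
        samples = seen
    data = {s: [p.sample_counts.get(s, 0) for p in pacs] for s in samples}
    return pd.DataFrame(data, index=[p.name for p in pacs])


def normalize_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tags-per-million scaling: each column rescaled to sum to 1e6.

    All-zero columns are left at zero with a warning (no tags to scale).
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = matrix.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("columns with zero total left unnormalized: %s",
                       list(matrix.columns[zero]))
    scale = np.where(zero, 0.0, 1e6 / np.where(zero, 1.0, totals))
    return matrix * scale


def gene_expression_matrix(pacs: Sequence, flank_nt: int = 250) -> pd.DataFrame:
    """Gene x sample PAT totals for count-based differential-expression tools.

    3'-end tag counts are quantitative for mRNA abundance, so a gene's
    expression is the sum of its PACs' tags. Intergenic PACs are grouped under
    hypothetical-gene ids (chrom:site-flank..site+flank around the dominant
    site).
    """
    from papacall.annotation_model import hypothetical_gene

    rows: Dict[str, Dict[str, int]] = {}
    samples: List[str] = []
    for p in pacs:
        if p.gene_id:
            gid = p.gene_id
        else:
            lo, hi = hypothetical_gene(p.dominant_site, flank_nt)
            gid = f"{p.chrom}:{lo}-{hi}"
        row = rows.setdefault(gid, {})
        for s, c in p.sample_counts.items():
            if s not in samples:
                samples.append(s)
            row[s] = row.get(s, 0) + c
    frame = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=samples)
    return frame.fillna(0).astype(int)


def pac_usage_matrix(pacs: Sequence, min_pacs: int = 2) -> pd.DataFrame:
    """Numbered per-gene PAC x sample counts for differential-usage tools.

    Rows are ``gene:NNN`` with PACs numbered along the genome; genes with
    fewer than ``min_pacs`` PACs are dropped (no usage change is definable).
    """
    by_gene: Dict[str, List] = {}
    samples: List[str] = []
    for p in pacs:
        if not p.gene_id:
            continue
        by_gene.setdefault(p.gene_id, []).append(p)
        for s in p.sample_counts:
            if s not in samples:
                samples.append(s)
    rows = {}
    for gid in sorted(by_gene):
        gene_pacs = sorted(by_gene[gid], key=lambda p: p.start)
        if len(gene_pacs) < min_pacs:
            continue
        for i, p in enumerate(gene_pacs, start=1):
            rows[f"{gid}:{i:03d}"] = {s: p.sample_counts.get(s, 0) for s in samples}
    frame = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=samples)
    return frame.fillna(0).astype(int)


# ---------------------------------------------------------------- trend test


@dataclass
class TrendResult:
    gene_id: str
    statistic: float  # M2 = (n-1) r^2, chi-square 1 df
    r: float
    p: float
    adjusted_p: float = float("nan")
    direction: str = ""  # lengthening / shortening / none, along group order
    n: int = 0

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "M2": self.statistic,
            "r": self.r,
            "p": self.p,
            "adjusted_p": self.adjusted_p,
            "direction": self.direction,
            "n": self.n,
        }


def utr_trend_test(
    counts,
    lengths: Sequence[float],
    gene_id: str = "",
    min_total: int = 10,
) -> TrendResult:
    """Trend test for 3'UTR lengthening/shortening over ordered sample groups.

    ``counts`` is an s x k table (groups x 3'UTR PACs, s >= 2, k >= 2) and
    ``lengths`` the k 3'UTR isoform lengths used as column scores; columns are
    sorted by length internally. Row scores are the group indices 1..s in the
    order supplied, so the sign of r (and the direction label) is relative to
    that order: r > 0 means later groups shift weight to longer isoforms
    (lengthening).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an s x k table with s >= 2 groups and k >= 2 PACs")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape[0] != table.shape[1]:
        raise ValueError("one length per PAC column required")
    if np.unique(lengths).size < 2:
        raise ValueError("constant 3'UTR lengths: trend scores degenerate")
    zero_rows = np.where(table.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise ValueError(f"group(s) {zero_rows.tolist()} have zero counts for {gene_id or 'gene'}")

    order = np.argsort(lengths, kind="stable")
    table = table[:, order]
    col_scores = lengths[order]
    s = table.shape[0]
    row_scores = np.arange(1, s + 1, dtype=float)

    n = table.sum()
    if n < min_total:
        raise ValueError(f"total count {int(n)} below minimum {min_total}")

    w = table / n
    mx = (w.sum(axis=1) * row_scores).sum()
    my = (w.sum(axis=0) * col_scores).sum()
    cov = (w * np.outer(row_scores - mx, col_scores - my)).sum()
    vx = (w.sum(axis=1) * (row_scores - mx) ** 2).sum()
    vy = (w.sum(axis=0) * (col_scores - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        r = 0.0
    else:
        r = float(cov / np.sqrt(vx * vy))
    r = float(np.clip(r, -1.0, 1.0))
    m2 = (n - 1) * r * r
    p = float(stats.chi2.sf(m2, df=1)) if m2 > 0 else 1.0
    direction = "lengthening" if r > 0 else ("shortening" if r < 0 else "none")
    return TrendResult(gene_id=gene_id, statistic=float(m2), r=r, p=p,
                       direction=direction, n=int(n))


def trend_test_genes(
    pacs: Sequence,
    groups: Mapping[str, Sequence[str]],
    min_total: int = 10,
    pool_replicates: bool = True,
) -> pd.DataFrame:
    """Run the trend test on every gene with >= 2 PACs in its 3'UTR.

    ``groups`` maps group name -> sample labels, in the biological order that
    defines the direction labels. Replicates within a group are pooled by
    default; with ``pool_replicates=False`` each sample becomes its own row in
    group order. Isoform length for a PAC is taken as its dominant site's
    distance from the gene's 5'-most 3'UTR PAC (relative length ordering is
    all the statistic uses). Genes failing preconditions are skipped with the
    reason recorded.
    """
    by_gene: Dict[str, List] = {}
    for p in pacs:
        if p.gene_id and p.region == "3UTR":
            by_gene.setdefault(p.gene_id, []).append(p)

    group_names = list(groups)
    results: List[dict] = []
    skipped: List[Tuple[str, str]] = []
    for gid in sorted(by_gene):
        gene_pacs = sorted(by_gene[gid], key=lambda p: p.dominant_site)
        if len(gene_pacs) < 2:
            skipped.append((gid, "fewer than two 3'UTR PACs"))
            continue
        strand = gene_pacs[0].strand
        # distance along transcription converts dominant sites to isoform length scores
        if strand == "+":
            origin = gene_pacs[0].dominant_site
            lengths = [p.dominant_site - origin for p in gene_pacs]
        else:
            origin = gene_pacs[-1].dominant_site
            lengths = [origin - p.dominant_site for p in gene_pacs]
        if pool_replicates:
            rows = [
                [sum(p.sample_counts.get(s, 0) for s in groups[g]) for p in gene_pacs]
                for g in group_names
            ]
        else:
            rows = [
                [p.sample_counts.get(s, 0) for p in gene_pacs]
                for g in group_names
                for s in groups[g]
            ]
        try:
            res = utr_trend_test(rows, lengths, gene_id=gid, min_total=min_total)
        except ValueError as exc:
            skipped.append((gid, str(exc)))
            continue
        results.append(res.as_row())

    frame = pd.DataFrame(
        results,
        columns=["gene_id", "M2", "r", "p", "adjusted_p", "direction", "n"],
    )
    if len(frame):
        frame["adjusted_p"] = adjust_pvalues(frame["p"].tolist())
    frame.attrs["skipped"] = skipped
    return frame


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method.upper() not in ("BH", "FDR_BH", "BENJAMINI-HOCHBERG"):
        raise ValueError(f"unsupported adjustment method {method!r}")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1].tolist()


# ---------------------------------------------------------------- switching


def fisher_exact_2x2(a: int, b: int, c: int, d: int, two_sided: bool = True) -> float:
    """Fisher's exact test p for the 2 x 2 table [[a, b], [c, d]].

    Two-sided p sums the probabilities of all tables (fixed margins) no more
    likely than the observed one. An all-zero table carries no information and
    returns p = 1 with a warning.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) == 0:
        logger.warning("Fisher test on an all-zero table; p = 1")
        return 1.0
    _, p = stats.fisher_exact(
        [[a, b], [c, d]], alternative="two-sided" if two_sided else "greater"
    )
    return float(p)


@dataclass
class SwitchingResult:
    gene_id: str
    pa1: str
    pa2: str
    pa1_region: str
    pa2_region: str
    distance: int
    counts: Dict[str, Tuple[int, int]]  # group -> (PA1 count, PA2 count)
    fisher_p: float
    criteria: Dict[str, bool] = field(default_factory=dict)
    group_pair: Tuple[str, str] = ("", "")

    @property
    def is_switching(self) -> bool:
        return all(self.criteria.values())

    def as_row(self) -> dict:
        row = {
            "gene_id": self.gene_id,
            "PA1": self.pa1,
            "PA2": self.pa2,
            "PA1_region": self.pa1_region,
            "PA2_region": self.pa2_region,
            "distance": self.distance,
            "fisher_p": self.fisher_p,
            "group1": self.group_pair[0],
            "group2": self.group_pair[1],
        }
        for g, (c1, c2) in self.counts.items():
            row[f"{g}_PA1"] = c1
            row[f"{g}_PA2"] = c2
        row.update({f"pass_{k}": v for k, v in self.criteria.items()})
        return row


def _ratio_exceeds(num: int, den: int, k: float) -> bool:
    """num:den > k-fold; zero denominator with positive numerator is infinite."""
    if num == 0 and den == 0:
        return False
    if den == 0:
        return True
    return num / den > k


def detect_switching(
    pacs: Sequence,
    groups: Mapping[str, Sequence[str]],
    min_distance: int = 100,
    min_gene_count: int = 10,
    min_fold: float = 2.0,
    min_difference: int = 5,
    alpha: float = 0.05,
    report_all: bool = False,
) -> List[SwitchingResult]:
    """Detect non-canonical APA-site switching genes between two sample groups.

    Per gene, the two most-supported PACs (PA1, PA2) are tested; genes whose
    top two PACs both sit in the 3'UTR are excluded (that regime belongs to
    the 3'UTR trend test). A gene switches between groups when all five hold:

    1. the dominant sites of PA1 and PA2 are >= ``min_distance`` nt apart;
    2. total gene read count exceeds ``min_gene_count``;
    3. PA1:PA2 > ``min_fold`` in one group and PA2:PA1 > ``min_fold`` in the
       other (reciprocal dominance reversal);
    4. |PA1 - PA2| exceeds ``min_difference`` within each of the two groups;
    5. Fisher's exact p on the 2 x 2 PAC-by-group count table < ``alpha``.

    With more than two groups every ordered pair is screened and the first
    passing pair is reported. ``report_all`` keeps non-switching genes with
    their per-criterion diagnostics.
    """
    if len(groups) < 2:
        raise ValueError("need at least two sample groups")
    by_gene: Dict[str, List] = {}
    for p in pacs:
        if p.gene_id:
            by_gene.setdefault(p.gene_id, []).append(p)

    group_names = list(groups)
    out: List[SwitchingResult] = []
    for gid in sorted(by_gene):
        gene_pacs = by_gene[gid]
        if len(gene_pacs) < 2:
            continue
        top2 = sorted(gene_pacs, key=lambda p: (-p.total, p.start))[:2]
        pa1, pa2 = top2
        if pa1.region == "3UTR" and pa2.region == "3UTR":
            continue
        gcounts = {
            g: (
                sum(pa1.sample_counts.get(s, 0) for s in groups[g]),
                sum(pa2.sample_counts.get(s, 0) for s in groups[g]),
            )
            for g in group_names
        }
        gene_total = sum(p.total for p in gene_pacs)
        distance = abs(pa1.dominant_site - pa2.dominant_site)

        best: Optional[SwitchingResult] = None
        for g1, g2 in itertools.permutations(group_names, 2):
            a, b = gcounts[g1]
            c, d = gcounts[g2]
            crit = {
                "distance": distance >= min_distance,
                "gene_count": gene_total > min_gene_count,
                "reciprocal_fold": _ratio_exceeds(a, b, min_fold)
                and _ratio_exceeds(d, c, min_fold),
                "difference": abs(a - b) > min_difference and abs(c - d) > min_difference,
            }
            fisher_p = fisher_exact_2x2(a, b, c, d)
            crit["fisher"] = fisher_p < alpha
            res = SwitchingResult(
                gene_id=gid,
                pa1=pa1.name,
                pa2=pa2.name,
                pa1_region=pa1.region,
                pa2_region=pa2.region,
                distance=distance,
                counts=gcounts,
                fisher_p=fisher_p,
                criteria=crit,
                group_pair=(g1, g2),
            )
            if res.is_switching:
                best = res
                break
            if best is None:
                best = res
        if best is not None and (best.is_switching or report_all):
            out.append(best)
    return out


# ---------------------------------------------------------------- signals

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CANONICAL_SIGNAL = "AATAAA"


def polya_signal_variants(canonical: str = CANONICAL_SIGNAL) -> List[str]:
    """The canonical hexamer plus all single-substitution variants (19 total)."""
    patterns = [canonical]
    for i, ref in enumerate(canonical):
        for alt in "ACGT":
            if alt != ref:
                patterns.append(canonical[:i] + alt + canonical[i + 1 :])
    return patterns


def _expand_iupac(pattern: str) -> str:
    try:
        return "".join(
            f"[{_IUPAC[c]}]" if len(_IUPAC[c]) > 1 else _IUPAC[c]
            for c in pattern.upper()
        )
    except KeyError as exc:
        raise ValueError(f"invalid pattern letter {exc.args[0]!r}") from None


def scan_polya_signals(
    sequence: str,
    site_index: Optional[int] = None,
    window: Optional[Tuple[int, int]] = None,
    extra_patterns: Sequence[str] = (),
) -> List[Tuple[str, int]]:
    """Scan for AATAAA, its 1-nt variants, and user patterns near a site.

    ``site_index`` is the 0-based index of the cleavage site within
    ``sequence``; positions are then reported relative to it (otherwise as
    0-based sequence offsets). ``window`` (relative start, end of pattern
    starts, inclusive) restricts the scan. Overlapping matches are all
    reported; user patterns may use IUPAC degenerate letters.
    """
    seq = sequence.upper()
    patterns = polya_signal_variants() + [p.upper() for p in extra_patterns]
    hits: List[Tuple[str, int]] = []
    for pat in patterns:
        regex = re.compile("(?=(" + _expand_iupac(pat) + "))")
        for m in regex.finditer(seq):
            pos = m.start()
            rel = pos - site_index if site_index is not None else pos
            if window is not None and not (window[0] <= rel <= window[1]):
                continue
            hits.append((pat, rel))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits
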