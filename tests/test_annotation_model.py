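"""Gene-model refinement: AMB regions, 3' extensions, position classification."""

import numpy as np
import pytest

from papacall import annotation_model as am
from papacall.annotation_model import (
    GenomeIndex,
    ModelIndex,
    TranscriptModel,
    average_utr3_length,
    build_refined_models,
    classify_position,
    hypothetical_gene,
    load_annotation,
)


def tmodel(tid, exons, cds=(), strand="+", gene="G", chrom="Chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=list(exons), cds=list(cds),
    )


# ---------------------------------------------------------------- GFF parsing

GFF_TWO_MRNA = """##gff-version 3
Chr1\tx\tgene\t1000\t3000\t.\t+\t.\tID=gene1
Chr1\tx\tmRNA\t1000\t3000\t.\t+\t.\tID=t1;Parent=gene1
Chr1\tx\texon\t1000\t1600\t.\t+\t.\tParent=t1
Chr1\tx\texon\t2000\t3000\t.\t+\t.\tParent=t1
Chr1\tx\tCDS\t1200\t1600\t.\t+\t0\tParent=t1
Chr1\tx\tCDS\t2000\t2600\t.\t+\t0\tParent=t1
Chr1\tx\tmRNA\t1000\t3000\t.\t+\t.\tID=t2;Parent=gene1
Chr1\tx\texon\t1000\t3000\t.\t+\t.\tParent=t2
Chr1\tx\tCDS\t1200\t2600\t.\t+\t0\tParent=t2
"""


def test_load_annotation_two_transcript_gene(tmp_path):
    path = tmp_path / "two.gff3"
    path.write_text(GFF_TWO_MRNA)
    by_gene = load_annotation(path)
    assert list(by_gene) == ["gene1"]
    ts = by_gene["gene1"]
    assert len(ts) == 2
    t1 = next(t for t in ts if t.transcript_id == "t1")
    assert t1.exons == [(1000, 1600), (2000, 3000)]
    assert t1.utr3 == [(2601, 3000)]
    assert t1.utr5 == [(1000, 1199)]


def test_load_annotation_noncoding_transcript_retained(tmp_path):
    gff = (
        "##gff-version 3\n"
        "Chr1\tx\tgene\t100\t500\t.\t+\t.\tID=g\n"
        "Chr1\tx\tmRNA\t100\t500\t.\t+\t.\tID=t;Parent=g\n"
        "Chr1\tx\texon\t100\t500\t.\t+\t.\tParent=t\n"
    )
    path = tmp_path / "nc.gff3"
    path.write_text(gff)
    by_gene = load_annotation(path)
    t = by_gene["g"][0]
    assert not t.is_coding
    # non-coding exonic bases are mapped to 3UTR in the refined model
    models = build_refined_models({"g": [t]}, fallback_extension_nt=50)
    labels = {models["g"].label_at(p) for p in range(100, 501)}
    assert labels == {"3UTR"}


def test_load_annotation_empty_file(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text("##gff-version 3\n")
    assert load_annotation(path) == {}


# ---------------------------------------------------------------- UTR length


def test_average_utr3_length_mean_and_rounding():
    a = tmodel("a", [(1, 200), (301, 500)], cds=[(50, 200), (301, 400)])
    assert a.utr3_length() == 100
    b = tmodel("b", [(1, 400)], cds=[(50, 200)])
    assert b.utr3_length() == 200
    assert average_utr3_length([a, b]) == 150
    assert average_utr3_length([a]) == 100
    # round half up: lengths 10 and 11 -> mean 10.5 -> 11
    c = tmodel("c", [(1, 110)], cds=[(1, 100)])
    d = tmodel("d", [(1, 111)], cds=[(1, 100)])
    assert average_utr3_length([c, d]) == 11


def test_average_utr3_length_requires_annotated_utr():
    t = tmodel("t", [(1, 100)], cds=[(1, 100)])
    with pytest.raises(ValueError, match="fallback"):
        average_utr3_length([t])


# ---------------------------------------------------------------- refinement


def test_extension_arithmetic_plus_strand():
    t = tmodel("t", [(1000, 2000)], cds=[(1100, 1800)])
    models = build_refined_models({"G": [t]}, fixed_extension_nt=120)
    m = models["G"]
    assert m.original_span == (1000, 2000)
    assert m.extended_span == (1000, 2120)
    assert m.extension_length == 120
    assert m.label_at(2050) == "3UTR"


def test_extension_minus_strand_goes_downstream_left():
    t = tmodel("t", [(1000, 2000)], cds=[(1200, 1900)], strand="-")
    m = build_refined_models({"G": [t]}, fixed_extension_nt=100)["G"]
    assert m.extended_span == (900, 2000)
    assert m.label_at(950) == "3UTR"


def test_gene_without_utr_gets_fallback_extension():
    coding = tmodel("a", [(1, 300)], cds=[(1, 200)], gene="A")  # utr3 = 100
    bare = tmodel("b", [(1000, 1500)], cds=[(1000, 1500)], gene="B")
    models = build_refined_models(
        {"A": [coding], "B": [bare]}, fixed_extension_nt=120,
        truncate_at_neighbors=False,
    )
    assert models["A"].extension_length == 120
    assert models["B"].extension_length == 100  # average annotated 3'UTR length
    assert not models["B"].annotated_3utr_present


def test_extension_truncated_before_downstream_neighbor():
    up = tmodel("u", [(1000, 2000)], cds=[(1100, 1800)], gene="U")
    down = tmodel("d", [(2051, 3000)], cds=[(2100, 2900)], gene="D")
    models = build_refined_models({"U": [up], "D": [down]}, fixed_extension_nt=120)
    assert models["U"].extended_span == (1000, 2050)  # one base before neighbor
    models = build_refined_models(
        {"U": [up], "D": [down]}, fixed_extension_nt=120, truncate_at_neighbors=False
    )
    assert models["U"].extended_span == (1000, 2120)


def test_extension_clipped_at_chromosome_end():
    t = tmodel("t", [(900, 980)], cds=[(900, 950)])
    m = build_refined_models({"G": [t]}, fixed_extension_nt=120,
                             chrom_lengths={"Chr1": 1000})["G"]
    assert m.extended_span == (900, 1000)


def four_transcript_gene():
    """Four transcripts whose disagreements produce exactly four AMB blocks."""
    base = 1000
    mk = lambda tid, exons, cds: tmodel(
        tid,
        [(base + s, base + e) for s, e in exons],
        [(base + s, base + e) for s, e in cds],
        gene="G4",
    )
    t1 = mk("t1", [(0, 299), (400, 699), (800, 1099), (1200, 1599)],
            [(100, 299), (400, 699), (800, 1099), (1200, 1399)])
    t2 = mk("t2", [(50, 299), (800, 1099), (1200, 1599)],
            [(100, 299), (800, 1099), (1200, 1399)])
    t3 = mk("t3", [(0, 299), (400, 699), (800, 1150), (1200, 1599)],
            [(100, 299), (400, 699), (800, 1150), (1200, 1399)])
    t4 = mk("t4", [(0, 299), (400, 699), (800, 1099), (1200, 1499)],
            [(100, 299), (400, 699), (800, 1099), (1200, 1399)])
    return [t1, t2, t3, t4]


def test_four_transcript_gene_defines_four_amb_blocks():
    models = build_refined_models({"G4": four_transcript_gene()},
                                  fixed_extension_nt=0)
    labels = models["G4"].labels
    amb = labels == am.LBL_AMB
    # count maximal AMB runs
    blocks = int(amb[0]) + int(((~amb[:-1]) & amb[1:]).sum())
    assert blocks == 4
    m = models["G4"]
    assert m.label_at(1000 + 500) == "AMB"   # exon-skipping block
    assert m.label_at(1000 + 1125) == "AMB"  # exon-length block
    assert m.label_at(1000 + 25) == "AMB"    # 5' coverage block
    assert m.label_at(1000 + 1550) == "AMB"  # 3' coverage block
    assert m.label_at(1000 + 1450) == "3UTR"  # agreed 3'UTR stays labeled


def test_single_transcript_gene_has_no_amb():
    t = tmodel("t", [(1, 300), (400, 600)], cds=[(50, 300), (400, 500)])
    m = build_refined_models({"G": [t]}, fixed_extension_nt=0)["G"]
    assert not (m.labels == am.LBL_AMB).any()


def test_amb_brute_force_oracle(sim_models, sim_annotation):
    """Per-base: transcripts agreeing -> their label; disagreeing -> AMB."""
    by_gene, _ = sim_annotation
    for gid, m in sim_models.items():
        ts = by_gene[gid]
        lo, hi = m.original_span
        arrays = np.stack([t.label_array(lo, hi) for t in ts])
        arrays[arrays == am.LBL_NONCODING] = am.LBL_3UTR
        got = m.labels[(lo - m.extended_span[0]):(lo - m.extended_span[0]) + (hi - lo + 1)]
        for col in range(hi - lo + 1):
            per_t = set(arrays[:, col].tolist())
            if len(per_t) == 1 and 0 not in per_t:
                assert got[col] == per_t.pop()
            else:
                assert got[col] == am.LBL_AMB


def test_label_map_completeness(sim_models):
    for m in sim_models.values():
        lo, hi = m.extended_span
        assert len(m.labels) == hi - lo + 1
        assert (m.labels > 0).all()


def test_extension_monotonicity():
    ts = {"G4": four_transcript_gene()}
    widths = []
    for ext in (0, 50, 120, 300):
        m = build_refined_models(ts, fixed_extension_nt=ext)["G4"]
        widths.append(m.extended_span[1] - m.extended_span[0])
    assert widths == sorted(widths)


def test_classify_round_trip(sim_models):
    index = ModelIndex(sim_models)
    for m in sim_models.values():
        lo, hi = m.extended_span
        for pos in range(lo, hi + 1, 97):  # sampled stride keeps it fast
            label, gid = index.classify(m.chrom, m.strand, pos)
            assert gid == m.gene_id
            assert label == m.label_at(pos)


def test_classify_intergenic_and_unknown_chrom(sim_models, sim_genome):
    genome, _ = sim_genome
    index = ModelIndex(sim_models, chromosomes=genome.chromosomes)
    assert index.classify("Chr1", "+", 50_000) == ("intergenic", None)
    # opposite strand of a genic position is intergenic too
    assert index.classify("Chr1", "-", 2_500) == ("intergenic", None)
    with pytest.raises(KeyError):
        index.classify("ChrX", "+", 100)


def test_original_span_wins_over_neighbor_extension():
    a = tmodel("a", [(1000, 2000)], cds=[(1100, 1800)], gene="A")
    b = tmodel("b", [(2050, 3000)], cds=[(2100, 2900)], gene="B")
    models = build_refined_models({"A": [a], "B": [b]}, fixed_extension_nt=120,
                                  truncate_at_neighbors=False)
    label, gid = classify_position(models, "Chr1", "+", 2060)
    assert gid == "B"  # inside B's original span, despite A's extension


# ---------------------------------------------------------------- windows


def test_hypothetical_gene_flanks():
    assert hypothetical_gene(17_954_540, 250) == (17_954_290, 17_954_790)
    assert hypothetical_gene(100, 250, chrom_length=50_000) == (1, 350)
    assert hypothetical_gene(42, 0) == (42, 42)


# ---------------------------------------------------------------- sequences


def test_genome_index_clipping_and_revcomp():
    g = GenomeIndex({"c": "ACGTACGTAC"})
    assert g.fetch("c", 1, 4) == "ACGT"
    assert g.fetch("c", -5, 3) == "ACG"
    assert g.fetch("c", 8, 99) == "TAC"
    assert g.fetch("c", 1, 4, "-") == "ACGT"[::-1].translate(
        str.maketrans("ACGT", "TGCA"))
    with pytest.raises(KeyError):
        g.fetch("nope", 1, 2)


def test_export_site_flank_includes_site_base(sim_genome, sim_pacs):
    genome, _ = sim_genome
    pacs, _ = sim_pacs
    pac = next(p for p in pacs if p.strand == "+")
    records = am.export_sequences(genome, pacs=[pac], mode="site_flank",
                                  upstream_nt=10, downstream_nt=10)
    assert len(records[0].seq) == 21
    site_base = genome.fetch(pac.chrom, pac.dominant_site, pac.dominant_site)
    assert str(records[0].seq)[10] == site_base


def test_export_minus_strand_is_reverse_complement(sim_genome, sim_pacs):
    genome, _ = sim_genome
    pacs, _ = sim_pacs
    pac = next(p for p in pacs if p.strand == "-")
    rec = am.export_sequences(genome, pacs=[pac], mode="site_flank",
                              upstream_nt=5, downstream_nt=5)[0]
    site = pac.dominant_site
    plus = genome.fetch(pac.chrom, site - 5, site + 5, "+")
    assert str(rec.seq) == am.reverse_complement(plus)


def test_export_region_filter_can_be_empty(sim_genome, sim_pacs):
    genome, _ = sim_genome
    pacs, _ = sim_pacs
    assert [p for p in pacs if p.region == "intron"] == []
    records = am.export_sequences(genome, pacs=pacs, mode="pac_span",
                                  region="intron")
    assert records == []


def test_export_gene_original_vs_extended(sim_genome, sim_models):
    genome, _ = sim_genome
    ext = am.export_sequences(genome, models=sim_models, mode="gene",
                              annotation_version="extended")
    orig = am.export_sequences(genome, models=sim_models, mode="gene",
                               annotation_version="original")
    by_id = {r.id: r for r in orig}
    for rec in ext:
        assert len(rec.seq) >= len(by_id[rec.id].seq)
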