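import numpy as np
import pysam
import pytest

from papacall import annotation_model as am
from papacall import pac_calling, read_prep
from papacall.simulate import default_config, make_annotation, make_genome, simulate_reads


@pytest.fixture(scope="session")
def sim_config():
    return default_config(seed=1)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    genome, truth = make_genome(sim_config)
    return genome, truth


@pytest.fixture(scope="session")
def sim_annotation(sim_config):
    return make_annotation(sim_config)


@pytest.fixture(scope="session")
def sim_models(sim_annotation, sim_genome):
    by_gene, _ = sim_annotation
    genome, _ = sim_genome
    return am.build_refined_models(by_gene, chrom_lengths=genome.lengths)


@pytest.fixture(scope="session")
def sim_reads(sim_config):
    return simulate_reads(sim_config)


@pytest.fixture(scope="session")
def sim_tags(sim_config, sim_reads, tmp_path_factory):
    """Poly(A) tags recovered from the truth alignments, labeled by sample."""
    sam = tmp_path_factory.mktemp("sam") / "truth.sam"
    sam.write_text(sim_reads.sam_text)
    tags = []
    with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
        for aln in fh:
            sample = aln.query_name.rsplit("_", 1)[1]
            tag = read_prep.infer_cleavage_site(aln, sim_config.read_type, sample=sample)
            if tag is not None:
                tags.append(tag)
    return tags


@pytest.fixture(scope="session")
def sim_pacs(sim_tags, sim_genome, sim_models):
    genome, _ = sim_genome
    index = am.ModelIndex(sim_models, chromosomes=genome.chromosomes)
    pacs, report = pac_calling.call_pacs(sim_tags, genome=genome, models=index)
    return pacs, report


def make_alignment(chrom="Chr1", start0=1000, length=30, reverse=False,
                   mapq=42, secondary=False, supplementary=False, unmapped=False,
                   name="r1", chrom_length=60_000):
    """Build a pysam AlignedSegment for convention tests."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": chrom_length}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "A" * length
    a.reference_id = 0
    a.reference_start = start0
    a.mapping_quality = mapq
    a.cigarstring = f"{length}M"
    a.flag = (16 if reverse else 0) | (256 if secondary else 0) | \
             (2048 if supplementary else 0) | (4 if unmapped else 0)
    return a
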