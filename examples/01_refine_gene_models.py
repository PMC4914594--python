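"""Refining a multi-transcript gene: AMB regions and 3'UTR extension.

Builds a two-transcript gene whose second transcript skips an exon, collapses
it into a unique per-base model, and classifies a few positions. Bases where
the transcripts disagree become AMB — a poly(A) site there cannot be
attributed to one transcript — and the 3' end is extended so downstream
cleavage sites are still called 3'UTR rather than intergenic.
"""

from papacall import TranscriptModel, build_refined_models, classify_position

t1 = TranscriptModel(
    transcript_id="t1", gene_id="gene1", chrom="Chr1", strand="+",
    exons=[(1000, 1600), (2000, 3000)], cds=[(1200, 1600), (2000, 2600)],
)
t2 = TranscriptModel(
    transcript_id="t2", gene_id="gene1", chrom="Chr1", strand="+",
    exons=[(1000, 3000)], cds=[(1200, 2600)],
)

models = build_refined_models({"gene1": [t1, t2]}, fixed_extension_nt=120)
m = models["gene1"]
print(f"original span  : {m.original_span}")
print(f"extended span  : {m.extended_span}  (+{m.extension_length} nt of 3'UTR)")

for pos in (1100, 1400, 1800, 2700, 3050):
    label, gene = classify_position(models, "Chr1", "+", pos)
    print(f"position {pos}: {label} ({gene})")

# 1800 is exonic in t2 but intronic in t1 -> AMB; 3050 lies in the extension,
# so a cleavage site there is still assigned to gene1's 3'UTR.
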