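"""Poly(A)-signal scanning and sequence export around cleavage sites.

Scans the 50 nt upstream of a cleavage site for the canonical AATAAA hexamer
and its 18 single-substitution variants, then exports the flanking sequence
as FASTA records.
"""

from papacall import GenomeIndex, scan_polya_signals
from papacall.annotation_model import export_sequences
from papacall.apa_stats import polya_signal_variants
from papacall.pac_calling import PAC

print(f"{len(polya_signal_variants())} hexamer patterns scanned "
      f"(AATAAA + 1-nt variants)")

# a site at position 61 with the canonical signal 25 nt upstream
seq = "G" * 30 + "AATAAA" + "CTGCTG" * 3 + "CTTGTT" + "T" * 20
genome = GenomeIndex({"Chr1": seq})
site = 61

hits = scan_polya_signals(seq, site_index=site - 1, window=(-50, -1))
for pattern, pos in hits:
    print(f"signal {pattern} at {pos:+d} nt relative to the cleavage site")

pac = PAC("Chr1", "+", site, site, {site: 12}, region="3UTR", gene_id="g")
records = export_sequences(genome, pacs=[pac], mode="site_flank",
                           upstream_nt=20, downstream_nt=5)
for rec in records:
    print(f">{rec.description}\n{rec.seq}")

# the canonical AATAAA sits at -30; the exported window covers
# [-20, +5] around the site (site base included, 26 nt).
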