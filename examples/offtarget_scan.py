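"""Exhaustively enumerate off-target sites for a guide.

Plants decoy sites at 1-6 mismatches (NGG and NAG PAMs) in a synthetic
tetraploid and scans with the default 5-mismatch bound: decoys at <= 5
mismatches are reported, the 6-mismatch decoy is not.
"""

from polyguide import GenomeIndex, fixtures as fx, scan

GUIDE = "GGAGACGAGCACGGTCGCGG"

gene = fx.GeneSpec(exon_lengths=(180, 240), intron_lengths=(120,),
                   guides=(fx.EmbeddedGuide(0, 60, GUIDE, "CGG"),))
f = fx.generate_genome(fx.FixtureSpec(
    seed=7, ploidy=4, chromosome_length=8000, target_gene=gene,
    decoy_sites=(fx.DecoySite(1, "NGG"), fx.DecoySite(2, "NAG"),
                 fx.DecoySite(4, "NGG"), fx.DecoySite(6, "NGG"))))

hits = scan(GUIDE, GenomeIndex(f.chromosomes), max_mismatches=5)
print(f"{len(hits)} sites within 5 mismatches of the guide:")
for h in hits:
    print(f"  {h.chromosome}:{h.start}({h.strand}) {h.site_sequence} "
          f"{h.pam} [{h.pam_kind}] mm={h.n_mismatches} "
          f"at={list(h.mismatch_positions)}")
# The four perfect hits are the allelic copies of the target itself;
# mismatch positions are numbered 1 (PAM-distal) to 20 (PAM-proximal).
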