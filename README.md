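# polyguide

CRISPR/Cas9 design and analysis for **autopolyploid** genomes, where
knocking a gene out means hitting *every* allelic copy. In an
autotetraploid such as cultivated alfalfa (*Medicago sativa*,
2n = 4x = 32), an allele-aware assembly represents each homologous
chromosome as its own sequence with ~1% divergence between allelic
copies, and a workable knockout guide must match all four copies exactly
while having no credible off-target site elsewhere. `polyguide`
implements that whole design-and-validation loop as a Python library
with a thin `polyguide` CLI:

* **Allele location** — find all allelic copies of a target gene from a
  query CDS/mRNA (k-mer anchoring + colinear chaining; exon structure
  from alignment blocks, GT..AG-aware boundary resolution), plus
  depth-ratio copy-number estimation (`round(median depth / haploid
  baseline)`).
* **Guide design** — enumerate every 20-nt protospacer 5′ of an NGG in
  any exon of any copy and rank by: covers all alleles (hard filter), no
  obvious off-target (hard filter), distance to the start codon, GC
  fraction, conserved-exon membership, and 5′-G (satisfiable by
  prepending a G for U6 expression, giving 21-nt vector spacers).
* **Off-target scan** — *exact* enumeration of all genomic sites with
  ≤ K mismatches (default 5) next to an NGG or NAG PAM, via pigeonhole
  seed partition; verified set-equal to brute-force Hamming scanning.
* **PCR-RE screening** — predict the blunt Cas9 cut (between protospacer
  positions 17|18, 3 bp 5′ of the PAM), find IUPAC restriction sites
  overlapping it (e.g. BstUI `CG^CG`), and compute wild-type digest
  bands; edited alleles lose the site and resist digestion.
* **Genotyping** — align Sanger-sequenced amplicon clones to the
  wild-type reference (global, affine gaps), collapse edits into
  mutation-type signatures and classify plants as wild-type / partial /
  null / chimeric; mutagenesis frequency = mutants / transformed calli.
* **Off-target variant filter** — reduce WGS variant calls of edited
  plants to candidate Cas9-induced mutations: SNVs excluded, only indels
  at or near (±2 bp) the −3 position of a predicted non-target site kept,
  with CDS-overlap annotation.
* **Ka/Ks and mutation rate** — Nei–Gojobori (1986) with Jukes–Cantor
  correction (`d = −¾·ln(1 − 4p/3)`), exact pathway averaging, and
  WGD-calibrated mutation rate `μ = Ks/(2T)`.
* **Synthetic fixtures** — seeded generators for tetraploid genomes with
  planted guides/decoys/enzyme sites (with truth tables) and edited
  clone sets, so everything above is testable without downloads.

## Worked example

```python
>>> from polyguide import mutagenesis_frequency, mutation_rate_from_wgd
>>> mutagenesis_frequency(5, 880)     # 5 mutants from 880 calli
0.57
>>> mutagenesis_frequency(26, 1508)
1.72
>>> f"{mutation_rate_from_wgd(0.63, 58e6):.3g}"  # Ks 0.63, 58 Mya WGD
'5.43e-09'
```

Designing against a synthetic tetraploid (see
`examples/design_guides.py` for the full script):

```
located 4 allelic copies
43 candidates, 43 pass the hard filters
  GCGGGAGACGAGCACGGTCG  GC=0.75 dist_to_ATG=  57 coverage=4/4 score=2.028
  GGAGACGAGCACGGTCGCGG  GC=0.75 dist_to_ATG=  60 coverage=4/4 score=2.019
  ...
```

Every listed guide matches all four allelic copies exactly
(`coverage=4/4`) and has no site within 3 mismatches elsewhere in the
genome. The guide `GGAGACGAGCACGGTCGCGG|CGG` carries a BstUI site
(`CGCG`, protospacer positions 16–19) straddling the predicted 17|18
cut, so mutants can be screened on a gel: `examples/pcr_re_screen.py`
prints wild-type bands `[69, 57]` versus an undigested `[124]` for an
amplicon with a 2-bp deletion at the cut.

The other examples cover off-target scanning
(`examples/offtarget_scan.py`), clone genotyping
(`examples/genotype_clones.py`, a four-deletion null mutant) and Ka/Ks
(`examples/kaks_mutation_rate.py`).

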