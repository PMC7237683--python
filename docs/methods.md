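# Methods

## The problem setting

An autotetraploid with tetrasomic inheritance carries four freely
pairing copies of each chromosome. An allele-aware assembly keeps all
four as separate sequences, which changes the CRISPR design problem in
two ways: a knockout guide must match all allelic copies of the target
(any unmatched copy leaves a functional allele), and the on-target
copies themselves appear as four perfect "hits" that must not be
mistaken for off-targets. `polyguide` treats the allele set as a
first-class object and threads it through design, scanning and
screening.

## Allele location (`polyguide.locate`)

Query k-mers (default k = 15) are anchored exactly on each chromosome
and on its reverse complement. Anchors sharing a diagonal
(subject − query offset) merge into candidate exon blocks; blocks are
chained colinearly (query and subject positions both increasing,
anchored length maximised by a small DP), and each diagonal jump in the
chain is an intron. Exon boundaries inside unanchored gaps are resolved
by minimising substitution count on the two flanking diagonals, with
ties broken in favour of a GT..AG intron and then the leftmost split.
Identity is matches over aligned query bases; coverage is aligned bases
over query length. Defaults `min_identity = 0.90`,
`min_query_coverage = 0.80` pass allelic divergence of ~1% with a wide
margin. Two loci are distinct copies whenever their genomic spans do
not overlap; of two overlapping interpretations, the higher
identity × coverage wins.

Limits: the locator assumes substitution-dominated divergence between
query and copies (the autopolyploid allele case). Large insertions in
the genomic copy are handled as introns; deletions longer than the
anchor size in an exon will fragment recovery. Exon boundary resolution
is exact only up to co-optimal splits.

Depth-based copy number is `round(median(depth)/baseline)` (half-up),
with the unrounded ratio reported alongside; the median makes the
estimate robust to ~10% coverage noise.

## Guide design (`polyguide.design`)

Candidates are all 20-mers immediately 5′ of an NGG whose protospacer
lies fully within an exon of any copy (the PAM may extend past the exon
end), on both strands, deduplicated by protospacer sequence. NAG is
never used for on-target design — it only widens the off-target search.
Per candidate:

* `allele_coverage`: exact protospacer+NGG presence in each copy's
  genomic span (both strands).
* `distance_to_start_codon`: CDS offset of the protospacer's 5′-most
  coding base, from the A of ATG.
* `in_conserved_exon`: the containing exon is sequence-identical across
  all copies — a proxy for "functional conserved domain" that needs no
  external protein annotation.

Scoring applies hard filters first — coverage equal to ploidy; the
off-target rule; optionally a strict 5′-G — then ranks by
`w_gc·GC + w_prox·1/(1 + d/L) + w_cons·conserved`, defaults
`w_gc = 1, w_prox = 1, w_cons = 0.5, L = 200 bp`. Proximity and GC are
preferences, not cutoffs, because sgRNA efficacy correlates with but is
not determined by either. The weights are declared defaults, exposed as
`ScoringWeights`. A protospacer that does not start with G is still
usable from a U6 promoter by prepending a G; the designer reports this
`vector_spacer` (21 nt), and `strict_5g=True` restores the hard filter.
"No obvious off-target" defaults to: zero non-allelic hits with ≤ 3
mismatches under either PAM class (`OffTargetRule`, configurable).

## Off-target scanning (`polyguide.offtarget`)

The scan must be exhaustive — a missed site invalidates a "no obvious
off-target" claim — so it uses the pigeonhole principle rather than a
heuristic aligner: a site with ≤ K mismatches against a 20-mer split
into K+1 contiguous seeds contains at least one seed exactly. Seed
occurrences are found by plain string search and every candidate window
is verified by a full Hamming count and PAM check (NGG/NAG; the PAM
contributes no mismatches but must match). `N` in the genome matches no
guide base and satisfies no PAM. Bulges are not modelled. Mismatch
positions are numbered 1 (PAM-distal) to 20 (PAM-proximal). The test
suite asserts set-equality against a numpy sliding-window oracle on
genomes up to 100 kb and the monotonicity hits(K) ⊆ hits(K+1).

`classify_hits` flags hits overlapping any located allelic copy as
on-target and summarises the rest as (mismatches, PAM-class) counts.

## Cut prediction and PCR-RE (`polyguide.restriction`)

SpCas9 is modelled as cutting bluntly between protospacer positions 17
and 18 (3 bp 5′ of the PAM) — the standard convention, and the one
consistent with a CGCG (BstUI) site at protospacer positions 16–19
overlapping the cut. Recognition sites are IUPAC patterns matched on
both strands with each genomic interval reported once; digestion uses
leftmost non-overlapping top-strand cuts, so fragment lengths always
sum to the amplicon length. `disrupted_by_edit` compares site counts
against an unedited reference. Methylation sensitivity, star activity
and partial digestion are out of scope.

## Genotyping (`polyguide.genotype`)

Clones are aligned globally to the wild-type amplicon with affine gaps
(match 2, mismatch −3, open −5, extend −1 — deterministic, declared).
Events outside ±20 bp of the cut are discarded as PCR/sequencing noise;
clones under 70% identity (matches over the longer sequence length) are
flagged unalignable and excluded with a warning rather than
misclassified. Identical alignments collapse to one edit signature.
Classification: wild-type (no edits), partial (wild-type clones plus
1..ploidy−1 types), null (no wild-type, 1..ploidy types), chimeric
(more types than ploidy, or a conflict — either supplied externally,
e.g. residual digested bands, or implied internally when wild-type
clones coexist with ploidy distinct edits). Distinct types are a lower
bound on mutated alleles (`n_mutated_alleles_min`): two alleles can
share an edit, and clone sampling cannot distinguish that case.

Mutagenesis frequency is `100·mutants/calli`, half-up to 2 decimals.

## Variant filtering (`polyguide.variants`)

Candidate Cas9-induced mutations among WGS calls are indels within
±2 bp (configurable `tolerance`; "at or near" has no canonical number,
so the default is logged into output) of the −3 inter-base of a
predicted site that is not the intended target. SNVs and complex
substitutions are excluded; failed-quality and unmatched records are
kept with a reason, never dropped, so record conservation is checkable.
Coding overlap comes from GFF3 CDS intervals (1-based inclusive).

## Ka/Ks and μ (`polyguide.molevol`)

NG86: per codon, each position contributes (synonymous changes)/3
synonymous sites, counting a change to a stop codon as nonsynonymous so
that S + N = 3 × codons exactly. Multi-difference codons average Sd/Nd
over all substitution orders that avoid stop intermediates; if every
order is blocked, all orders are used (each stop-crossing step counted
nonsynonymous). Codons with gaps or ambiguity in either sequence, and
pairs where either codon is a stop, are excluded. Jukes–Cantor
saturation (p ≥ 3/4) yields an explicit `None` with a note, never a
silent NaN. The implementation matches both an exhaustive independent
enumeration (to 1e-10) and Biopython's NG86 in the tests.

μ = Ks/(2T): a WGD of age T separates paralog pairs whose synonymous
divergence accrued along two lineages, hence the factor 2. With
T = 58 My this maps Ks 0.63 → 5.43×10⁻⁹ and Ks 0.65 → 5.60×10⁻⁹ per
site per year.

## Synthetic fixtures (`polyguide.fixtures`)

The generator emulates the structural facts that matter for testing an
allele-aware pipeline: `ploidy` chromosome copies per homologous group;
pairwise allelic divergence defaulting to 10⁻⁴ substitutions/site
(each copy mutates independently from a group ancestor at rate d/2, so
pairwise divergence ≈ d for small d); a target gene embedded at
identical coordinates in every copy (with optional allele-private
substitutions); decoy off-target sites derived from the planted guide
at exact mismatch counts, placed on random strands far (> 2 guide
lengths) from the gene and each other so the truth table is exact; and
enzyme recognition sites written at fixed offsets from the predicted
cut. Background sequence is uniform A/C/G/T with no N, keeping mismatch
truth unambiguous. All coordinates are emitted 1-based inclusive
(GFF3/TSV convention); internal arithmetic is 0-based half-open. Same
seed ⇒ byte-identical FASTA/GFF3/TSV.

Clone sets allocate clones to alleles by largest-remainder rounding of
the sampling proportions (so a stated allele is never lost to
multinomial dropout — the intended truth class is always realised),
then shuffle; chimeric plants get extra deletion types injected one
clone each. What the fixtures deliberately omit: sequencing errors,
chromatogram artefacts, repeats/TE structure, real intron/exon length
distributions and GC heterogeneity. Passing the recovery suites
therefore demonstrates algorithmic correctness on clean allele-aware
structure, not robustness to raw-data noise.

## Problem sizes

The shipped test and acceptance runs use 4×2–25 kb genomes (up to
100 kb per replicate), 50-replicate scanner/locator sweeps, 200
simulated plants of 20–30 clones, and 300–1000 random 50-codon pairs —
sizes chosen so the whole suite completes in seconds while every
property is still exercised at full algorithmic generality.

## Known limitations

* The locator reports evidence (identity, coverage, exon intervals) but
  does not emulate manual curation of ambiguous alleles.
* Off-target scanning is mismatch-only (no DNA/RNA bulges) and carries
  no CFD/MIT-style scoring; "no obvious off-target" is a declared
  threshold, not a learned model.
* Guide ranking weights are declared defaults, not fitted to efficacy
  data; no Doench/Azimuth-style on-target model is included.
* The variant filter consumes VCF produced upstream; it does not call
  variants, and its evidence columns are meant for manual review.
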