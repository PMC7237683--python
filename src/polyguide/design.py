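"""Allele-aware SpCas9 guide enumeration and ranking.

In an autotetraploid, a guide is only useful for knockout if it matches
all allelic copies of the gene, so candidate protospacers (20-mers 5' of
an NGG) are enumerated from the exons of every located copy, deduplicated
by sequence, and scored against five design criteria: cover all alleles
(hard filter), no obvious off-target sites (hard filter on the scan
summary), proximity to the start codon, GC content (correlates with
sgRNA efficacy), and a 5'-G for U6-driven expression.  A protospacer that
does not start with G can be expressed with a prepended G (the reported
``vector_spacer``), which is how a 21-nt spacer arises from a 20-nt
protospacer; ``strict_5g`` turns the 5'-G rule back into a hard filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from ._seq import gc_fraction, revcomp
from .locate import AlleleSet
from .offtarget import GenomeIndex

GUIDE_LEN = 20


@dataclass(frozen=True)
class ScoringWeights:
    gc: float = 1.0
    start_proximity: float = 1.0
    conserved_exon: float = 0.5
    proximity_scale_bp: int = 200  # L in 1/(1 + d/L)


@dataclass(frozen=True)
class GuideCandidate:
    protospacer: str
    pam: str
    chromosome: str
    strand: str
    start: int  # 1-based, protospacer 5' end on its own strand
    exon_index: int
    distance_to_start_codon: int
    gc_fraction: float
    starts_with_g: bool
    allele_coverage: int
    in_conserved_exon: bool
    offtarget_summary: Counter | None = None
    rank_score: float | None = None

    @property
    def vector_spacer(self) -> str:
        """Spacer as cloned into a U6 vector: 5'-G prepended when the
        protospacer itself does not start with G (giving a 21-nt spacer)."""
        return self.protospacer if self.starts_with_g else "G" + self.protospacer


def _copy_span_seq(copy, genome: GenomeIndex) -> str:
    return genome.fetch(copy.chromosome,
                        copy.exons[0][0], copy.exons[-1][1])


def _cds_map(copy):
    """List of (genomic_pos_1based, cds_offset_0based) per coding base."""
    out = {}
    off = 0
    exons = copy.exons if copy.strand == "+" else copy.exons[::-1]
    for (s, e) in exons:
        rng = range(s, e + 1) if copy.strand == "+" else range(e, s - 1, -1)
        for g in rng:
            out[g] = off
            off += 1
    return out


def enumerate_guides(alleles: AlleleSet, genome: GenomeIndex,
                     ploidy: int | None = None) -> list[GuideCandidate]:
    """Every 20-mer immediately 5' of an NGG within any exon of any copy,
    both strands, deduplicated by protospacer sequence.

    ``allele_coverage`` counts copies containing protospacer+NGG exactly;
    ``distance_to_start_codon`` is measured from the protospacer's
    5'-most CDS base to the A of the start codon in CDS coordinates.
    """
    if not alleles.copies:
        raise ValueError("empty AlleleSet")
    for c in alleles.copies:
        if not c.exons:
            raise ValueError("copy without exons")
    ploidy = ploidy if ploidy is not None else len(alleles.copies)

    span_seqs = {id(c): _copy_span_seq(c, genome) for c in alleles.copies}
    conserved = _conserved_exons(alleles, genome)

    found: dict[str, GuideCandidate] = {}
    for copy in alleles.copies:
        cds_of = _cds_map(copy)
        for ei, (es, ee) in enumerate(copy.exons):
            for strand in "+-":
                for g5 in _scan_exon(genome, copy.chromosome, es, ee, strand):
                    proto, pam, positions = g5
                    if proto in found:
                        continue
                    cds_positions = [cds_of[p] for p in positions
                                     if p in cds_of]
                    dist = min(cds_positions) if cds_positions else -1
                    cov = sum(
                        1 for c2 in alleles.copies
                        if _present(proto, span_seqs[id(c2)]))
                    start = positions[0] if strand == "+" else positions[0]
                    exon_key = (copy.strand, ei if copy.strand == "+"
                                else len(copy.exons) - 1 - ei)
                    found[proto] = GuideCandidate(
                        protospacer=proto, pam=pam,
                        chromosome=copy.chromosome, strand=strand,
                        start=start, exon_index=exon_key[1],
                        distance_to_start_codon=dist,
                        gc_fraction=gc_fraction(proto),
                        starts_with_g=proto.startswith("G"),
                        allele_coverage=cov,
                        in_conserved_exon=conserved.get(
                            (id(copy), ei), False))
    return sorted(found.values(),
                  key=lambda c: (c.chromosome, c.start, c.strand))


def _scan_exon(genome: GenomeIndex, chrom: str, es: int, ee: int,
               strand: str):
    """Yield (protospacer, pam, [genomic 5'-end position]) for each
    candidate whose protospacer lies fully inside exon [es, ee] (1-based
    inclusive); the PAM may extend past the exon into flanking sequence."""
    chrom_seq = genome.chromosomes[chrom]
    L = len(chrom_seq)
    for s in range(es, ee - GUIDE_LEN + 2):  # 1-based protospacer start
        if strand == "+":
            if s + GUIDE_LEN + 2 > L:
                continue
            proto = chrom_seq[s - 1:s - 1 + GUIDE_LEN]
            pam = chrom_seq[s - 1 + GUIDE_LEN:s + GUIDE_LEN + 2]
            if len(pam) == 3 and pam[1] == "G" and pam[2] == "G" \
                    and not set(proto + pam) - set("ACGT"):
                yield proto, pam, [s + i for i in range(GUIDE_LEN)]
        else:
            # protospacer on '-': occupies plus positions s..s+19; its 5'
            # end is at plus position s+19; PAM is 3 bp to the plus-left
            if s - 3 < 1:
                continue
            win = chrom_seq[s - 1:s - 1 + GUIDE_LEN]
            pam_fwd = chrom_seq[s - 4:s - 1]
            proto = revcomp(win)
            pam = revcomp(pam_fwd)
            if len(pam) == 3 and pam[1] == "G" and pam[2] == "G" \
                    and not set(proto + pam) - set("ACGT"):
                yield proto, pam, [s + GUIDE_LEN - 1 - i
                                   for i in range(GUIDE_LEN)]


def _present(proto: str, span_seq: str) -> bool:
    for pam_strand_seq in (span_seq, revcomp(span_seq)):
        pos = pam_strand_seq.find(proto)
        while pos != -1:
            pam = pam_strand_seq[pos + GUIDE_LEN:pos + GUIDE_LEN + 3]
            if len(pam) == 3 and pam[1] == "G" and pam[2] == "G":
                return True
            pos = pam_strand_seq.find(proto, pos + 1)
    return False


def _conserved_exons(alleles: AlleleSet, genome: GenomeIndex,
                     ) -> dict[tuple[int, int], bool]:
    """Exon (by coding-strand index) identical in sequence across all
    copies -> conserved.  Copies with differing exon counts conserve
    nothing."""
    out: dict[tuple[int, int], bool] = {}
    counts = {len(c.exons) for c in alleles.copies}
    if len(counts) != 1:
        return {(id(c), i): False
                for c in alleles.copies for i in range(len(c.exons))}
    n = counts.pop()
    seqs_per_copy = []
    for c in alleles.copies:
        exons = c.exons if c.strand == "+" else c.exons[::-1]
        seqs = []
        for (s, e) in exons:
            seq = genome.fetch(c.chromosome, s, e)
            seqs.append(seq if c.strand == "+" else revcomp(seq))
        seqs_per_copy.append(seqs)
    for i in range(n):
        identical = len({seqs[i] for seqs in seqs_per_copy}) == 1
        for c in alleles.copies:
            ei = i if c.strand == "+" else len(c.exons) - 1 - i
            out[(id(c), ei)] = identical
    return out


@dataclass(frozen=True)
class OffTargetRule:
    """What counts as an 'obvious' off-target: any non-allelic hit with at
    most ``max_mismatches`` mismatches (either PAM class by default)."""

    max_mismatches: int = 3
    pam_kinds: frozenset = frozenset({"NGG", "NAG"})

    def obvious(self, summary: Counter) -> bool:
        return any(mm <= self.max_mismatches and kind in self.pam_kinds
                   and n > 0
                   for (mm, kind), n in summary.items())


def score_guide(candidate: GuideCandidate, ploidy: int,
                weights: ScoringWeights = ScoringWeights(),
                offtarget_rule: OffTargetRule = OffTargetRule(),
                strict_5g: bool = False) -> GuideCandidate | None:
    """Apply the hard filters and compute the rank score; returns None for
    a filtered-out candidate."""
    if candidate.offtarget_summary is None:
        raise RuntimeError("off-target summary not populated; run the "
                           "scanner before scoring")
    if candidate.allele_coverage != ploidy:
        return None
    if strict_5g and not candidate.starts_with_g:
        return None
    if offtarget_rule.obvious(candidate.offtarget_summary):
        return None
    L = weights.proximity_scale_bp
    d = max(candidate.distance_to_start_codon, 0)
    score = (weights.gc * candidate.gc_fraction
             + weights.start_proximity * (1.0 / (1.0 + d / L))
             + weights.conserved_exon * candidate.in_conserved_exon)
    return replace(candidate, rank_score=score)


def rank_guides(candidates: list[GuideCandidate], ploidy: int,
                weights: ScoringWeights = ScoringWeights(),
                offtarget_rule: OffTargetRule = OffTargetRule(),
                strict_5g: bool = False) -> list[GuideCandidate]:
    """Filter and sort candidates: rank score descending, ties broken by
    fewer total off-target hits then smaller genomic coordinate."""
    scored = [s for c in candidates
              if (s := score_guide(c, ploidy, weights, offtarget_rule,
                                   strict_5g)) is not None]
    def key(c: GuideCandidate):
        total_ot = sum(c.offtarget_summary.values())
        return (-c.rank_score, total_ot, c.chromosome, c.start)
    return sorted(scored, key=key)
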