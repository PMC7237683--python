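"""Classify edited plants from Sanger-sequenced amplicon clones.

PCR amplicons spanning the target site are sub-cloned and 20–30 clones
sequenced per plant.  Each clone is aligned globally to the wild-type
amplicon; indels/substitutions within a window around the predicted cut
become that clone's mutation-type signature, and a plant is classified
from the set of signatures observed:

* wild-type — every clone matches the reference;
* partial   — wild-type clones plus 1..ploidy-1 mutation types
              (e.g. three mutated alleles and one wild-type allele);
* null      — no wild-type clone, 1..ploidy mutation types
              (all allelic copies disrupted);
* chimeric  — more mutation types than the ploidy allows (non-uniform
              cellular genotypes, up to five types seen in T0 plants),
              or an external conflict flag (e.g. residual digested bands
              with no wild-type clone).

Distinct mutation types are a lower bound on mutated alleles (two alleles
can carry the same edit), reported as ``n_mutated_alleles_min``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align


@dataclass(frozen=True)
class CloneCall:
    """Edit signature of one clone relative to the reference amplicon.

    ``edits`` holds (kind, position, payload) tuples where position is the
    bp offset of the event relative to the cut inter-base (negative =
    PAM-distal side) and payload is the deleted length / inserted
    sequence / substituted base.
    """

    clone_id: str
    edits: tuple[tuple[str, int, str], ...]
    alignable: bool = True

    @property
    def is_wild_type(self) -> bool:
        return self.alignable and not self.edits

    @property
    def signature(self) -> str:
        if not self.alignable:
            return "unalignable"
        if not self.edits:
            return "wild-type"
        return ";".join(f"{k}{p:+d}:{x}" for k, p, x in self.edits)


@dataclass(frozen=True)
class PlantGenotype:
    plant_id: str
    n_mutation_types: int
    wild_type_observed: bool
    n_mutated_alleles_min: int
    classification: str  # wild-type | partial | null | chimeric
    ploidy: int
    mutation_types: tuple[str, ...] = ()


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


_ALIGNER = _aligner()


def call_clone(clone_seq: str, reference_amplicon: str, cut_index: int,
               window: int = 20, clone_id: str = "clone",
               ) -> CloneCall:
    """Align one clone to the reference and extract edits near the cut.

    ``cut_index`` is the number of reference bases left of the cut
    inter-base.  Edits whose positions fall outside ±``window`` of the cut
    are treated as PCR/sequencing noise and ignored.  Clones below 70%
    identity are flagged unalignable.
    """
    ref = reference_amplicon.upper()
    clone = clone_seq.upper()
    aln = _ALIGNER.align(ref, clone)[0]
    edits: list[tuple[str, int, str]] = []
    matches = 0
    aligned_cols = 0
    blocks_r, blocks_q = aln.aligned
    prev_r = prev_q = 0
    for (rs, re_), (qs, qe) in zip(blocks_r, blocks_q):
        if rs > prev_r and qs > prev_q:
            # simultaneous gap; the aligner never produces this in global
            # mode but guard anyway as a complex event at the region start
            edits.append(("complex", prev_r - cut_index,
                          f"{ref[prev_r:rs]}>{clone[prev_q:qs]}"))
        elif rs > prev_r:
            edits.append(("del", prev_r - cut_index, str(rs - prev_r)))
        elif qs > prev_q:
            edits.append(("ins", prev_r - cut_index, clone[prev_q:qs]))
        for i in range(re_ - rs):
            aligned_cols += 1
            if ref[rs + i] == clone[qs + i]:
                matches += 1
            else:
                edits.append(("sub", rs + i - cut_index,
                              f"{ref[rs + i]}>{clone[qs + i]}"))
        prev_r, prev_q = re_, qe
    if prev_r < len(ref) and prev_q < len(clone):
        edits.append(("complex", prev_r - cut_index,
                      f"{ref[prev_r:]}>{clone[prev_q:]}"))
    elif prev_r < len(ref):
        edits.append(("del", prev_r - cut_index, str(len(ref) - prev_r)))
    elif prev_q < len(clone):
        edits.append(("ins", prev_r - cut_index, clone[prev_q:]))

    # identity over the longer sequence, not just aligned columns —
    # otherwise a gappy alignment of unrelated sequence looks clean
    identity = matches / max(len(ref), len(clone), 1)
    if identity < 0.70:
        return CloneCall(clone_id=clone_id, edits=(), alignable=False)
    kept = tuple(e for e in edits if abs(e[1]) <= window)
    return CloneCall(clone_id=clone_id, edits=kept)


def classify_plant(calls: list[CloneCall], ploidy: int = 4,
                   min_clones: int = 5, plant_id: str = "plant",
                   conflict_flag: bool = False) -> PlantGenotype:
    """Classify a plant from its clone calls.

    ``conflict_flag`` marks external evidence of non-uniform genotype
    (e.g. dim digested PCR-RE bands although no wild-type clone was
    recovered) and forces the chimeric call.  Clone order never matters.
    """
    usable = [c for c in calls if c.alignable]
    if len(usable) < min_clones:
        raise ValueError(f"need at least {min_clones} alignable clones, "
                         f"got {len(usable)}")
    types = sorted({c.signature for c in usable if not c.is_wild_type})
    wt = any(c.is_wild_type for c in usable)
    n_types = len(types)
    # a wild-type clone alongside ploidy distinct edits implies more
    # allele states than alleles: that is itself a conflict
    conflict = conflict_flag or (wt and n_types >= ploidy)
    if n_types == 0 and not conflict:
        cls = "wild-type"
    elif n_types > ploidy or conflict:
        cls = "chimeric"
    elif wt:
        cls = "partial"
    else:
        cls = "null"
    return PlantGenotype(plant_id=plant_id, n_mutation_types=n_types,
                         wild_type_observed=wt,
                         n_mutated_alleles_min=n_types,
                         classification=cls, ploidy=ploidy,
                         mutation_types=tuple(types))


def mutagenesis_frequency(n_mutants: int, n_calli: int) -> float:
    """Mutant plants over transformed calli, as a percentage rounded
    half-up to 2 decimals (e.g. 5/880 -> 0.57)."""
    if n_calli <= 0:
        raise ValueError("n_calli must be positive")
    if not 0 <= n_mutants <= n_calli:
        raise ValueError("need 0 <= n_mutants <= n_calli")
    pct = Decimal(100) * Decimal(n_mutants) / Decimal(n_calli)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
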