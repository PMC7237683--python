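"""Seeded synthetic autotetraploid fixtures.

Generates genomes that emulate an allele-aware autopolyploid assembly:
each homologous group is represented by ``ploidy`` nearly identical
chromosome copies (default pairwise divergence 1e-4 substitutions/site),
with a target gene embedded identically in every copy, planted off-target
decoys at controlled mismatch counts, and restriction sites positioned
relative to the predicted Cas9 cut.  Every planted feature is recorded in
a truth table so downstream modules can be tested against exact
coordinates without any external data.

Also simulates Sanger clone sets from edited plants: a small number of
clones sampled from the (up to ``ploidy``) allelic versions of an
amplicon, each carrying a specified indel/substitution, optionally with
extra mutation types to mimic chimeric T0 plants.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp

GUIDE_LEN = 20
PAM_LEN = 3

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


@dataclass(frozen=True)
class EmbeddedGuide:
    """A protospacer+PAM planted inside one exon of the target gene."""

    exon_index: int
    offset: int  # 0-based offset of the protospacer within the exon
    protospacer: str
    pam: str = "CGG"

    def __post_init__(self):
        if len(self.protospacer) != GUIDE_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN:
            raise ValueError("PAM must be 3 nt")


@dataclass(frozen=True)
class GeneSpec:
    """Exon/intron layout of the target gene with embedded guide(s).

    ``allele_variants`` maps allele index -> list of (cds_offset, base)
    substitutions private to that allelic copy; by default all copies are
    identical.  Introns begin GT and end AG so spliced structure is
    recoverable.
    """

    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...] = ()
    guides: tuple[EmbeddedGuide, ...] = ()
    allele_variants: dict[int, tuple[tuple[int, str], ...]] = field(
        default_factory=dict)

    def __post_init__(self):
        if len(self.intron_lengths) != max(len(self.exon_lengths) - 1, 0):
            raise ValueError("need exactly len(exons)-1 introns")
        if any(n < 4 for n in self.intron_lengths):
            raise ValueError("introns must be >= 4 bp (GT..AG)")
        for g in self.guides:
            if g.exon_index >= len(self.exon_lengths):
                raise ValueError("guide exon_index out of range")
            if g.offset + GUIDE_LEN > self.exon_lengths[g.exon_index]:
                raise ValueError("protospacer does not fit in its exon")

    @property
    def length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass(frozen=True)
class DecoySite:
    """An off-target decoy derived from the target guide."""

    mismatches: int
    pam_kind: str = "NGG"  # NGG | NAG

    def __post_init__(self):
        if self.pam_kind not in ("NGG", "NAG"):
            raise ValueError("pam_kind must be NGG or NAG")
        if not 0 <= self.mismatches <= GUIDE_LEN:
            raise ValueError("mismatch count must be within guide length")


@dataclass(frozen=True)
class EnzymeSite:
    """A concrete recognition-site sequence written at a fixed offset
    (site start relative to the guide cut inter-base) into the gene."""

    recognition_site: str
    offset_from_cut: int


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_chromosome_groups: int = 1
    ploidy: int = 4
    chromosome_length: int = 20_000
    allelic_divergence: float = 1e-4
    target_gene: GeneSpec | None = None
    decoy_sites: tuple[DecoySite, ...] = ()
    enzyme_sites: tuple[EnzymeSite, ...] = ()

    def __post_init__(self):
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not 0.0 <= self.allelic_divergence < 1.0:
            raise ValueError("allelic_divergence must be in [0, 1)")
        if self.decoy_sites and (self.target_gene is None
                                 or not self.target_gene.guides):
            raise ValueError("decoys require a target gene with a guide")


TRUTH_COLUMNS = ["kind", "name", "chrom", "start", "end", "strand",
                 "sequence", "mismatches", "pam"]


@dataclass
class Fixture:
    """In-memory genome fixture: sequences, GFF3 features, truth table."""

    spec: FixtureSpec
    chromosomes: dict[str, str]
    gff3: str
    truth: pd.DataFrame

    def fasta(self) -> str:
        buf = io.StringIO()
        for name, seq in self.chromosomes.items():
            buf.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                buf.write(seq[i:i + 60] + "\n")
        return buf.getvalue()

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": outdir / "genome.fa",
                 "gff3": outdir / "genome.gff3",
                 "truth": outdir / "truth.tsv"}
        paths["fasta"].write_text(self.fasta())
        paths["gff3"].write_text(self.gff3)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _chrom_name(group: int, allele: int) -> str:
    return f"chr{group + 1}.{allele + 1}"


def _diverge(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Mutate each site with probability ``rate`` to a different base."""
    out = seq.copy()
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return out
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _build_gene(spec: GeneSpec, rng: np.random.Generator):
    """Return (gene_seq, exon_intervals, cds) in gene-local 0-based coords."""
    exons = [list(_random_seq(rng, n)) for n in spec.exon_lengths]
    for g in spec.guides:
        site = g.protospacer + g.pam
        exon = exons[g.exon_index]
        if g.offset + len(site) > len(exon):
            # PAM may spill into the following intron; keep it in-exon here
            raise ValueError("protospacer+PAM does not fit in its exon")
        exon[g.offset:g.offset + len(site)] = site
    # give the CDS a start codon so distance-to-ATG is well defined
    exons[0][0:3] = "ATG"
    introns = []
    for n in spec.intron_lengths:
        s = list(_random_seq(rng, n))
        s[0:2] = "GT"
        s[-2:] = "AG"
        introns.append(s)
    parts, intervals, pos = [], [], 0
    for i, ex in enumerate(exons):
        intervals.append((pos, pos + len(ex)))
        parts.append(ex)
        pos += len(ex)
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    gene = "".join("".join(p) for p in parts)
    cds = "".join("".join(ex) for ex in exons)
    return gene, intervals, cds


def _decoy_sequence(guide: EmbeddedGuide, decoy: DecoySite,
                    rng: np.random.Generator) -> tuple[str, str]:
    proto = list(guide.protospacer)
    pos = rng.choice(GUIDE_LEN, size=decoy.mismatches, replace=False)
    for p in sorted(pos):
        alts = [b for b in "ACGT" if b != proto[p]]
        proto[p] = alts[rng.integers(len(alts))]
    n = "ACGT"[rng.integers(4)]
    pam = n + ("GG" if decoy.pam_kind == "NGG" else "AG")
    return "".join(proto), pam


def generate_genome(spec: FixtureSpec) -> Fixture:
    """Generate a deterministic synthetic genome per ``spec``.

    One sequence per (group, allele); allelic copies differ only by the
    sampled divergence outside planted features.  The target gene (if any)
    sits at the same coordinates in every allelic copy of group 1; decoys
    are planted at loci far from the gene and from each other.
    """
    rng = np.random.default_rng(spec.seed)
    gene = None
    if spec.target_gene is not None:
        gene, exon_ivs, cds = _build_gene(spec.target_gene, rng)
        if spec.target_gene.length + 200 > spec.chromosome_length:
            raise ValueError("target gene does not fit in chromosome_length "
                             f"({spec.target_gene.length} + margin > "
                             f"{spec.chromosome_length})")

    chroms: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []
    gff_rows: list[str] = []

    for g in range(spec.n_chromosome_groups):
        ancestor = rng.choice(_BASES, size=spec.chromosome_length)
        per_site = spec.allelic_divergence / 2.0  # pairwise ~ divergence
        for a in range(spec.ploidy):
            arr = _diverge(rng, ancestor, per_site)
            arrays[_chrom_name(g, a)] = arr

    used: dict[str, list[tuple[int, int]]] = {c: [] for c in arrays}

    if gene is not None:
        gs = spec.target_gene
        margin = 100
        gene_start = int(rng.integers(
            margin, spec.chromosome_length - gs.length - margin))
        gene_arr = np.frombuffer(gene.encode(), dtype=np.uint8)
        for a in range(spec.ploidy):
            chrom = _chrom_name(0, a)
            arr = arrays[chrom]
            arr[gene_start:gene_start + gs.length] = gene_arr
            # allele-private CDS substitutions
            for off, base in gs.allele_variants.get(a, ()):
                cpos = 0
                for (es, ee) in exon_ivs:
                    if off < cpos + (ee - es):
                        arr[gene_start + es + (off - cpos)] = ord(base)
                        break
                    cpos += ee - es
            used[chrom].append((gene_start, gene_start + gs.length))
            gid = f"gene1_{chrom}"
            truth_rows.append(dict(
                kind="gene", name=gid, chrom=chrom, start=gene_start + 1,
                end=gene_start + gs.length, strand="+",
                sequence="", mismatches="", pam=""))
            gff_rows.append("\t".join([
                chrom, "polyguide", "gene", str(gene_start + 1),
                str(gene_start + gs.length), ".", "+", ".", f"ID={gid}"]))
            gff_rows.append("\t".join([
                chrom, "polyguide", "mRNA", str(gene_start + 1),
                str(gene_start + gs.length), ".", "+", ".",
                f"ID={gid}.t1;Parent={gid}"]))
            for i, (es, ee) in enumerate(exon_ivs):
                s1, e1 = gene_start + es + 1, gene_start + ee
                for feat in ("exon", "CDS"):
                    attr = (f"ID={gid}.t1.{feat.lower()}{i + 1};"
                            f"Parent={gid}.t1")
                    gff_rows.append("\t".join([
                        chrom, "polyguide", feat, str(s1), str(e1), ".",
                        "+", "0" if feat == "CDS" else ".", attr]))
                truth_rows.append(dict(
                    kind="exon", name=f"{gid}.exon{i + 1}", chrom=chrom,
                    start=s1, end=e1, strand="+", sequence="",
                    mismatches="", pam=""))
            for k, gu in enumerate(gs.guides):
                es, _ = exon_ivs[gu.exon_index]
                st = gene_start + es + gu.offset
                truth_rows.append(dict(
                    kind="guide_site", name=f"guide{k + 1}_{chrom}",
                    chrom=chrom, start=st + 1, end=st + GUIDE_LEN + PAM_LEN,
                    strand="+", sequence=gu.protospacer + gu.pam,
                    mismatches=0, pam=gu.pam))
            # enzyme sites: written relative to the first guide's cut
            if gs.guides and spec.enzyme_sites:
                gu = gs.guides[0]
                es, _ = exon_ivs[gu.exon_index]
                cut = gene_start + es + gu.offset + 17  # bases left of cut
                for ez in spec.enzyme_sites:
                    st = cut + ez.offset_from_cut
                    site = ez.recognition_site.upper()
                    arr[st:st + len(site)] = np.frombuffer(
                        site.encode(), dtype=np.uint8)
                    truth_rows.append(dict(
                        kind="enzyme_site", name=f"enzyme_{site}_{chrom}",
                        chrom=chrom, start=st + 1, end=st + len(site),
                        strand="+", sequence=site, mismatches="", pam=""))

    # decoys: one copy each, far from the gene and from each other
    pad = 2 * (GUIDE_LEN + PAM_LEN)
    for j, decoy in enumerate(spec.decoy_sites):
        gu = spec.target_gene.guides[0]
        proto, pam = _decoy_sequence(gu, decoy, rng)
        site = proto + pam
        strand = "+" if rng.integers(2) == 0 else "-"
        for _attempt in range(1000):
            chrom = list(arrays)[rng.integers(len(arrays))]
            st = int(rng.integers(pad, spec.chromosome_length - len(site) - pad))
            iv = (st - pad, st + len(site) + pad)
            if all(iv[1] <= s or iv[0] >= e for s, e in used[chrom]):
                break
        else:  # pragma: no cover - pathological spec
            raise ValueError("could not place decoy without overlap")
        used[chrom].append((st, st + len(site)))
        written = site if strand == "+" else revcomp(site)
        arrays[chrom][st:st + len(site)] = np.frombuffer(
            written.encode(), dtype=np.uint8)
        # start/end: protospacer 5' and 3' ends on its own strand, 1-based
        start_1 = st + 1 if strand == "+" else st + len(site)
        end_1 = st + GUIDE_LEN if strand == "+" else st + 1 + PAM_LEN
        truth_rows.append(dict(
            kind="decoy", name=f"decoy{j + 1}", chrom=chrom, start=start_1,
            end=end_1, strand=strand, sequence=proto,
            mismatches=decoy.mismatches, pam=pam))

    for name, arr in arrays.items():
        chroms[name] = arr.tobytes().decode("ascii")

    gff3 = "##gff-version 3\n" + "".join(r + "\n" for r in gff_rows)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return Fixture(spec=spec, chromosomes=chroms, gff3=gff3, truth=truth)


# ---------------------------------------------------------------------------
# Edited clone sets


@dataclass(frozen=True)
class Deletion:
    length: int
    offset: int = 0  # bases 3' of the cut where the deletion starts

    def signature(self) -> str:
        return f"del{self.length}@{self.offset}"


@dataclass(frozen=True)
class Insertion:
    sequence: str
    offset: int = 0

    def signature(self) -> str:
        return f"ins{self.sequence}@{self.offset}"


@dataclass(frozen=True)
class Substitution:
    offset: int
    to_base: str

    def signature(self) -> str:
        return f"sub{self.to_base}@{self.offset}"


WildType = None  # an allele left unedited

Edit = Deletion | Insertion | Substitution | None


@dataclass(frozen=True)
class EditedCloneSpec:
    n_clones: int
    allele_edits: dict[int, Edit]
    chimera_extra_types: int = 0
    sampling_proportions: dict[int, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sampling_proportions is not None:
            if set(self.sampling_proportions) != set(self.allele_edits):
                raise ValueError("proportions must cover exactly the alleles")
            total = sum(self.sampling_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("sampling proportions must sum to 1")


def apply_edit(reference: str, cut_index: int, edit: Edit) -> str:
    """Apply one edit to a reference amplicon. ``cut_index`` is the number
    of bases left of the cut inter-base (0-based)."""
    if edit is None:
        return reference
    if isinstance(edit, Deletion):
        start = cut_index + edit.offset
        if not (0 <= start and start + edit.length <= len(reference)):
            raise ValueError("edit outside amplicon")
        return reference[:start] + reference[start + edit.length:]
    if isinstance(edit, Insertion):
        at = cut_index + edit.offset
        if not 0 <= at <= len(reference):
            raise ValueError("edit outside amplicon")
        return reference[:at] + edit.sequence + reference[at:]
    if isinstance(edit, Substitution):
        at = cut_index + edit.offset
        if not 0 <= at < len(reference):
            raise ValueError("edit outside amplicon")
        return reference[:at] + edit.to_base + reference[at + 1:]
    raise TypeError(f"unknown edit {edit!r}")


def _allocate(n: int, proportions: dict[int, float]) -> dict[int, int]:
    """Largest-remainder allocation so every allele with p>0 is sampled
    in its stated proportion without multinomial dropout."""
    keys = sorted(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    rem = n - sum(counts.values())
    order = sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    return counts


def generate_clone_set(spec: EditedCloneSpec, reference_amplicon: str,
                       protospacer: str) -> tuple[list[tuple[str, str]],
                                                  pd.DataFrame]:
    """Simulate a Sanger clone set for one plant.

    Returns ``(clones, labels)``: clones as (id, sequence) pairs and a
    truth table with each clone's allele of origin and mutation-type
    signature.  The amplicon must contain the protospacer (plus-strand);
    the cut is placed between protospacer positions 17 and 18.
    """
    idx = reference_amplicon.find(protospacer)
    if idx < 0:
        raise ValueError("reference amplicon must contain the protospacer")
    cut = idx + 17
    rng = np.random.default_rng(spec.seed)
    props = spec.sampling_proportions or {
        k: 1.0 / len(spec.allele_edits) for k in spec.allele_edits}
    counts = _allocate(spec.n_clones, props)

    # chimeric plants carry mutation types beyond the allelic set; borrow
    # one clone per extra type from the most-sampled allele
    extra_edits: list[Edit] = []
    existing = {e.signature() for e in spec.allele_edits.values()
                if e is not None}
    length = 3
    while len(extra_edits) < spec.chimera_extra_types:
        cand = Deletion(length=length, offset=-1)
        if cand.signature() not in existing:
            extra_edits.append(cand)
            existing.add(cand.signature())
        length += 1
    for e in extra_edits:
        donor = max(counts, key=lambda k: counts[k])
        if counts[donor] <= 1:
            raise ValueError("not enough clones to inject chimeric types")
        counts[donor] -= 1

    entries: list[tuple[int | str, Edit]] = []
    for allele in sorted(counts):
        entries += [(allele, spec.allele_edits[allele])] * counts[allele]
    for j, e in enumerate(extra_edits):
        entries.append((f"chimera{j + 1}", e))
    entries = [entries[i] for i in rng.permutation(len(entries))]

    clones, rows = [], []
    for i, (allele, edit) in enumerate(entries):
        seq = apply_edit(reference_amplicon, cut, edit)
        cid = f"clone{i + 1:03d}"
        clones.append((cid, seq))
        rows.append(dict(clone_id=cid, allele=str(allele),
                         mutation_type=("wild-type" if edit is None
                                        else edit.signature())))
    labels = pd.DataFrame(rows, columns=["clone_id", "allele",
                                         "mutation_type"])
    return clones, labels
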