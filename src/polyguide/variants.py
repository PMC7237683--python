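"""Filter WGS variant calls of edited plants down to candidate
Cas9-induced off-target mutations.

Cas9 cuts 3 bp 5' of the PAM and its repair products are overwhelmingly
indels at that position, so true off-target mutations in resequenced
mutants are expected to be indels at or near the -3 inter-base of a
predicted off-target site.  SNVs are excluded outright (they are
indistinguishable from background heterozygosity/somaclonal variation),
variants at the intended target are excluded as on-target, and the
remaining indels are kept only when they fall within ``tolerance`` bp of
a site's -3 position.  Coding-region overlap is annotated from GFF3 CDS
features so the headline question — any off-target mutation in a
protein-coding gene? — can be answered directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .offtarget import OffTargetHit
from .restriction import predict_cut_site


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int  # 1-based (VCF POS; anchor base for indels)
    ref: str
    alt: str
    passes_quality: bool = True

    @property
    def type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt) and self.alt.startswith(self.ref):
            return "insertion"
        if len(self.ref) > len(self.alt) and self.ref.startswith(self.alt):
            return "deletion"
        return "complex"

    @property
    def event_interbase(self) -> int:
        """Inter-base coordinate where the indel event begins (after the
        anchor base, VCF left-aligned convention)."""
        return self.position


@dataclass(frozen=True)
class CdsInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    gene_id: str


@dataclass(frozen=True)
class OffTargetVerdict:
    variant: VariantRecord
    matched_site: OffTargetHit | None
    distance_to_minus3: int | None
    in_coding_region: bool
    is_candidate: bool
    reason: str


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF (4.x) into records; multi-allelic sites expand to one
    record per ALT; FILTER other than PASS/. marks the record as failing
    quality."""
    from cyvcf2 import VCF
    out = []
    for v in VCF(str(path)):
        ok = v.FILTER is None  # cyvcf2: None means PASS or '.'
        for alt in v.ALT:
            out.append(VariantRecord(chromosome=v.CHROM, position=v.POS,
                                     ref=v.REF, alt=alt,
                                     passes_quality=ok))
    return out


def read_cds_intervals(gff3_path: str | Path) -> list[CdsInterval]:
    """CDS features from a GFF3 file, keyed by their Parent (or ID)."""
    out = []
    for line in Path(gff3_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9 or f[2] != "CDS":
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        gene = attrs.get("Parent", attrs.get("ID", "unknown"))
        out.append(CdsInterval(chromosome=f[0], start=int(f[3]),
                               end=int(f[4]), gene_id=gene))
    return out


def _site_cut(site: OffTargetHit) -> int:
    return predict_cut_site(site.start, site.strand)


def filter_offtarget_variants(variants: list[VariantRecord],
                              sites: list[OffTargetHit],
                              cds_intervals: list[CdsInterval] = (),
                              tolerance: int = 2,
                              ) -> list[OffTargetVerdict]:
    """One verdict per input variant (records are conserved, never
    silently dropped).

    A variant is a candidate Cas9 off-target mutation iff it is an indel
    located within ``tolerance`` bp of the -3 inter-base (protospacer
    17|18) of a predicted site that is NOT the intended target.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_chrom: dict[str, list[OffTargetHit]] = {}
    for s in sites:
        by_chrom.setdefault(s.chromosome, []).append(s)

    verdicts = []
    for v in variants:
        coding = any(c.chromosome == v.chromosome
                     and c.start <= v.position <= c.end
                     for c in cds_intervals)
        if not v.passes_quality:
            verdicts.append(OffTargetVerdict(v, None, None, coding, False,
                                             "failed quality"))
            continue
        if v.type == "SNV":
            verdicts.append(OffTargetVerdict(v, None, None, coding, False,
                                             "SNV excluded"))
            continue
        if v.type == "complex":
            verdicts.append(OffTargetVerdict(v, None, None, coding, False,
                                             "complex event excluded"))
            continue
        # nearest site by |event - cut|, preferring non-on-target
        best, best_d = None, None
        for s in by_chrom.get(v.chromosome, ()):
            d = v.event_interbase - _site_cut(s)
            if best_d is None or (abs(d), s.is_on_target) < \
                    (abs(best_d), best.is_on_target):
                best, best_d = s, d
        if best is None or abs(best_d) > tolerance:
            verdicts.append(OffTargetVerdict(v, best, best_d, coding,
                                             False,
                                             "no off-target site nearby"))
        elif best.is_on_target:
            verdicts.append(OffTargetVerdict(v, best, best_d, coding,
                                             False, "targeted region"))
        else:
            verdicts.append(OffTargetVerdict(v, best, best_d, coding,
                                             True, "indel near -3"))
    return verdicts


def summarize_coding_offtargets(verdicts: list[OffTargetVerdict],
                                cds_intervals: list[CdsInterval] = (),
                                ) -> tuple[int, dict[str, int]]:
    """Count candidate off-target mutations in protein-coding regions,
    with a per-gene breakdown."""
    per_gene: dict[str, int] = {}
    n = 0
    for vd in verdicts:
        if not (vd.is_candidate and vd.in_coding_region):
            continue
        n += 1
        genes = {c.gene_id for c in cds_intervals
                 if c.chromosome == vd.variant.chromosome
                 and c.start <= vd.variant.position <= c.end} or {"unknown"}
        for g in genes:
            per_gene[g] = per_gene.get(g, 0) + 1
    return n, per_gene
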