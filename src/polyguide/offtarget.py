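"""Exact mismatch-bounded off-target enumeration for SpCas9 guides.

Finds every genomic site matching a 20-nt guide with at most K mismatches
(default 5) immediately 5' of an NGG or NAG PAM, on either strand, using a
pigeonhole seed partition: the guide is split into K+1 contiguous seeds,
so any site within K mismatches contains at least one seed exactly; seed
occurrences are located by string search and each candidate window is
verified by a full Hamming count plus PAM check.  This is exact — no
heuristics, no missed sites — at the scale of desk-sized genomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from ._seq import hamming, revcomp

GUIDE_LEN = 20
_PAM_SECOND = {"NGG": "G", "NAG": "A"}


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic site matching a guide within the mismatch bound.

    ``start`` is the 1-based coordinate of the site's 5' end on its own
    strand; mismatch positions are 1 (PAM-distal) .. 20 (PAM-proximal).
    """

    chromosome: str
    strand: str
    start: int
    site_sequence: str
    pam: str
    pam_kind: str
    n_mismatches: int
    mismatch_positions: tuple[int, ...]
    is_on_target: bool = False


@dataclass
class GenomeIndex:
    """Named chromosome sequences (upper-case) for scanning and slicing."""

    chromosomes: dict[str, str]

    def __post_init__(self):
        self.chromosomes = {n: s.upper()
                            for n, s in self.chromosomes.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeIndex":
        from Bio import SeqIO
        return cls({rec.id: str(rec.seq)
                    for rec in SeqIO.parse(str(path), "fasta")})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice on the plus strand."""
        return self.chromosomes[chrom][start - 1:end]


def _seed_partition(n: int, parts: int) -> list[tuple[int, int]]:
    """Split [0, n) into ``parts`` contiguous near-equal pieces."""
    base, extra = divmod(n, parts)
    out, pos = [], 0
    for i in range(parts):
        ln = base + (1 if i < extra else 0)
        out.append((pos, pos + ln))
        pos += ln
    return out


def _pam_kind(pam: str, pams: frozenset[str]) -> str | None:
    if len(pam) != 3 or pam[0] not in "ACGT" or pam[2] != "G":
        return None
    for kind in pams:
        if pam[1] == _PAM_SECOND[kind]:
            return kind
    return None


def scan(guide: str, genome: GenomeIndex, max_mismatches: int = 5,
         pams: frozenset[str] | set[str] = frozenset({"NGG", "NAG"}),
         ) -> list[OffTargetHit]:
    """Enumerate all sites matching ``guide`` within ``max_mismatches``
    adjacent to an allowed PAM, on both strands.

    Returns hits sorted by (chromosome, start, strand); complete and
    duplicate-free by construction (verified against brute force in the
    test suite for genomes up to hundreds of kb).
    """
    guide = guide.upper()
    if len(guide) != GUIDE_LEN:
        raise ValueError("guide must be 20 nt")
    if set(guide) - set("ACGT"):
        raise ValueError("guide must be unambiguous A/C/G/T")
    if not 0 <= max_mismatches <= 10:
        raise ValueError("max_mismatches must be in [0, 10]")
    pams = frozenset(pams)
    if not pams <= {"NGG", "NAG"}:
        raise ValueError(f"unsupported PAM kinds: {pams - {'NGG', 'NAG'}}")

    seeds = _seed_partition(GUIDE_LEN, max_mismatches + 1)
    hits: list[OffTargetHit] = []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        for strand in "+-":
            g = guide if strand == "+" else revcomp(guide)
            # on '-' the protospacer is the revcomp of the window read on
            # '+'; window positions are computed on the plus strand either
            # way and converted to the hit's own-strand 5' coordinate.
            seen: set[int] = set()
            for (s, e) in seeds:
                probe = (g[s:e] if strand == "+"
                         else g[GUIDE_LEN - e:GUIDE_LEN - s])
                off = s if strand == "+" else GUIDE_LEN - e
                pos = seq.find(probe)
                while pos != -1:
                    w = pos - off
                    if w >= 0 and w + GUIDE_LEN <= L and w not in seen:
                        seen.add(w)
                        hit = _verify(chrom, seq, w, strand, guide,
                                      max_mismatches, pams)
                        if hit is not None:
                            hits.append(hit)
                    pos = seq.find(probe, pos + 1)
    hits.sort(key=lambda h: (h.chromosome, h.start, h.strand))
    return hits


def _verify(chrom: str, seq: str, w: int, strand: str, guide: str,
            max_mm: int, pams: frozenset[str]) -> OffTargetHit | None:
    window = seq[w:w + GUIDE_LEN]
    if strand == "+":
        pam = seq[w + GUIDE_LEN:w + GUIDE_LEN + 3]
        site = window
        start = w + 1
    else:
        pam = revcomp(seq[w - 3:w]) if w >= 3 else ""
        site = revcomp(window)
        start = w + GUIDE_LEN
    kind = _pam_kind(pam, pams)
    if kind is None:
        return None
    if set(site) - set("ACGT"):
        return None  # N never matches a guide base
    mism = tuple(i + 1 for i in range(GUIDE_LEN) if site[i] != guide[i])
    if len(mism) > max_mm:
        return None
    return OffTargetHit(chromosome=chrom, strand=strand, start=start,
                        site_sequence=site, pam=pam, pam_kind=kind,
                        n_mismatches=len(mism), mismatch_positions=mism)


def classify_hits(hits: list[OffTargetHit], alleles) -> dict:
    """Split hits into on-target (overlapping an allelic copy of the
    intended gene) and off-target, and summarise the off-target ones as a
    complete contingency of (n_mismatches, pam_kind) counts.

    ``alleles`` is an AlleleSet from the locator (or any object with
    ``.copies`` carrying chromosome/span) — hits overlapping any copy's
    genomic span are flagged ``is_on_target`` and excluded from counts.

    Returns ``{"hits": [...], "counts": Counter, "n_on_target": int}``.
    """
    spans = []
    for c in getattr(alleles, "copies", []):
        lo = min(s for s, _ in c.exons)
        hi = max(e for _, e in c.exons)
        spans.append((c.chromosome, lo, hi))
    out_hits, counts = [], Counter()
    n_on = 0
    for h in hits:
        lo = h.start if h.strand == "+" else h.start - GUIDE_LEN + 1
        hi = lo + GUIDE_LEN - 1
        on = any(ch == h.chromosome and lo <= e and hi >= s
                 for ch, s, e in spans)
        out_hits.append(replace(h, is_on_target=on))
        if on:
            n_on += 1
        else:
            counts[(h.n_mismatches, h.pam_kind)] += 1
    return {"hits": out_hits, "counts": counts, "n_on_target": n_on}
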