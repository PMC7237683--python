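"""Locate all allelic copies of a target gene in an allele-aware assembly.

In an autotetraploid assembly each homologous chromosome is a separate
sequence, so a single-copy gene appears as ~4 nearly identical loci
(allelic divergence on the order of 1%).  Given a query CDS/mRNA this
module finds every locus reaching the identity/coverage thresholds and
reconstructs its exon structure: query k-mers are anchored on the genome
(both strands), anchors sharing a diagonal are merged into candidate exon
blocks, blocks are chained colinearly per locus, and exon boundaries in
unanchored gaps are resolved by mismatch minimisation with a GT..AG
splice-donor/acceptor preference.  Copy number can additionally be
estimated from sequencing depth over the CDS relative to a haploid
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp


@dataclass(frozen=True)
class GeneCopy:
    """One located allelic copy: forward-strand genomic exon intervals
    (1-based inclusive, sorted), coding strand, spliced sequence."""

    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_sequence: str
    identity_to_query: float
    query_coverage: float


@dataclass
class AlleleSet:
    gene_id: str
    copies: list[GeneCopy] = field(default_factory=list)

    @property
    def copy_number(self) -> int:
        return len(self.copies)

    def to_gff3(self) -> str:
        lines = ["##gff-version 3"]
        for i, c in enumerate(self.copies, 1):
            gid = f"{self.gene_id}_copy{i}"
            lo, hi = c.exons[0][0], c.exons[-1][1]
            attrs = (f"ID={gid};identity={c.identity_to_query:.4f};"
                     f"coverage={c.query_coverage:.4f}")
            lines.append("\t".join([c.chromosome, "polyguide", "gene",
                                    str(lo), str(hi), ".", c.strand, ".",
                                    attrs]))
            exons = c.exons if c.strand == "+" else c.exons[::-1]
            for j, (s, e) in enumerate(sorted(exons), 1):
                lines.append("\t".join([
                    c.chromosome, "polyguide", "exon", str(s), str(e), ".",
                    c.strand, ".", f"ID={gid}.exon{j};Parent={gid}"]))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CopyNumberEstimate:
    copy_number: int
    ratio: float


def copy_number_from_depth(per_base_depth, haploid_baseline_depth: float,
                           ) -> CopyNumberEstimate:
    """Copy number as round(median depth / haploid baseline).

    The median makes the ratio robust to coverage noise and to the odd
    collapsed/expanded interval.  Half-way ratios round up.
    """
    if haploid_baseline_depth <= 0:
        raise ValueError("baseline depth must be positive")
    depth = np.asarray(per_base_depth, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    ratio = float(np.median(depth) / haploid_baseline_depth)
    return CopyNumberEstimate(copy_number=int(np.floor(ratio + 0.5)),
                              ratio=ratio)


# ---------------------------------------------------------------------------
# k-mer anchoring + chaining


def _anchors(query: str, subject: str, k: int) -> dict[int, list[int]]:
    """Map diagonal (spos - qpos) -> sorted query positions of exact
    k-mer matches."""
    index: dict[str, list[int]] = {}
    for q in range(len(query) - k + 1):
        index.setdefault(query[q:q + k], []).append(q)
    diags: dict[int, list[int]] = {}
    for s in range(len(subject) - k + 1):
        for q in index.get(subject[s:s + k], ()):
            diags.setdefault(s - q, []).append(q)
    for v in diags.values():
        v.sort()
    return diags


def _blocks_from_diagonals(diags: dict[int, list[int]], k: int,
                           merge_gap: int) -> list[tuple[int, int, int]]:
    """Merge anchors on one diagonal into (qstart, qend, diag) blocks;
    anchors separated by more than ``merge_gap`` unanchored query bases
    (mismatch runs) start a new block."""
    blocks = []
    for d, qs in diags.items():
        start = prev = qs[0]
        for q in qs[1:]:
            if q - prev > merge_gap:
                blocks.append((start, prev + k, d))
                start = q
            prev = q
        blocks.append((start, prev + k, d))
    return blocks


def _chain(blocks: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best colinear chain (query and subject both increasing) by DP on
    anchored length."""
    blocks = sorted(blocks, key=lambda b: (b[0], b[1]))
    n = len(blocks)
    best = [b[1] - b[0] for b in blocks]
    back = [-1] * n
    for i in range(n):
        qi, _, di = blocks[i]
        for j in range(i):
            qj, ej, dj = blocks[j]
            if ej <= qi + 15 and dj < di and blocks[j][0] < qi:
                # small q-overlap allowed; subject must advance
                cand = best[j] + (blocks[i][1] - blocks[i][0])
                if cand > best[i]:
                    best[i], back[i] = cand, j
            elif dj == di and ej <= qi:
                cand = best[j] + (blocks[i][1] - blocks[i][0])
                if cand > best[i]:
                    best[i], back[i] = cand, j
    i = int(np.argmax(best))
    chain = []
    while i != -1:
        chain.append(blocks[i])
        i = back[i]
    return chain[::-1]


def _mm(query: str, subject: str, qs: int, qe: int, d: int) -> int:
    sub = subject[qs + d:qe + d]
    seg = query[qs:qe]
    if len(sub) != len(seg):
        return len(seg)
    return sum(a != b for a, b in zip(seg, sub))


def _resolve_boundary(query: str, subject: str, lo: int, hi: int,
                      d1: int, d2: int) -> int:
    """Choose the split t in [lo, hi] assigning query[..t) to diagonal d1
    and query[t..) to d2: minimise mismatches, prefer GT..AG introns."""
    best_t, best_key = lo, None
    for t in range(lo, hi + 1):
        cost = _mm(query, subject, lo, t, d1) + _mm(query, subject, t, hi, d2)
        intron = subject[t + d1:t + d2]
        canonical = 0 if (len(intron) >= 4 and intron[:2] == "GT"
                          and intron[-2:] == "AG") else 1
        key = (cost, canonical, t)
        if best_key is None or key < best_key:
            best_t, best_key = t, key
    return best_t


def _locus_to_copy(chain, query, subject, chrom, strand, sub_is_rc):
    """Turn a chained block list into exon intervals + stats."""
    # assign every query base between block midpoints to a diagonal
    segs: list[tuple[int, int, int]] = []  # (qs, qe, diag)
    first_q, last_q = chain[0][0], chain[-1][1]
    d_first, d_last = chain[0][2], chain[-1][2]
    # extend first/last block to the query ends along their diagonals,
    # clipped to the subject
    q0 = max(0, -d_first)
    q1 = min(len(query), len(subject) - d_last)
    bounds = [q0]
    for (a, b) in zip(chain, chain[1:]):
        lo, hi = min(a[1], b[0]), max(a[1], b[0])
        lo, hi = min(lo, hi), hi
        lo = max(lo, q0)
        hi = min(hi, q1)
        if a[2] == b[2]:
            bounds.append(lo)  # same diagonal: blocks merge anyway
        else:
            bounds.append(_resolve_boundary(query, subject, lo, hi,
                                            a[2], b[2]))
    bounds.append(q1)
    for i, blk in enumerate(chain):
        qs, qe = bounds[i], bounds[i + 1]
        if qe > qs:
            segs.append((qs, qe, blk[2]))
    # merge consecutive segments on the same diagonal
    merged: list[list[int]] = []
    for qs, qe, d in segs:
        if merged and merged[-1][2] == d and merged[-1][1] == qs:
            merged[-1][1] = qe
        else:
            merged.append([qs, qe, d])

    aligned = mismatches = 0
    exons_sub: list[tuple[int, int]] = []  # 0-based half-open on subject
    cds_parts = []
    for qs, qe, d in merged:
        exons_sub.append((qs + d, qe + d))
        cds_parts.append(subject[qs + d:qe + d])
        aligned += qe - qs
        mismatches += _mm(query, subject, qs, qe, d)
    identity = (aligned - mismatches) / aligned if aligned else 0.0
    coverage = aligned / len(query)
    cds = "".join(cds_parts)
    L = len(subject)
    if sub_is_rc:
        exons_fwd = sorted((L - e + 1, L - s) for s, e in exons_sub)
    else:
        exons_fwd = sorted((s + 1, e) for s, e in exons_sub)
    return GeneCopy(chromosome=chrom, strand="-" if sub_is_rc else "+",
                    exons=tuple(exons_fwd), cds_sequence=cds,
                    identity_to_query=identity, query_coverage=coverage)


def locate_alleles(query: str, genome, min_identity: float = 0.90,
                   min_query_coverage: float = 0.80, k: int = 15,
                   max_locus_gap: int = 10_000,
                   gene_id: str = "query") -> AlleleSet:
    """Find every genomic locus matching ``query`` at the thresholds.

    Each locus is reported once; overlapping candidate loci on one
    genomic span are merged (the better-scoring interpretation wins).
    Returns an empty AlleleSet (copy_number 0) when nothing reaches the
    thresholds.
    """
    query = query.upper()
    if not query:
        raise ValueError("empty query")
    if not getattr(genome, "chromosomes", None):
        raise ValueError("empty genome")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if len(query) < k:
        raise ValueError(f"query shorter than anchor size k={k}")

    copies: list[GeneCopy] = []
    for chrom, seq in genome.chromosomes.items():
        for sub_is_rc in (False, True):
            subject = revcomp(seq) if sub_is_rc else seq
            diags = _anchors(query, subject, k)
            if not diags:
                continue
            # cluster anchors into loci by subject position
            points = sorted((q + d, q, d) for d, qs in diags.items()
                            for q in qs)
            clusters, cur = [], [points[0]]
            for p in points[1:]:
                if p[0] - cur[-1][0] > max_locus_gap:
                    clusters.append(cur)
                    cur = [p]
                else:
                    cur.append(p)
            clusters.append(cur)
            for cl in clusters:
                cdiags: dict[int, list[int]] = {}
                for _, q, d in cl:
                    cdiags.setdefault(d, []).append(q)
                for v in cdiags.values():
                    v.sort()
                blocks = _blocks_from_diagonals(cdiags, k, merge_gap=3 * k)
                chain = _chain(blocks)
                if not chain:
                    continue
                copy = _locus_to_copy(chain, query, subject, chrom,
                                      sub_is_rc, sub_is_rc)
                if (copy.identity_to_query >= min_identity
                        and copy.query_coverage >= min_query_coverage):
                    copies.append(copy)
    # one report per genomic span: drop the worse of overlapping copies
    copies.sort(key=lambda c: (-c.identity_to_query * c.query_coverage,
                               c.chromosome, c.exons))
    kept: list[GeneCopy] = []
    for c in copies:
        lo, hi = c.exons[0][0], c.exons[-1][1]
        clash = any(k2.chromosome == c.chromosome
                    and lo <= k2.exons[-1][1] and hi >= k2.exons[0][0]
                    for k2 in kept)
        if not clash:
            kept.append(c)
    kept.sort(key=lambda c: (c.chromosome, c.exons))
    return AlleleSet(gene_id=gene_id, copies=kept)
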