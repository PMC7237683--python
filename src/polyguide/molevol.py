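"""Nei–Gojobori (1986) Ka/Ks and WGD-calibrated mutation rates.

The NG86 method counts, for each codon, the fraction of the nine
single-base neighbours that are synonymous (synonymous sites), classifies
observed differences by averaging over all substitution pathways between
the two codons that avoid stop codons, converts the proportions ps = Sd/S
and pn = Nd/N to distances with the Jukes–Cantor correction
d = -(3/4)·ln(1 - (4/3)p), and reports Ka/Ks.  A shared legume
whole-genome duplication of known age T then calibrates the per-site
per-year mutation rate as mu = Ks/(2T): the Ks peak measures the
divergence accumulated along the two post-WGD lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

_STOPS = frozenset(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)
_BASES = "ACGT"


@dataclass(frozen=True)
class KaKsResult:
    S: float               # synonymous sites (fractional, averaged)
    N: float               # nonsynonymous sites
    Sd: float              # synonymous differences (pathway-averaged)
    Nd: float              # nonsynonymous differences
    ps: float
    pn: float
    Ks: float | None       # None when Jukes-Cantor saturated (p >= 3/4)
    Ka: float | None
    ka_ks: float | None    # None when Ks undefined or zero
    n_codons: int          # codon pairs actually counted
    notes: tuple[str, ...] = ()


def _syn_sites(codon: str) -> float:
    """Synonymous-site count for one codon: per position, the fraction of
    the three possible changes that preserve the amino acid.  A change to
    a stop codon counts as nonsynonymous, keeping S+N == 3."""
    aa = _AA[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in _STOPS and _AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over all substitution orders
    that avoid intermediate stop codons; if every order passes through a
    stop, all orders are used."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in _STOPS:
                ok = False
            else:
                if _AA[cur] == _AA[nxt]:
                    sd += 1
                else:
                    nd += 1
            cur = nxt
        (valid if ok else blocked).append((sd, nd, order))
    paths = valid or _all_paths(c1, c2, diff)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _all_paths(c1: str, c2: str, diff) -> list[tuple[float, float, tuple]]:
    out = []
    for order in permutations(diff):
        cur, sd, nd = c1, 0, 0
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt not in _STOPS and cur not in _STOPS \
                    and _AA.get(cur) == _AA.get(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        out.append((sd, nd, order))
    return out


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def nei_gojobori(seq_a: str, seq_b: str) -> KaKsResult:
    """NG86 Ka/Ks on a pairwise codon alignment (equal-length, in-frame,
    gaps as '-').  Codons containing a gap or N in either sequence, and
    codon pairs where either codon is a stop, are excluded from counting.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    if len(a) % 3:
        raise ValueError("alignment length must be divisible by 3")

    S_a = S_b = Sd = Nd = 0.0
    n_codons = 0
    notes: list[str] = []
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if set(ca + cb) - set(_BASES):
            continue  # gap or ambiguity
        if ca in _STOPS or cb in _STOPS:
            continue
        n_codons += 1
        S_a += _syn_sites(ca)
        S_b += _syn_sites(cb)
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        return KaKsResult(S=0.0, N=0.0, Sd=0.0, Nd=0.0, ps=0.0, pn=0.0,
                          Ks=None, Ka=None, ka_ks=None, n_codons=0,
                          notes=("no countable codons",))
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_codons - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    if Ks is None:
        notes.append("Ks saturated (ps >= 3/4)")
    if Ka is None:
        notes.append("Ka saturated (pn >= 3/4)")
    ka_ks = None
    if Ka is not None and Ks is not None and Ks > 0:
        ka_ks = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ks=Ks, Ka=Ka,
                      ka_ks=ka_ks, n_codons=n_codons, notes=tuple(notes))


def mutation_rate_from_wgd(ks: float, wgd_age_years: float) -> float:
    """Per-site per-year mutation rate mu = Ks/(2T) from the Ks of
    paralog pairs created by a WGD of age T years.  The factor 2 accounts
    for divergence accumulating on both descendant lineages."""
    if wgd_age_years <= 0:
        raise ValueError("WGD age must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * wgd_age_years)


def monoploid_size_delta(total_assembly_mb: float, ploidy: int,
                         reference_size_mb: float) -> tuple[float, float]:
    """(monoploid size, monoploid minus reference) in Mb — e.g. a
    2738 Mb tetraploid assembly has a 685 Mb monoploid genome, 295 Mb
    larger than a 390 Mb diploid relative."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    mono = total_assembly_mb / ploidy
    return mono, mono - reference_size_mb
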