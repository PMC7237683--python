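"""Independent brute-force oracles used only by the test suite.

Deliberately written without reusing polyguide internals: the scanner
oracle is a numpy sliding-window Hamming comparison, the Ka/Ks oracle is
a plain exhaustive pathway enumeration over a literal genetic-code table,
and the IUPAC oracle expands ambiguity codes position by position.
"""

from __future__ import annotations

from itertools import permutations
from math import log

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# off-target scanning oracle


def brute_scan(guide: str, chromosomes: dict[str, str], max_mm: int,
               pams=("NGG", "NAG")) -> set[tuple[str, int, str, int]]:
    """All sites within max_mm mismatches of guide with an allowed PAM.

    Returns {(chrom, 1-based own-strand 5' start, strand, n_mm)}.  Windows
    containing non-ACGT bases, or with an invalid/ambiguous PAM, never
    match.
    """
    second = {"NGG": ord("G"), "NAG": ord("A")}
    allowed_second = {second[p] for p in pams}
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    g_fwd = np.frombuffer(guide.encode(), dtype=np.uint8)
    out = set()
    L = len(guide)
    for chrom, seq in chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(arr)
        if n < L + 3:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, L)
        clean = np.isin(win, acgt).all(axis=1)
        # plus strand: window at w, PAM at w+L..w+L+2
        mm = (win != g_fwd).sum(axis=1)
        for w in np.nonzero((mm <= max_mm) & clean)[0]:
            if w + L + 3 > n:
                continue
            p0, p1, p2 = arr[w + L:w + L + 3]
            if p0 in acgt and p1 in allowed_second and p2 == ord("G"):
                out.add((chrom, int(w) + 1, "+", int(mm[w])))
        # minus strand: forward window equals rc(site); compare to rc(guide)
        g_rev = np.frombuffer(rc(guide).encode(), dtype=np.uint8)
        mm2 = (win != g_rev).sum(axis=1)
        for w in np.nonzero((mm2 <= max_mm) & clean)[0]:
            if w < 3:
                continue
            # PAM on minus strand = rc(arr[w-3:w]); its pattern N[G/A]G
            q0, q1, q2 = arr[w - 3:w]
            pam = rc(chr(q0) + chr(q1) + chr(q2))
            if (pam[0] in "ACGT" and ord(pam[1]) in allowed_second
                    and pam[2] == "G"):
                out.add((chrom, int(w) + L, "-", int(mm2[w])))
    return out


# ---------------------------------------------------------------------------
# NG86 oracle

_ORDER = "TCAG"
_CODE = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
         "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
AA = {a + b + c: _CODE[16 * i + 4 * j + k]
      for i, a in enumerate(_ORDER)
      for j, b in enumerate(_ORDER)
      for k, c in enumerate(_ORDER)}


def _sites_one(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            other = codon[:pos] + b + codon[pos + 1:]
            if AA[other] != "*" and AA[other] == AA[codon]:
                s += 1.0 / 3.0
    return s


def _diffs_one(c1: str, c2: str) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    good, bad = [], []
    for order in permutations(positions):
        cur, sd, nd, hits_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if AA[nxt] == "*":
                hits_stop = True
            elif AA[cur] == AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (bad if hits_stop else good).append((sd, nd))
    if not good:
        good = []
        for order in permutations(positions):
            cur, sd, nd = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if AA.get(cur, "*") != "*" and AA[nxt] != "*" \
                        and AA[cur] == AA[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            good.append((sd, nd))
    return (sum(x[0] for x in good) / len(good),
            sum(x[1] for x in good) / len(good))


def ng86_oracle(s1: str, s2: str):
    """Exhaustive NG86 with Jukes-Cantor correction.  Returns a dict with
    S, N, Sd, Nd, ps, pn, Ks, Ka (None when saturated)."""
    assert len(s1) == len(s2) and len(s1) % 3 == 0
    Sa = Sb = Sd = Nd = 0.0
    n = 0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        if set(c1 + c2) - set("ACGT"):
            continue
        if AA[c1] == "*" or AA[c2] == "*":
            continue
        n += 1
        Sa += _sites_one(c1)
        Sb += _sites_one(c2)
        sd, nd = _diffs_one(c1, c2)
        Sd += sd
        Nd += nd
    S = (Sa + Sb) / 2.0
    N = 3.0 * n - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    jc = lambda p: None if p >= 0.75 else -0.75 * log(1 - 4.0 * p / 3.0)
    return dict(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
                Ks=jc(ps), Ka=jc(pn), n_codons=n)


# ---------------------------------------------------------------------------
# IUPAC site-matching oracle

_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
          "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
          "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}


def iupac_sites_oracle(pattern: str, subject: str) -> set[tuple[int, int]]:
    """0-based half-open intervals matching the pattern on either strand,
    by direct per-position set membership."""
    n = len(pattern)
    pats = [pattern.upper(), rc(pattern.upper())]
    out = set()
    for pat in pats:
        for i in range(len(subject) - n + 1):
            if all(subject[i + j] in _IUPAC[pat[j]] for j in range(n)):
                out.add((i, i + n))
    return out
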