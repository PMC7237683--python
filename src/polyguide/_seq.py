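"""Small shared sequence utilities: complements, IUPAC matching, GC."""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")

#: IUPAC nucleotide code -> set of concrete bases it matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(G+C)/length over an A/C/G/T/N sequence; N counts as non-GC.

    Raises ``ValueError`` on an empty sequence.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    return (s.count("G") + s.count("C")) / len(s)


def iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern into a regex over concrete A/C/G/T.

    Ambiguity codes in the *subject* are not expanded: an ``N`` in genomic
    sequence matches nothing but a literal pattern ``N`` never occurs in
    practice because callers match against upper-case A/C/G/T text, so an
    ``N`` base simply fails every character class.
    """
    parts = []
    for ch in pattern.upper():
        try:
            opts = IUPAC[ch]
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}") from None
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def iupac_find_all(pattern: str, subject: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) IUPAC matches."""
    rx = iupac_regex(pattern)
    hits, pos = [], 0
    while True:
        m = rx.search(subject, pos)
        if m is None:
            return hits
        hits.append(m.start())
        pos = m.start() + 1


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))
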