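"""Restriction-site aware screening design for CRISPR mutants (PCR-RE).

The screening trick: pick a guide whose predicted Cas9 cleavage point
(blunt cut 3 bp 5' of the PAM, i.e. between protospacer positions 17 and
18) falls inside a restriction enzyme recognition site.  Wild-type PCR
amplicons are then cleaved by the enzyme while edited alleles — whose
indels disrupt the site — resist digestion, so mutants are visible as
undigested bands on a gel.  BstUI (CG^CG) against the MsPALM1 guide
GGAGACGAGCACGGTCGCGG|CGG is the canonical example: CGCG sits at
protospacer positions 16–19, straddling the 17|18 cut.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from ._seq import iupac_find_all, revcomp

CUT_OFFSET_FROM_5P = 17  # blunt cut between protospacer positions 17|18


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut
    offset (cut falls after ``cut_offset`` bases of the site)."""

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self):
        if len(self.recognition_site) < 4:
            raise ValueError("recognition site must be >= 4 nt")
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError("cut offset outside recognition site")


@dataclass(frozen=True)
class DigestResult:
    fragment_lengths: tuple[int, ...]
    n_sites: int
    disrupted_by_edit: bool = False


def load_enzymes(path: str | Path | None = None) -> dict[str, Enzyme]:
    """Load the enzyme table (TSV: name, site, cut offset).  With no path,
    the small library shipped with the package is used (includes BstUI)."""
    if path is None:
        src = resources.files("polyguide").joinpath("data/enzymes.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    out = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        e = Enzyme(row["name"], row["recognition_site"].upper(),
                   int(row["cut_offset"]))
        out[e.name] = e
    return out


def predict_cut_site(guide_start: int, strand: str) -> int:
    """Genomic inter-base coordinate of the blunt Cas9 cut.

    ``guide_start`` is the 1-based coordinate of the protospacer 5' end on
    its own strand.  The returned integer ``c`` places the cut between
    plus-strand positions ``c`` and ``c+1``.
    """
    if strand == "+":
        return guide_start + CUT_OFFSET_FROM_5P - 1
    if strand == "-":
        return guide_start - CUT_OFFSET_FROM_5P
    raise ValueError("strand must be '+' or '-'")


def find_sites(enzyme: Enzyme, subject: str) -> list[tuple[int, int]]:
    """0-based half-open intervals of all recognition-site matches on
    either strand, each genomic interval reported once (palindromes and
    double-strand hits collapse)."""
    n = len(enzyme.recognition_site)
    ivs: set[tuple[int, int]] = set()
    for p in iupac_find_all(enzyme.recognition_site, subject.upper()):
        ivs.add((p, p + n))
    for p in iupac_find_all(revcomp(enzyme.recognition_site),
                            subject.upper()):
        ivs.add((p, p + n))
    return sorted(ivs)


def find_overlapping_sites(protospacer: str, pam: str, context: str,
                           enzymes: list[Enzyme],
                           ) -> list[tuple[Enzyme, tuple[int, int], bool]]:
    """All enzyme recognition sites in ``context`` and whether each
    overlaps the predicted cut of the embedded guide.

    ``context`` must contain protospacer+PAM on its plus strand.  Returns
    (enzyme, 0-based half-open interval, overlaps_cut) triples;
    ``overlaps_cut`` is true iff the site interval contains the cut
    inter-base strictly in its interior boundary sense: a cut after
    context position ``c`` lies within site (s, e) iff s < c < e
    measured in bases left of the cut.
    """
    context = context.upper()
    idx = context.find(protospacer.upper() + pam.upper())
    if idx < 0:
        raise ValueError("context must contain protospacer+PAM")
    cut = idx + CUT_OFFSET_FROM_5P  # bases left of the cut inter-base
    out = []
    for ez in enzymes:
        for (s, e) in find_sites(ez, context):
            out.append((ez, (s, e), s < cut < e))
    return out


def digest(amplicon: str, enzyme: Enzyme,
           reference: str | None = None) -> DigestResult:
    """In-silico digest: fragment lengths from leftmost non-overlapping
    top-strand cuts.  If ``reference`` is given, ``disrupted_by_edit`` is
    set when the edited amplicon has fewer sites than the reference."""
    amplicon = amplicon.upper()
    if len(amplicon) < len(enzyme.recognition_site):
        raise ValueError("amplicon shorter than recognition site")
    sites = find_sites(enzyme, amplicon)
    cuts, last_end = [], -1
    for (s, e) in sites:
        if s > last_end:  # leftmost non-overlapping occurrences
            cuts.append(s + enzyme.cut_offset)
            last_end = e - 1
    cuts = [c for c in cuts if 0 < c < len(amplicon)]
    frags, prev = [], 0
    for c in cuts:
        frags.append(c - prev)
        prev = c
    frags.append(len(amplicon) - prev)
    disrupted = False
    if reference is not None:
        n_ref = len(find_sites(enzyme, reference.upper()))
        disrupted = len(sites) < n_ref
    return DigestResult(fragment_lengths=tuple(frags), n_sites=len(cuts),
                        disrupted_by_edit=disrupted)
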