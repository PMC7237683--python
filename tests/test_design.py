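"""Guide enumeration and the five-criteria ranking."""

import re
from collections import Counter
from dataclasses import replace

import pytest

from polyguide import (GenomeIndex, OffTargetRule, ScoringWeights,
                       enumerate_guides, gc_fraction, locate_alleles,
                       rank_guides, revcomp, score_guide)
from conftest import PALM1_PROTO, make_fixture, planted_cds


def _with_summary(c, counts=None):
    return replace(c, offtarget_summary=Counter(counts or {}))


def test_printed_guide_enumerated_with_full_allele_coverage(palm1_genome,
                                                            palm1_alleles):
    cands = enumerate_guides(palm1_alleles, palm1_genome)
    best = [c for c in cands if c.protospacer == PALM1_PROTO]
    assert len(best) == 1
    c = best[0]
    assert c.pam == "CGG"
    assert c.allele_coverage == 4
    assert c.gc_fraction == pytest.approx(0.75)
    assert c.starts_with_g
    assert c.vector_spacer == PALM1_PROTO


def test_exon_without_ngg_yields_no_candidates():
    aset = locate_alleles("ATGAAATATAAATATAAATATAAATATAAATATAAATATAAATAT"
                          "AAATATAAATATAAA",
                          GenomeIndex({"c": "T" * 50
                                       + "ATGAAATATAAATATAAATATAAATATAAA"
                                         "TATAAATATAAATATAAATATAAATATAAA"
                                       + "T" * 50}),
                          min_identity=0.9, min_query_coverage=0.8)
    assert aset.copy_number == 1
    g = GenomeIndex({"c": "T" * 50 + "ATGAAATATAAATATAAATATAAATATAAATAT"
                     "AAATATAAATATAAATATAAATATAAA" + "T" * 50})
    assert enumerate_guides(aset, g) == []


def test_enumeration_matches_brute_force_regex_within_exons(
        palm1_fixture, palm1_genome, palm1_alleles):
    """Completeness: every [ACGT]{20}NGG occurrence inside an exon of any
    copy, on either strand, appears among the candidates."""
    expected = set()
    truth = palm1_fixture.truth
    for _, r in truth[truth.kind == "exon"].iterrows():
        chrom_seq = palm1_genome.chromosomes[r.chrom]
        for s0 in range(r.start - 1, r.end - 20 + 1):  # 0-based starts
            plus = chrom_seq[s0:s0 + 20]
            pam_p = chrom_seq[s0 + 20:s0 + 23]
            if re.fullmatch(r"[ACGT]{20}", plus) and \
                    re.fullmatch(r"[ACGT]GG", pam_p):
                expected.add(plus)
            pam_m = revcomp(chrom_seq[s0 - 3:s0]) if s0 >= 3 else ""
            if re.fullmatch(r"[ACGT]{20}", plus) and \
                    re.fullmatch(r"[ACGT]GG", pam_m):
                expected.add(revcomp(plus))
    got = {c.protospacer for c in
           enumerate_guides(palm1_alleles, palm1_genome)}
    assert expected == got


def test_reverse_complemented_fixture_yields_mirrored_guides(
        palm1_fixture, palm1_genome, palm1_alleles):
    flipped = GenomeIndex({n: revcomp(s)
                           for n, s in palm1_fixture.chromosomes.items()})
    aset = locate_alleles(planted_cds(palm1_fixture), flipped)
    mirrored = {c.protospacer
                for c in enumerate_guides(aset, flipped)}
    original = {c.protospacer
                for c in enumerate_guides(palm1_alleles, palm1_genome)}
    assert mirrored == original  # guides live on both strands already


def test_gc_fraction_examples():
    assert gc_fraction("GGGG") == 1.0
    assert gc_fraction("ATAT") == 0.0
    assert gc_fraction(PALM1_PROTO) == 0.75
    assert gc_fraction("GCNN") == 0.5  # N counted as non-GC
    with pytest.raises(ValueError):
        gc_fraction("")


def test_hard_filter_rejects_partial_allele_coverage(palm1_genome,
                                                     palm1_alleles):
    c = enumerate_guides(palm1_alleles, palm1_genome)[0]
    c3 = _with_summary(replace(c, allele_coverage=3))
    assert score_guide(c3, ploidy=4) is None
    c4 = _with_summary(replace(c, allele_coverage=4))
    assert score_guide(c4, ploidy=4) is not None


def test_offtarget_rule_filters_obvious_hits(palm1_genome, palm1_alleles):
    c = enumerate_guides(palm1_alleles, palm1_genome)[0]
    c = replace(c, allele_coverage=4)
    risky = _with_summary(c, {(2, "NGG"): 1})
    assert score_guide(risky, ploidy=4) is None
    distant = _with_summary(c, {(4, "NGG"): 7, (5, "NAG"): 3})
    assert score_guide(distant, ploidy=4) is not None
    lax = OffTargetRule(max_mismatches=1)
    assert score_guide(risky, ploidy=4, offtarget_rule=lax) is not None


def test_unscanned_candidate_raises_state_error(palm1_genome,
                                                palm1_alleles):
    c = enumerate_guides(palm1_alleles, palm1_genome)[0]
    with pytest.raises(RuntimeError, match="summary"):
        score_guide(c, ploidy=4)


def test_higher_gc_ranks_first_all_else_equal(palm1_genome, palm1_alleles):
    c = enumerate_guides(palm1_alleles, palm1_genome)[0]
    c = replace(c, allele_coverage=4)
    hi = _with_summary(replace(c, gc_fraction=0.75))
    lo = _with_summary(replace(c, gc_fraction=0.45))
    ranked = rank_guides([lo, hi], ploidy=4)
    assert ranked[0].gc_fraction == 0.75


def test_five_prime_g_satisfiable_by_prepending(palm1_genome,
                                                palm1_alleles):
    cands = enumerate_guides(palm1_alleles, palm1_genome)
    non_g = next(c for c in cands if not c.starts_with_g)
    non_g = _with_summary(replace(non_g, allele_coverage=4))
    scored = score_guide(non_g, ploidy=4)
    assert scored is not None
    assert scored.vector_spacer == "G" + scored.protospacer
    assert len(scored.vector_spacer) == 21
    assert score_guide(non_g, ploidy=4, strict_5g=True) is None


def test_relaxing_hard_filters_never_removes_candidates(palm1_genome,
                                                        palm1_alleles):
    cands = [_with_summary(c, {(3, "NAG"): 1}) if i % 2 else
             _with_summary(c)
             for i, c in
             enumerate(enumerate_guides(palm1_alleles, palm1_genome))]
    strict = {c.protospacer for c in rank_guides(
        cands, 4, offtarget_rule=OffTargetRule(3), strict_5g=True)}
    relaxed = {c.protospacer for c in rank_guides(
        cands, 4, offtarget_rule=OffTargetRule(0), strict_5g=False)}
    assert strict <= relaxed
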