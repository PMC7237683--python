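"""Cas9 off-target variant filtering: SNV exclusion, -3 proximity rule,
record conservation, coding-region summary."""

import pytest

from polyguide import (OffTargetHit, VariantRecord, filter_offtarget_variants,
                       read_cds_intervals, read_vcf,
                       summarize_coding_offtargets)
from polyguide.variants import CdsInterval


def _site(chrom="chr1.1", start=1001, strand="+", mm=3, on=False):
    return OffTargetHit(chromosome=chrom, strand=strand, start=start,
                        site_sequence="A" * 20, pam="AGG", pam_kind="NGG",
                        n_mismatches=mm, mismatch_positions=tuple(range(1, mm + 1)),
                        is_on_target=on)


# a plus-strand site starting at 1001 cuts after base 1017
SITE = _site()
CUT = 1017


def test_snv_exactly_at_minus3_is_never_a_candidate():
    v = VariantRecord("chr1.1", CUT, "A", "G")
    (vd,) = filter_offtarget_variants([v], [SITE])
    assert not vd.is_candidate
    assert vd.reason == "SNV excluded"


def test_deletion_at_minus3_is_a_candidate():
    v = VariantRecord("chr1.1", CUT, "AGT", "A")  # 2-bp deletion after 1017
    (vd,) = filter_offtarget_variants([v], [SITE])
    assert vd.is_candidate
    assert vd.matched_site == SITE
    assert vd.distance_to_minus3 == 0


def test_insertion_ten_bp_away_rejected_at_default_tolerance():
    v = VariantRecord("chr1.1", CUT + 10, "A", "AT")
    (vd,) = filter_offtarget_variants([v], [SITE])
    assert not vd.is_candidate
    assert vd.reason == "no off-target site nearby"


def test_indel_at_on_target_site_excluded_as_targeted_region():
    on_site = _site(on=True)
    v = VariantRecord("chr1.1", CUT, "AG", "A")
    (vd,) = filter_offtarget_variants([v], [on_site])
    assert not vd.is_candidate
    assert vd.reason == "targeted region"


def test_minus_strand_site_cut_coordinate():
    # 5' end at 2000 on '-': cut after forward base 1983
    site = _site(start=2000, strand="-")
    v = VariantRecord("chr1.1", 1983, "AT", "A")
    (vd,) = filter_offtarget_variants([v], [site])
    assert vd.is_candidate


def test_every_variant_gets_exactly_one_verdict(rng):
    variants = []
    for i in range(60):
        pos = int(rng.integers(900, 1100))
        kind = i % 3
        if kind == 0:
            variants.append(VariantRecord("chr1.1", pos, "A", "G"))
        elif kind == 1:
            variants.append(VariantRecord("chr1.1", pos, "AT", "A"))
        else:
            variants.append(VariantRecord("chr1.1", pos, "A", "ACC"))
    verdicts = filter_offtarget_variants(variants, [SITE])
    assert len(verdicts) == len(variants)
    assert [vd.variant for vd in verdicts] == variants
    # no verdict is both candidate and SNV
    assert not any(vd.is_candidate and vd.variant.type == "SNV"
                   for vd in verdicts)
    # all indels within tolerance of the -3 inter-base are candidates
    for vd in verdicts:
        expected = (vd.variant.type in ("insertion", "deletion")
                    and abs(vd.variant.event_interbase - CUT) <= 2)
        assert vd.is_candidate == expected


def test_raising_tolerance_never_shrinks_the_candidate_set():
    variants = [VariantRecord("chr1.1", CUT + d, "AT", "A")
                for d in range(-8, 9)]
    prev: set = set()
    for tol in range(0, 9):
        cand = {vd.variant for vd in
                filter_offtarget_variants(variants, [SITE], tolerance=tol)
                if vd.is_candidate}
        assert prev <= cand
        prev = cand


def test_failed_quality_records_kept_with_reason():
    v = VariantRecord("chr1.1", CUT, "AG", "A", passes_quality=False)
    (vd,) = filter_offtarget_variants([v], [SITE])
    assert not vd.is_candidate
    assert vd.reason == "failed quality"


CDS = [CdsInterval("chr1.1", 990, 1100, "geneA"),
       CdsInterval("chr1.2", 500, 800, "geneB")]


def test_coding_candidate_counted_per_gene():
    v_coding = VariantRecord("chr1.1", CUT, "AG", "A")
    site2 = _site(chrom="chr1.2", start=600)
    v_noncoding = VariantRecord("chr1.2", 617 + 300, "AG", "A")
    verdicts = filter_offtarget_variants([v_coding, v_noncoding],
                                         [SITE, site2], CDS)
    n, per_gene = summarize_coding_offtargets(verdicts, CDS)
    assert n == 1
    assert per_gene == {"geneA": 1}


def test_zero_candidates_summarise_to_zero():
    verdicts = filter_offtarget_variants(
        [VariantRecord("chr1.1", CUT, "A", "G")], [SITE], CDS)
    assert summarize_coding_offtargets(verdicts, CDS) == (0, {})


def test_intergenic_candidates_do_not_count_as_coding():
    v = VariantRecord("chr1.2", 2000 + 17, "AG", "A")
    site = _site(chrom="chr1.2", start=2000)
    verdicts = filter_offtarget_variants([v], [site], CDS)
    assert verdicts[0].is_candidate
    assert summarize_coding_offtargets(verdicts, CDS) == (0, {})


def test_vcf_and_gff_round_trip(tmp_path):
    vcf = tmp_path / "calls.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1.1,length=5000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1.1\t1017\t.\tAGT\tA\t50\tPASS\t.\n"
        "chr1.1\t1200\t.\tA\tG\t50\tPASS\t.\n"
        "chr1.1\t1300\t.\tA\tAT\t10\tq10\t.\n")
    recs = read_vcf(vcf)
    assert [r.type for r in recs] == ["deletion", "SNV", "insertion"]
    assert recs[2].passes_quality is False

    gff = tmp_path / "anno.gff3"
    gff.write_text("##gff-version 3\n"
                   "chr1.1\tx\tgene\t900\t1400\t.\t+\t.\tID=g1\n"
                   "chr1.1\tx\tCDS\t990\t1100\t.\t+\t0\tID=c1;Parent=g1\n")
    cds = read_cds_intervals(gff)
    assert cds == [CdsInterval("chr1.1", 990, 1100, "g1")]

    verdicts = filter_offtarget_variants(recs, [SITE], cds)
    assert [vd.is_candidate for vd in verdicts] == [True, False, False]
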