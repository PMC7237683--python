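"""Synthetic-fixture generator: determinism, truth-table exactness,
divergence calibration, clone-set simulation."""

import numpy as np
import pytest

from polyguide import GenomeIndex, fixtures as fx, revcomp
from conftest import make_fixture, make_gene


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    a = make_fixture(seed=7, decoys=[1, 3])
    b = make_fixture(seed=7, decoys=[1, 3])
    assert a.fasta() == b.fasta()
    assert a.gff3 == b.gff3
    assert a.truth.equals(b.truth)
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for k in pa:
        assert pa[k].read_bytes() == pb[k].read_bytes()


def test_zero_divergence_gives_identical_allele_sequences():
    f = make_fixture(seed=3, divergence=0.0)
    seqs = list(f.chromosomes.values())
    assert len(seqs) == 4
    assert len(set(seqs)) == 1


def test_realized_divergence_matches_request():
    d, L = 0.01, 40_000
    f = make_fixture(seed=5, divergence=d, length=L, gene=None)
    seqs = list(f.chromosomes.values())
    sd = np.sqrt(d * (1 - d) / L)
    for i in range(4):
        for j in range(i + 1, 4):
            obs = sum(a != b for a, b in zip(seqs[i], seqs[j])) / L
            assert abs(obs - d) <= 3 * sd


def test_truth_table_is_self_consistent():
    """Slicing the emitted FASTA at every truth coordinate reproduces the
    recorded sequence (guide sites and both-strand decoys)."""
    f = make_fixture(seed=9, decoys=[1, 2, 3, 4, 5])
    g = GenomeIndex(f.chromosomes)
    for _, r in f.truth[f.truth.kind == "guide_site"].iterrows():
        assert g.fetch(r.chrom, r.start, r.end) == r.sequence
    for _, r in f.truth[f.truth.kind == "decoy"].iterrows():
        if r.strand == "+":
            assert g.fetch(r.chrom, r.start, r.start + 19) == r.sequence
        else:
            assert revcomp(g.fetch(r.chrom, r.start - 19, r.start)) \
                == r.sequence


def test_planted_decoys_found_by_string_search():
    f = make_fixture(seed=7, decoys=[1, 3, 5, 6])
    decoys = f.truth[f.truth.kind == "decoy"]
    assert len(decoys) == 4
    assert sorted(decoys.mismatches) == [1, 3, 5, 6]
    for _, r in decoys.iterrows():
        seq = f.chromosomes[r.chrom]
        site = (r.sequence + r.pam if r.strand == "+"
                else revcomp(r.sequence + r.pam))
        start0 = (r.start - 1 if r.strand == "+"
                  else r.start - 20 - 3)
        assert seq.find(site, start0) == start0
        # planted mismatch count vs the target protospacer is exact
        proto = f.spec.target_gene.guides[0].protospacer
        assert sum(a != b for a, b in zip(r.sequence, proto)) \
            == r.mismatches


def test_gene_too_large_for_chromosome_is_rejected():
    with pytest.raises(ValueError, match="fit"):
        make_fixture(seed=1, length=500)


def test_invariants_of_spec_types():
    with pytest.raises(ValueError):
        fx.FixtureSpec(seed=1, ploidy=0)
    with pytest.raises(ValueError):
        fx.FixtureSpec(seed=1, allelic_divergence=1.0)
    with pytest.raises(ValueError):
        fx.DecoySite(mismatches=21)
    with pytest.raises(ValueError):  # decoys need a guide to derive from
        fx.FixtureSpec(seed=1, decoy_sites=(fx.DecoySite(1),))


# ---------------------------------------------------------------------------
# clone sets

AMP = ("ATTCGATCCTGAACTGTGCAATGCCTTACGT" + "GGAGACGAGCACGGTCGCGG" + "CGG"
       + "TGTTCAAGACCTTTGGATCATAGAACCATGA")
PROTO = "GGAGACGAGCACGGTCGCGG"


def test_all_wild_type_alleles_give_reference_clones():
    spec = fx.EditedCloneSpec(n_clones=8, allele_edits={i: None
                                                        for i in range(4)})
    clones, labels = fx.generate_clone_set(spec, AMP, PROTO)
    assert all(s == AMP for _, s in clones)
    assert set(labels.mutation_type) == {"wild-type"}


def test_four_distinct_deletions_give_four_types_no_wild_type():
    spec = fx.EditedCloneSpec(
        n_clones=30, seed=2,
        allele_edits={0: fx.Deletion(1), 1: fx.Deletion(2),
                      2: fx.Deletion(4), 3: fx.Deletion(5)})
    clones, labels = fx.generate_clone_set(spec, AMP, PROTO)
    assert len(clones) == 30
    assert labels.mutation_type.nunique() == 4
    assert "wild-type" not in set(labels.mutation_type)


def test_chimera_injection_adds_a_fifth_mutation_type():
    spec = fx.EditedCloneSpec(
        n_clones=20, seed=2, chimera_extra_types=1,
        allele_edits={0: fx.Deletion(1), 1: fx.Deletion(2),
                      2: fx.Deletion(4), 3: fx.Deletion(5)})
    _, labels = fx.generate_clone_set(spec, AMP, PROTO)
    assert labels.mutation_type.nunique() == 5


def test_sampling_proportions_validated_and_honoured():
    with pytest.raises(ValueError, match="sum to 1"):
        fx.EditedCloneSpec(n_clones=10, allele_edits={0: None, 1: None},
                           sampling_proportions={0: 0.8, 1: 0.8})
    spec = fx.EditedCloneSpec(n_clones=10,
                              allele_edits={0: None, 1: fx.Deletion(2)},
                              sampling_proportions={0: 0.3, 1: 0.7})
    _, labels = fx.generate_clone_set(spec, AMP, PROTO)
    assert labels.allele.value_counts().to_dict() == {"1": 7, "0": 3}


def test_edit_outside_amplicon_rejected():
    spec = fx.EditedCloneSpec(n_clones=2,
                              allele_edits={0: fx.Deletion(2, offset=500)})
    with pytest.raises(ValueError, match="outside"):
        fx.generate_clone_set(spec, AMP, PROTO)


def test_clone_set_missing_protospacer_rejected():
    spec = fx.EditedCloneSpec(n_clones=2, allele_edits={0: None})
    with pytest.raises(ValueError, match="protospacer"):
        fx.generate_clone_set(spec, "ACGT" * 30, PROTO)
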