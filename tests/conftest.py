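import numpy as np
import pytest

from polyguide import GenomeIndex, fixtures as fx, locate

PALM1_PROTO = "GGAGACGAGCACGGTCGCGG"
PDS_SPACER = "GCTGGAGGCAAGAGATGTTCT"  # 21-nt vector spacer (5'-G + 20)


def make_gene(protospacer=PALM1_PROTO, pam="CGG", two_exons=True):
    if two_exons:
        return fx.GeneSpec(exon_lengths=(180, 240), intron_lengths=(120,),
                           guides=(fx.EmbeddedGuide(0, 60, protospacer, pam),))
    return fx.GeneSpec(exon_lengths=(420,), intron_lengths=(),
                       guides=(fx.EmbeddedGuide(0, 60, protospacer, pam),))


def make_fixture(seed=7, decoys=(), ploidy=4, length=8000, divergence=1e-4,
                 groups=1, **kw):
    spec = fx.FixtureSpec(seed=seed, n_chromosome_groups=groups,
                          ploidy=ploidy, chromosome_length=length,
                          allelic_divergence=divergence,
                          target_gene=kw.pop("gene", make_gene()),
                          decoy_sites=tuple(fx.DecoySite(*d) if isinstance(d, tuple)
                                            else fx.DecoySite(d)
                                            for d in decoys), **kw)
    return fx.generate_genome(spec)


def planted_cds(fixture, chrom="chr1.1"):
    """Reconstruct the planted CDS of one copy from the truth table."""
    g = GenomeIndex(fixture.chromosomes)
    rows = fixture.truth
    exons = rows[(rows.kind == "exon") & (rows.chrom == chrom)]
    return "".join(g.fetch(r.chrom, r.start, r.end)
                   for _, r in exons.iterrows())


@pytest.fixture(scope="session")
def palm1_fixture():
    """Tetraploid fixture with the MsPALM1-style guide planted in all four
    allelic copies and no decoys."""
    return make_fixture(seed=11)


@pytest.fixture(scope="session")
def palm1_genome(palm1_fixture):
    return GenomeIndex(palm1_fixture.chromosomes)


@pytest.fixture(scope="session")
def palm1_alleles(palm1_fixture, palm1_genome):
    cds = planted_cds(palm1_fixture)
    return locate.locate_alleles(cds, palm1_genome, gene_id="MsPALM1")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
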