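"""Genotype an edited plant from simulated Sanger clones.

Simulates 30 clones from a tetraploid plant whose four alleles carry
four distinct deletions (a null mutant), calls each clone against the
wild-type amplicon and classifies the plant.  Also prints the printed-
style mutagenesis frequency arithmetic.
"""

from polyguide import (call_clone, classify_plant, fixtures as fx,
                       mutagenesis_frequency)

PROTO = "GGAGACGAGCACGGTCGCGG"
AMP = ("ATTCGATCCTGAACTGTGCAATGCCTTACG" + PROTO + "CGG"
       + "ACTTGCAAGACCTTTGGATCATAGAACCAT")
CUT = 30 + 17

spec = fx.EditedCloneSpec(
    n_clones=30, seed=5,
    allele_edits={0: fx.Deletion(1), 1: fx.Deletion(2),
                  2: fx.Deletion(4), 3: fx.Insertion("A")})
clones, labels = fx.generate_clone_set(spec, AMP, PROTO)

calls = [call_clone(seq, AMP, CUT, clone_id=cid) for cid, seq in clones]
g = classify_plant(calls, ploidy=4)
print(f"classification: {g.classification}")
print(f"mutation types ({g.n_mutation_types}): {list(g.mutation_types)}")
print(f"wild-type clones observed: {g.wild_type_observed}")
# No wild-type clone and four distinct edits -> all four alleles are
# disrupted: a null mutant in the first (T0) generation.

print("\nmutagenesis frequency for 5 mutants from 880 calli:",
      mutagenesis_frequency(5, 880), "%")
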