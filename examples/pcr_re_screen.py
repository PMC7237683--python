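"""PCR-RE screening design: a BstUI site on the Cas9 cut.

The MsPALM1-style guide GGAGACGAGCACGGTCGCGG|CGG carries CGCG at
protospacer positions 16-19, straddling the predicted blunt cut between
positions 17 and 18.  Wild-type amplicons are cleaved; a 2-bp deletion at
the cut destroys the site and the edited amplicon resists digestion.
"""

from polyguide import Enzyme, digest, find_overlapping_sites

PROTO, PAM = "GGAGACGAGCACGGTCGCGG", "CGG"
amp = ("ATTCGATCCTGAACTGTGCAATGCCTTACGTCTTACGATCATTGGACCTTAG"
       + PROTO + PAM
       + "ACTTGCAAGACCTTTGGATCATAGAACCATGGTTCAAGACCTTTGGATCAT")
bstui = Enzyme("BstUI", "CGCG", 2)

for ez, (s, e), overlaps in find_overlapping_sites(PROTO, PAM, amp, [bstui]):
    print(f"{ez.name} site at {s + 1}-{e}"
          + ("  <-- overlaps the predicted cut" if overlaps else ""))

wt = digest(amp, bstui)
print("wild-type bands:", list(wt.fragment_lengths))

cut = amp.find(PROTO) + 17
edited = amp[:cut - 1] + amp[cut + 1:]  # 2-bp deletion at the cut
res = digest(edited, bstui, reference=amp)
print("edited bands:  ", list(res.fragment_lengths),
      "| site disrupted:", res.disrupted_by_edit)
# A mutant shows the uncut (full-length) band where the wild type shows
# two digestion products - the gel readout used to screen edited plants.
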