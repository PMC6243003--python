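"""Intron phases and R-/V-type calls from a GFF3 gene model.

Builds a two-exon Group IIc-style gene whose phase-2 intron interrupts the
codon right after a conserved arginine upstream of the zinc finger — the
classic R-type intron — and shows how the typing decision is made.
"""

from familyscope.domains import scan_protein
from familyscope.structure import GeneModel, introns_of, type_domain_introns

CODON = {
    "M": "ATG", "W": "TGG", "R": "CGT", "K": "AAA", "Y": "TAT", "G": "GGT",
    "Q": "CAA", "A": "GCT", "C": "TGT", "H": "CAT", "V": "GTT",
}

protein = (
    "MAA" + "WRKYGQK" + "AAAAAAAR" + "AA"
    + "C" + "AAAA" + "C" + "AAAAAVA" + "A" * 16 + "HAH" + "AAAA"
)
cds = "".join(CODON[a] for a in protein) + "TAA"

# Split inside the codon after the conserved R (residue 17), phase 2.
cut = 3 * 18 + 2
intron = "GT" + "T" * 60 + "AG"
genome = {"chr1": cds[:cut] + intron + cds[cut:]}
gene = GeneModel(
    "g1", "g1.1", "chr1", "+",
    [(0, cut), (cut + len(intron), len(genome["chr1"]))],
)

for i in introns_of(gene):
    print(f"intron {i.index}: genomic {i.start}-{i.end}, phase {i.phase}")

domains = scan_protein("g1.1", protein)
for i in type_domain_introns(gene, domains, protein):
    print(f"typed: phase {i.phase} -> {i.type}-type "
          f"(codon of residue {i.host_codon_protein_index} interrupted)")

print("translation check:", gene.translate(genome) == protein)

# Phase 2 + last complete codon encoding R + position before the finger's
# first cysteine = R-type, the conserved intron of most WRKY groups.
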