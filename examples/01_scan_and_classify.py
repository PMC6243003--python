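"""Scan a tiny proteome for WRKY domains and classify the hits.

Builds three proteins in memory — a two-domain Group I protein, a single
C2HC Group III protein and a non-WRKY decoy — scans them with the motif
grammar and prints the resulting family records.
"""

from familyscope import classify
from familyscope.domains import scan_protein

PROTEINS = {
    "geneA.1": (
        "MSSTT"
        + "WRKYGQK" + "PVEKSLDRAA" + "C" + "AGDE" + "C" + "QVKKRVERSLDDPSMFIVTY" + "EG" + "HSH"
        + "GIDKSTLEQLNK"
        + "WRKYGQK" + "EIRNSADRSA" + "C" + "PMRK" + "C" + "AVKKRVERSLDDPSMFIVTYE" + "GD" + "HNH"
        + "ELPSTRS"
    ),
    "geneB.1": (
        "MDPFI"
        + "WRKYGQK" + "DILGAKFPRS" + "C" + "FRAGMKP" + "C" + "PVKKRVQRSADDPSLLITTYEGT" + "HNC"
        + "SEVAABLTRS".replace("B", "N")
    ),
    "decoy.1": "MGSTRENLIKQAEDFAGMRSPLTVNIDKEPGRSTQLMALDNFEKGIRSTV",
}

records = []
for pid, seq in PROTEINS.items():
    domains = scan_protein(pid, seq)
    print(f"{pid}: {len(domains)} WRKY domain(s)")
    for d in domains:
        print(
            f"  {d.role_in_protein:6s} "
            f"heptapeptide={d.heptapeptide.variant if d.heptapeptide else '-'} "
            f"finger={d.signature or '-'} ({d.completeness})"
        )
    if domains:
        rec = classify.FamilyRecord(pid, classify.gene_id_of(pid), seq, domains)
        records.append(classify.assign_group(rec))

for rec in records:
    print(f"{rec.protein_id} -> group {rec.group} (evidence: {rec.evidence})")

# geneA has two domains, hence Group I; geneB's single C2HC finger puts it
# in Group III; the decoy produces no record at all.
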