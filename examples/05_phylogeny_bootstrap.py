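"""Align WRKY domain sequences, build an NJ tree and bootstrap it.

Two pairs of near-identical domains are aligned; neighbor joining should
separate the pairs, and the bootstrap should support that split strongly.
"""

from familyscope import phylo

DOMAINS = {
    "Va_1": "WRKYGQKPVEKSLDRAACAGDECQVKKRVERSL",
    "Va_2": "WRKYGQKPVEKSLDRSACAGDECQVKKRVERSL",
    "Vr_1": "WRKYGQKDILGAKFPRSCFRAGMKPCPVKKRVA",
    "Vr_2": "WRKYGQKDILGAKFPRSCFRAGMKPCPVKKRVQ",
}

aln = phylo.progressive_align(list(DOMAINS.values()), list(DOMAINS))
print(f"alignment: {len(aln.rows)} rows x {aln.n_sites} columns")

dm = phylo.p_distance(aln)
print("p-distances:")
for i, a in enumerate(dm.ids):
    print(" ", a, [round(float(x), 3) for x in dm.matrix[i]])

tree = phylo.bootstrap(aln, n_replicates=1000, seed=7)
print("NJ tree with bootstrap supports:", tree.newick())

label, margin = phylo.nearest_reference(
    DOMAINS["Va_2"], [("r1", "cladeA", DOMAINS["Va_1"]), ("r2", "cladeB", DOMAINS["Vr_1"])]
)
print(f"nearest reference for Va_2: {label} (margin {margin:.3f})")

# The (Va_1,Va_2) vs (Vr_1,Vr_2) split is supported by many alignment
# columns, so its bootstrap support sits near 100.
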