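"""Percentage distribution of a WRKY family from per-group gene counts.

Uses the published per-group gene counts of the Adzuki bean (84 genes) and
Mung bean (85 genes) WRKY families and prints the group shares the way a
distribution figure would report them.
"""

from familyscope import classify

ADZUKI = {"I": 15, "IIa": 5, "IIb": 14, "IIc": 20, "IId": 7, "IIe": 10, "III": 13}
MUNG = {"I": 16, "IIa": 1, "IIb": 19, "IIc": 20, "IId": 7, "IIe": 9, "III": 13}

for name, counts in (("Adzuki bean", ADZUKI), ("Mung bean", MUNG)):
    s = classify.summarize(counts)
    print(f"{name}: {s.total} WRKY genes")
    for group in classify.GROUPS:
        print(f"  {group:4s} {s.counts[group]:3d}  {s.percentages[group]:5.1f}%")
    print(f"  IIa+IIb combined ~ {s.combined_IIa_IIb}%")

# The two distributions are nearly identical (e.g. Group I 17.9% vs 18.8%),
# the classic signature of two closely related Vigna genomes.
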