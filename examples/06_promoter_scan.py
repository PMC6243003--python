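"""Extract a promoter and scan it for cis-regulatory elements.

Plants an ABA-responsive ABRELATERD1 core (ACGTG) and a drought/cold
DRECRTCOREAT core (RCCGAC) into a synthetic promoter and reports the hits
relative to the start codon (offset -1 = base immediately 5' of ATG).
"""

import numpy as np

from familyscope.promoters import Promoter, load_elements, scan
from familyscope.structure import GeneModel
from familyscope.promoters import extract_promoter

rng = np.random.default_rng(0)
upstream = list("".join(rng.choice(list("AT"), size=1500)))
upstream[1500 - 1200 : 1500 - 1195] = list("ACGTG")     # offset -1200
upstream[1500 - 500 : 1500 - 494] = list("GCCGAC")      # offset -500
contig = "".join(upstream) + "ATG" + "GCTTAA" + "A" * 50

gene = GeneModel("g1", "g1.1", "chr1", "+", [(1500, 1509)])
promoter = extract_promoter({"chr1": contig}, gene)
print(f"promoter length: {len(promoter.sequence)} bp (truncated: {promoter.truncated})")

for hit in scan(promoter, load_elements()):
    print(f"  {hit.element:14s} offset {hit.offset:6d} strand {hit.strand}  {hit.sequence}")

# Both planted elements are reported at their planted offsets; the AT-rich
# filler cannot harbour the other dictionary motifs, so nothing else fires.
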