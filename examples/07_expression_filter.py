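"""Apply the FPKM detection threshold and the log2(FPKM+1) transform.

A small gene-by-tissue FPKM table straddles the 0.5 threshold: one gene is
clearly expressed, one sits exactly at the threshold (counted, inclusive),
one stays below it and one is all-zero (reported separately).
"""

import pandas as pd

from familyscope.expression import expressed_genes, log_transform

fpkm = pd.DataFrame(
    {
        "leaf": [56.68, 0.5, 0.4, 0.0],
        "root": [0.85, 0.0, 0.49, 0.0],
    },
    index=["WRKY7", "WRKY_at_threshold", "WRKY_low", "WRKY_silent"],
)

call = expressed_genes(fpkm)
print("expressed:        ", sorted(call.expressed))
print("below threshold:  ", sorted(call.below_threshold))
print("not detected:     ", sorted(call.not_detected))

print("\nlog2(FPKM+1) for plotting:")
print(log_transform(fpkm).round(2).to_string())

# 0 maps to 0 and 7 would map to 3 exactly; the pseudocount keeps all
# plotting-scale values nonnegative.
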