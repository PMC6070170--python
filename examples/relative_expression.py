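"""Livak 2^-ddCt fold changes from a replicate Ct table.

Three technical replicates per (gene, tissue) are averaged on the Ct scale;
fold changes are expressed relative to an explicit calibrator tissue with a
reference gene normalizing within each tissue.
"""

import pandas as pd

from mirscout import band_relative, ddct_fold_change
from mirscout.expression import ddct_table

rows = []
for tissue, cts in (("stem", (19.8, 20.1, 20.1)), ("leaf", (22.0, 22.2, 21.8)),
                    ("capsule", (25.0, 25.1, 24.9))):
    rows += [{"gene": "mirX", "tissue": tissue, "replicate": i, "ct": ct}
             for i, ct in enumerate(cts)]
    rows += [{"gene": "rRNA5.8S", "tissue": tissue, "replicate": i, "ct": 15.0}
             for i in range(3)]

records = ddct_table(pd.DataFrame(rows), reference_gene="rRNA5.8S",
                     calibrator_tissue="capsule")
for r in records:
    print(f"{r.gene_id} in {r.tissue:8s}: {r.relative_level:6.2f}x")

print("\nsingle quadruple:", ddct_fold_change(20, 15, 25, 15), "x")
print("band densitometry:", band_relative(200, 50, 100, 50), "x")

# Fold changes are relative to the capsule calibrator (exactly 1.0 there by
# construction); stem shows the highest level.  The quadruple (20,15,25,15)
# gives ddCt=-5, i.e. 32x; the band example doubles the calibrator ratio.
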