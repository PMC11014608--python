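"""The four log-fold-change formulas on one dropout scenario.

A gene is absent in a small cluster (100 cells, mean 0) but expressed at
mean 1 in the remaining 10,000 cells.  The true ratio is 0/1, so the
reported logFC is entirely an artifact of each formula's pseudocount:
the 1/n pseudocount gives about -6.6, the unit pseudocount compresses to
about -1, and the 1e-9 pseudocount explodes to about -29.9.
"""

import numpy as np

import sccompare as sc

n1, n2 = 100, 10_000
Y = np.concatenate([np.zeros(n1), np.full(n2, np.log1p(1.0))])[:, None]
nm = sc.NormMatrix(Y=Y, size_factor=np.ones(n1 + n2),
                   barcodes=[f"C{i}" for i in range(n1 + n2)],
                   features=["GENE"])
g1, g2 = np.arange(n1), np.arange(n1, n1 + n2)

for formula in ("reference", "seurat_v5", "seurat_v4", "scanpy"):
    val = sc.logfc(nm, g1, g2, formula=formula)[0]
    print(f"{formula:12s} logFC = {val:8.2f}")
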