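"""Score immune-cell gene sets in single samples with ssGSEA.

Builds a tiny expression matrix, scores two gene sets, and shows the
rank-invariance that makes the method robust to monotone normalization
differences between platforms.
"""

import numpy as np
import pandas as pd

from tics import ExpressionMatrix, GeneSetCollection, ssgsea_matrix

rng = np.random.default_rng(0)

genes = [f"g{i:02d}" for i in range(30)]
samples = ["patient_A", "patient_B", "patient_C"]
expr = ExpressionMatrix(
    pd.DataFrame(rng.normal(7, 2, size=(30, 3)), index=genes, columns=samples)
)
# patient_A overexpresses the first set's genes
expr.values.loc[genes[:8], "patient_A"] += 3.0

sets = GeneSetCollection({"cytotoxic-like": genes[:8], "myeloid-like": genes[10:18]})
scores = ssgsea_matrix(expr, sets, alpha=0.25)
print("enrichment scores (rows = gene sets, columns = samples):")
print(scores.scores.round(3))

# a monotone transform of the expression changes nothing
squashed = ExpressionMatrix(np.tanh(expr.values / 10) * 100)
scores2 = ssgsea_matrix(squashed, sets, alpha=0.25)
print("\nmax |difference| after a monotone transform of the input:",
      float((scores.scores - scores2.scores).abs().values.max()))
# The positive score for cytotoxic-like in patient_A reflects the planted
# overexpression; identical scores after the transform show the method
# depends only on within-sample expression ranks.
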