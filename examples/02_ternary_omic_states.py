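"""Discretize CNA focal scores and RNA-seq expression into ternary states.

CNA states are the sign of the focal score.  RNA states compare each
tumor value against a per-gene Gaussian fit to normal-tissue samples:
beyond two standard deviations is activated/repressed, otherwise
normal (the 2 SD two-sided tail is ~4.6%, just under the usual .05).
"""

import numpy as np
import pandas as pd

from pathact import cna_state, fit_rna_reference, rna_state

genes = ["CD28", "CD86", "TP53"]
cna = pd.DataFrame(
    {"tumor1": [0.4, -0.2, 0.0], "tumor2": [0.0, 0.3, -0.5]}, index=genes
)
rng = np.random.default_rng(0)
normal = pd.DataFrame(
    rng.normal([[8.0], [6.0], [7.0]], 0.5, size=(3, 20)),
    index=genes,
    columns=[f"normal{i}" for i in range(20)],
)
tumor = pd.DataFrame(
    {"tumor1": [10.1, 6.1, 7.2], "tumor2": [8.1, 3.9, 6.8]}, index=genes
)

ref = fit_rna_reference(normal)
print("reference mean/sd per gene:")
print(pd.DataFrame({"mean": ref.mean.round(2), "sd": ref.sd.round(2)}))
print()
print("CNA states (sign of focal score):")
print(cna_state(cna).astype(int))
print()
print("RNA states (beyond mean +/- 2 sd of the normal reference):")
print(rna_state(tumor, ref, k_sd=2.0).astype(int))
print()
print("+1 = activated, 0 = normal, -1 = repressed.  CD28 in tumor1 is")
print("amplified and overexpressed; CD86 in tumor2 is underexpressed")
print("despite a copy-number gain — the factor graph reconciles such")
print("conflicts using the pathway context.")
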