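"""Infer pathway activity (IPLs) on a small network, including a conflict.

Each observed protein carries dna -> rna -> activity ternary variables;
observations attach with noise eta, regulation factors with noise
epsilon, and sum-product BP yields per-entity marginals.  The IPL is
log10(p_activated / p_repressed) of the activity marginal: positive =
more likely activated.
"""

import pandas as pd

from pathact import (
    build_factor_graph,
    compute_ipl,
    exact_posteriors,
    infer_posteriors,
)
from pathact.pathway_io import Entity, Interaction, PathwayNetwork

net = PathwayNetwork(
    entities={
        "CD86": Entity("CD86", "protein"),
        "CD28": Entity("CD28", "protein"),
        "CD28_CD86": Entity("CD28_CD86", "complex"),
    },
    interactions=[
        Interaction("CD86", "CD28_CD86", "component"),
        Interaction("CD28", "CD28_CD86", "component"),
    ],
)

# CD86: copy-number loss but RNA overexpression (conflicting omics);
# CD28: coherent activation on both layers
cna = pd.Series({"CD86": -1.0, "CD28": 1.0})
rna = pd.Series({"CD86": 1.0, "CD28": 1.0})

fg = build_factor_graph(net, cna, rna)
post = infer_posteriors(fg)
ipl = compute_ipl(post)

print("variables:", len(fg.variables), " factors:", len(fg.factors))
print()
print("activity marginals (p_repressed, p_normal, p_activated):")
for name in ("CD86", "CD28", "CD28_CD86"):
    p = post.probs[(name, "activity")]
    print(f"  {name:10s} {p.round(3)}")
print()
print("IPLs:", ipl.round(3).to_dict())
print()
oracle = exact_posteriors(fg)
gap = max(
    abs(post.probs[v] - oracle.probs[v]).max() for v in fg.variables
)
print(f"BP vs exhaustive enumeration, max gap: {gap:.2e} (exact on trees)")
print()
print("CD86's conflicting omics leave a mildly positive IPL (RNA wins on")
print("the activity layer); the complex needs BOTH components, so its")
print("activation follows the weaker member (min rule).")
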