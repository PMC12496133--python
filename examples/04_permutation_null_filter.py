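"""Filter IPLs against a within-patient permutation null.

For each patient, (CNA, RNA) state pairs are shuffled between genes —
pairs never split — and IPLs are recomputed on every permuted sample.
A real IPL within three median absolute deviations of its permuted
distribution is indistinguishable from chance and set to NA; the
largest connected component of survivors defines the pathway states.
"""

import pandas as pd

from pathact import (
    PermutationPlan,
    cna_state,
    fit_rna_reference,
    generate_permutations,
    infer_cohort_ipls,
    mad_filter_matrix,
    pathway_states,
    rna_state,
    simulate_cohort,
    make_toy_network,
    CohortSpec,
)

net = make_toy_network(25, wiring="complex-modules", module_size=7)
sim = simulate_cohort(net, CohortSpec(n_patients=4, seed=3))

cna_st = cna_state(sim["cna"])
rna_st = rna_state(sim["rna_tumor"], fit_rna_reference(sim["rna_normal"]))

ipls, _ = infer_cohort_ipls(net, cna_st, rna_st)
perm_cna, perm_rna = generate_permutations(
    cna_st, rna_st, PermutationPlan(n_perm=20, seed=3)
)
print(f"{cna_st.shape[1]} patients x 20 permutations -> "
      f"{perm_cna.shape[1]} permuted samples")

perm_ipls, _ = infer_cohort_ipls(net, perm_cna, perm_rna)
filtered, null = mad_filter_matrix(ipls, perm_ipls, k_mad=3.0)
states, retained = pathway_states(filtered, net)

n_nonzero = (ipls.abs() > 1e-9).sum()
n_kept = filtered.notna().sum()
print("\nper patient: entities with nonzero IPL -> surviving the null filter")
for p in ipls.columns:
    print(f"  {p}: {int(n_nonzero[p]):2d} -> {int(n_kept[p]):2d}"
          f"   retained component size {len(retained[p])}")
print()
carriers = sim["truth"]["is_carrier"]
print("carriers:", list(carriers.index[carriers]))
print("the planted module survives in carriers; background alterations are")
print("mostly filtered or stranded as singletons outside the retained set.")
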