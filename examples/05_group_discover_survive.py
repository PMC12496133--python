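"""Full workflow on a synthetic cohort: profiles, groups, submodules,
key proteins and survival.

Half the patients carry a planted activated module (coherent CNA + RNA
shifts on a ring of 7 proteins).  The pipeline builds per-patient
overrepresentation profiles over gene sets, clusters patients, mines
the groups for consistently altered submodules, and tests whether
key-protein activation stratifies survival.
"""

from sklearn.metrics import adjusted_rand_score

from pathact import (
    CohortSpec,
    PipelineConfig,
    make_gene_sets,
    make_toy_network,
    run_pipeline,
    simulate_cohort,
)

net = make_toy_network(25, wiring="complex-modules", module_size=7)
spec = CohortSpec(seed=1)  # 20 patients, 50% carriers, RNA effect 3 SD
sim = simulate_cohort(net, spec)
sets = make_gene_sets(net, sim["planted"], seed=1)

res = run_pipeline(
    net, sets, sim["cna"], sim["rna_tumor"], sim["rna_normal"],
    clinical=sim["survival"][["time", "event"]],
    config=PipelineConfig(n_perm=20, k_groups=2, seed=1),
)

truth = sim["truth"]["is_carrier"].astype(int)
ari = adjusted_rand_score(truth.loc[res.groups.index], res.groups)
print(f"grouping vs planted carriers: adjusted Rand index = {ari:.2f}")
print("group sizes:", res.groups.value_counts().to_dict())

for g, subs in res.submodules.items():
    for s in subs:
        keys = [p for p, d in s.key]
        print(f"\ngroup {g} submodule: {len(s.entities)} entities, "
              f"{len(s.proteins)} proteins")
        print("  key proteins (same nonzero state in every group patient):",
              keys)

if res.survival_results is not None and len(res.survival_results):
    row = res.survival_results.iloc[0]
    print(f"\nsurvival stratified by key-protein activation: "
          f"log-rank stat {row['statistic']:.3f}, P = {row['p_value']:.4f} "
          f"({row['n_activated']} activated vs {row['n_other']} other)")
print("\nplanted genes:", sim["planted"])
print("Carriers cluster apart because only they keep the planted module")
print("after the permutation-null filter; its proteins come back as key")
print("proteins, and their activation tracks the simulated survival benefit.")
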