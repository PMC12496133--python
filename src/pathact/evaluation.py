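"""Calibration and recovery studies on synthetic cohorts.

These routines re-measure, from scratch, the quantitative behaviour the
package is designed around: permutation accounting, the Gaussian-tail
rationale of the RNA threshold, agreement of belief propagation with
brute-force enumeration, agreement of the overrepresentation test with
an independent exact-test oracle, the MAD filter's keep/drop decisions,
planted-signal recovery of the full pipeline, and null calibration of
the log-rank test and the enrichment false-positive rate.  They are
used by the acceptance test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .discovery import logrank_test
from .factor_graph import build_factor_graph, exact_posteriors, infer_posteriors
from .ipl_filter import mad_filter
from .perm_null import PermutationPlan, generate_permutations
from .pipeline import PipelineConfig, run_pipeline
from .profiles import fisher_overrepresentation_p, overrepresentation
from .synthetic import CohortSpec, make_gene_sets, make_toy_network, simulate_cohort

__all__ = [
    "permutation_accounting",
    "gaussian_two_sd_tail",
    "bp_enumeration_max_error",
    "fisher_oracle_max_error",
    "mad_filter_decisions",
    "planted_recovery_suite",
    "logrank_null_uniformity",
    "null_enrichment_fraction",
]


def permutation_accounting(
    n_patients: int = 492, n_perm: int = 100, n_genes: int = 10, seed: int = 0
) -> int:
    """Number of permuted pseudo-samples for a cohort (n_patients x n_perm)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    pats = [f"p{i}" for i in range(n_patients)]
    cna = pd.DataFrame(
        rng.choice([-1.0, 0.0, 1.0], (n_genes, n_patients)), index=genes, columns=pats
    )
    rna = pd.DataFrame(
        rng.choice([-1.0, 0.0, 1.0], (n_genes, n_patients)), index=genes, columns=pats
    )
    perm_cna, perm_rna = generate_permutations(
        cna, rna, PermutationPlan(n_perm=n_perm, seed=seed)
    )
    assert perm_cna.shape == perm_rna.shape
    return int(perm_cna.shape[1])


def gaussian_two_sd_tail() -> float:
    """Two-sided Gaussian tail mass beyond 2 SD (~0.0455, below .05)."""
    from scipy.stats import norm

    return float(2.0 * norm.sf(2.0))


def _random_acyclic_fixture(rng: np.random.Generator):
    n = int(rng.integers(2, 5))  # <= 4 observed proteins -> <= 12 variables
    proteins = [f"P{i}" for i in range(n)]
    from .pathway_io import Entity, Interaction, PathwayNetwork

    edges = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        rel = str(
            rng.choice(
                [
                    "protein-activate",
                    "protein-repress",
                    "transcript-activate",
                    "transcript-repress",
                ]
            )
        )
        edges.append(Interaction(proteins[j], proteins[i], rel))
    net = PathwayNetwork(
        entities={p: Entity(p, "protein") for p in proteins}, interactions=edges
    )
    vals = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(2, n))
    cna = pd.Series(vals[0], index=proteins)
    rna = pd.Series(vals[1], index=proteins)
    return net, cna, rna


def bp_enumeration_max_error(n_fixtures: int = 100, seed: int = 0) -> float:
    """Worst per-probability gap between BP and enumeration on acyclic fixtures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        net, cna, rna = _random_acyclic_fixture(rng)
        fg = build_factor_graph(net, cna, rna)
        bp = infer_posteriors(fg)
        ex = exact_posteriors(fg)
        for v in fg.variables:
            worst = max(worst, float(np.abs(bp.probs[v] - ex.probs[v]).max()))
    return worst


def fisher_oracle_max_error(
    max_exhaustive_n: int = 60,
    n_random: int = 2000,
    max_n: int = 200,
    seed: int = 0,
) -> float:
    """Worst |P - oracle| vs scipy's exact test over 2x2 tables.

    Exhaustive for universes up to ``max_exhaustive_n``; seeded random
    tables up to ``max_n`` beyond that.
    """
    from scipy.stats import fisher_exact

    worst = 0.0

    def check(k, K, n, N):
        nonlocal worst
        table = [[k, K - k], [n - k, N - K - (n - k)]]
        _, expected = fisher_exact(table, alternative="greater")
        got = fisher_overrepresentation_p(k, K, n, N)
        worst = max(worst, abs(got - expected))

    for N in range(1, max_exhaustive_n + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                lo, hi = max(0, K + n - N), min(K, n)
                for k in (lo, (lo + hi) // 2, hi):
                    check(k, K, n, N)
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        N = int(rng.integers(max_exhaustive_n + 1, max_n + 1))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        lo, hi = max(0, K + n - N), min(K, n)
        k = int(rng.integers(lo, hi + 1))
        check(k, K, n, N)
    return worst


def mad_filter_decisions() -> dict:
    """The worked keep/drop decisions of the null filter.

    Null of 50 values at -0.1 and 50 at +0.1 has median 0 and MAD 0.1:
    a real IPL of 0.25 sits inside three MADs (dropped), 0.35 outside
    (kept); a constant null drops its own value.
    """
    perms = [-0.1] * 50 + [0.1] * 50
    return {
        "inside_dropped": bool(np.isnan(mad_filter(0.25, perms, 3.0))),
        "outside_kept_value": float(mad_filter(0.35, perms, 3.0)),
        "constant_null_dropped": bool(np.isnan(mad_filter(0.5, [0.5] * 100, 3.0))),
    }


def _planted_module_closure(net, planted):
    planted = set(planted)
    components: dict[str, set] = {}
    for it in net.interactions:
        if it.relation == "component":
            components.setdefault(it.target, set()).add(it.source)
    return planted | {c for c, mem in components.items() if mem <= planted}


def planted_recovery_run(seed: int) -> tuple[float, bool]:
    """One planted-cohort pipeline run: (ARI vs truth, submodule recovered).

    Study conditions: 50-entity complex-module network (25 proteins in
    rings of 7), 20 patients with 50% carriers, RNA effect 3 SD, 20
    permutations per patient, two groups.  Submodule recovery means a
    reported submodule lies inside the planted module (planted proteins
    plus complexes wholly made of them), has >= 5 entities, and all of
    its proteins are key proteins with the planted direction.
    """
    from sklearn.metrics import adjusted_rand_score

    net = make_toy_network(25, wiring="complex-modules", module_size=7)
    spec = CohortSpec(seed=seed)
    sim = simulate_cohort(net, spec)
    sets = make_gene_sets(net, sim["planted"], seed=seed)
    cfg = PipelineConfig(n_perm=20, k_groups=2, seed=seed)
    res = run_pipeline(
        net, sets, sim["cna"], sim["rna_tumor"], sim["rna_normal"], config=cfg
    )
    truth = sim["truth"]["is_carrier"].astype(int)
    ari = float(adjusted_rand_score(truth.loc[res.groups.index], res.groups))
    closure = _planted_module_closure(net, sim["planted"])
    direction = spec.direction
    recovered = any(
        set(s.entities) <= closure
        and len(s.entities) >= cfg.min_submodule_size
        and len(s.key) >= 1
        and {p for p, _ in s.key} == set(s.proteins)
        and all(d == direction for _, d in s.key)
        for subs in res.submodules.values()
        for s in subs
    )
    return ari, recovered


def planted_recovery_suite(base_seed: int = 0, n_seeds: int = 10) -> dict:
    """ARI and submodule recovery over ``n_seeds`` planted cohorts."""
    aris = []
    recovered = []
    for k in range(n_seeds):
        ari, ok = planted_recovery_run(base_seed + k)
        aris.append(ari)
        recovered.append(ok)
    return {
        "aris": aris,
        "n_ari_pass": int(sum(a >= 0.8 for a in aris)),
        "n_submodule_recovered": int(sum(recovered)),
        "n_seeds": n_seeds,
    }


def logrank_null_uniformity(n_runs: int = 200, seed: int = 0) -> dict:
    """Log-rank P under a hazard-ratio-1 null: KS distance from uniform."""
    from scipy.stats import kstest

    rng = np.random.default_rng(seed)
    pvals = []
    while len(pvals) < n_runs:
        n = 40
        time = rng.exponential(1500.0, n)
        censor = rng.uniform(0, 3000.0, n)
        obs = np.minimum(time, censor)
        event = (time <= censor).astype(int)
        strata = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        rng.shuffle(strata)
        if event.sum() == 0:
            continue
        surv = pd.DataFrame({"time": obs, "event": event, "stratum": strata})
        _, p = logrank_test(surv)
        pvals.append(p)
    ks = kstest(pvals, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}


def null_enrichment_fraction(
    n_patients: int = 25, n_sets: int = 40, seed: int = 0
) -> float:
    """Fraction of gene sets reaching adjusted P < .05 under a global null."""
    from .pathway_io import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = sorted(f"g{i}" for i in range(60))
    sets = GeneSetCollection(
        sets={
            f"S{j}": frozenset(rng.choice(universe, size=10, replace=False))
            for j in range(n_sets)
        },
        descriptions={},
    )
    n_sig = 0
    n_tot = 0
    for _ in range(n_patients):
        states = pd.Series(rng.choice([0.0, 1.0], size=60), index=universe)
        df = overrepresentation(states, sets, set(universe))
        n_sig += int((df["adj_p"] < 0.05).sum())
        n_tot += len(df)
    return n_sig / n_tot
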