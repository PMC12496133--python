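"""Synthetic pathway networks and multi-omic cohorts with planted signal.

The generator emulates the statistical structure the pipeline assumes:

* a toy pathway network (chain / tree / one-loop wiring of protein
  activations, optionally decorated with complexes);
* normal-tissue RNA drawn from per-gene Gaussians, tumor RNA equal in
  distribution for non-carriers;
* a *planted* chain of proteins whose RNA is shifted by ``delta``
  reference standard deviations and whose CNA focal scores take the
  planted direction with a set probability, in a *carrier* subset of
  patients (both omic layers move coherently by default; either layer
  can be decoupled to emulate single-omic-only signal);
* exponential survival with a carrier hazard ratio and independent
  uniform censoring.

Everything is a pure function of the seed, and all outputs round-trip
through the package's TSV readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathway_io import Entity, GeneSetCollection, Interaction, PathwayNetwork

__all__ = ["CohortSpec", "make_toy_network", "simulate_cohort", "make_gene_sets"]


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort.

    ``delta`` is the planted RNA effect size in units of the per-gene
    reference SD; ``cna_prob`` the chance a planted gene's CNA focal
    score takes the planted direction in a carrier.  ``n_decoy_genes``
    adds measured genes that are absent from the pathway network, as in
    real cohorts where the assay covers far more genes than the network
    does; decoys carry background noise only, and their main effect is
    to dilute where within-patient permutations place the altered state
    pairs.  Survival times are exponential with ``baseline_hazard``
    (per day), multiplied by ``hazard_ratio`` for carriers, censored
    uniformly on [0, censor_horizon].
    """

    n_patients: int = 20
    n_normals: int = 10
    carrier_fraction: float = 0.5
    chain_length: int = 7
    direction: int = 1
    delta: float = 3.0
    cna_prob: float = 0.8
    background_cna_prob: float = 0.05
    n_decoy_genes: int = 120
    baseline_hazard: float = 1.0 / 1500.0
    hazard_ratio: float = 0.4
    censor_horizon: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in [0, 1]")
        if not (0 <= self.cna_prob <= 1 and 0 <= self.background_cna_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")
        if self.n_decoy_genes < 0:
            raise ValueError("n_decoy_genes must be >= 0")


def make_toy_network(
    n_proteins: int,
    n_complexes: int = 0,
    wiring: str = "chain",
    seed: int = 0,
    module_size: int = 8,
) -> PathwayNetwork:
    """Small valid pathway network with a chosen wiring scheme.

    chain: P1 -> P2 -> ... protein-activations; tree: random-parent
    arborescence; one-loop: chain plus one back edge; hub-modules:
    proteins partitioned into blocks of ``module_size``, each wired as
    a hub activating its spokes; complex-modules: the same blocks with
    consecutive proteins joined pairwise through complexes (receptor-
    complex-style AND-logic assemblies, no regulatory edges — for
    complex-modules ``n_complexes`` is ignored, the chaining fixes it).

    Shallow modules are the regime where a within-patient permutation
    null is informative: deep cascades relay any permuted upstream
    alteration through tie-breaking votes and so sit in a hot null,
    and a lone hub alteration switches a whole star module.  Complex
    chaining requires every component altered, so isolated background
    alterations never assemble a module.  For the other schemes,
    complexes (if any) each take ``component`` edges from two adjacent
    proteins.
    """
    if n_proteins < 0 or n_complexes < 0:
        raise ValueError("counts must be >= 0")
    if wiring not in {"chain", "tree", "one-loop", "hub-modules", "complex-modules"}:
        raise ValueError(f"unknown wiring scheme {wiring!r}")
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(max(n_proteins, 1))))
    pnames = [f"P{i:0{width}d}" for i in range(1, n_proteins + 1)]
    entities = {p: Entity(p, "protein") for p in pnames}
    interactions: list[Interaction] = []

    if wiring == "chain" or wiring == "one-loop":
        for a, b in zip(pnames, pnames[1:]):
            interactions.append(Interaction(a, b, "protein-activate"))
        if wiring == "one-loop" and n_proteins >= 3:
            interactions.append(
                Interaction(pnames[-1], pnames[0], "protein-activate")
            )
    elif wiring == "tree":
        for i, b in enumerate(pnames[1:], start=1):
            a = pnames[int(rng.integers(0, i))]
            interactions.append(Interaction(a, b, "protein-activate"))
    elif wiring == "hub-modules":
        for start in range(0, n_proteins, module_size):
            block = pnames[start : start + module_size]
            for spoke in block[1:]:
                interactions.append(
                    Interaction(block[0], spoke, "protein-activate")
                )
    elif wiring == "complex-modules":
        cpx = 0
        for start in range(0, n_proteins, module_size):
            block = pnames[start : start + module_size]
            pairs = list(zip(block, block[1:]))
            if len(block) >= 3:
                pairs.append((block[-1], block[0]))  # ring: robust to one dropout
            for a, b in pairs:
                cpx += 1
                cname = f"CPX{cpx:03d}"
                entities[cname] = Entity(cname, "complex")
                interactions.append(Interaction(a, cname, "component"))
                interactions.append(Interaction(b, cname, "component"))
        return PathwayNetwork(entities=entities, interactions=interactions)

    for j in range(1, n_complexes + 1):
        cname = f"CPX{j:03d}"
        entities[cname] = Entity(cname, "complex")
        if n_proteins >= 2:
            a = pnames[(2 * (j - 1)) % (n_proteins - 1)]
            b = pnames[(2 * (j - 1)) % (n_proteins - 1) + 1]
            interactions.append(Interaction(a, cname, "component"))
            interactions.append(Interaction(b, cname, "component"))
        elif n_proteins == 1:
            interactions.append(Interaction(pnames[0], cname, "component"))
    return PathwayNetwork(entities=entities, interactions=interactions)


def planted_genes(net: PathwayNetwork, spec: CohortSpec) -> list[str]:
    """The first ``chain_length`` proteins (sorted) carry the alteration."""
    proteins = sorted(net.proteins())
    if spec.chain_length > len(proteins):
        raise ValueError("planted chain longer than the protein set")
    return proteins[: spec.chain_length]


def simulate_cohort(
    net: PathwayNetwork,
    spec: CohortSpec,
    alter_rna: bool = True,
    alter_cna: bool = True,
) -> dict:
    """Simulate (CNA, tumor RNA, normal RNA, truth labels, survival).

    Returns a dict with keys ``cna``, ``rna_tumor``, ``rna_normal``
    (genes x samples DataFrames of focal scores / log-expression),
    ``truth`` (patient, is_carrier), ``survival`` (time, event,
    stratum = carrier/non-carrier) and ``planted`` (gene list).
    ``alter_rna`` / ``alter_cna`` decouple the two omic layers.
    """
    rng = np.random.default_rng(spec.seed)
    network_genes = sorted(net.proteins())
    if not network_genes:
        raise ValueError("network has no protein genes to simulate")
    decoys = [f"DG{i:04d}" for i in range(1, spec.n_decoy_genes + 1)]
    genes = network_genes + decoys
    planted = planted_genes(net, spec)
    if spec.carrier_fraction > 0 and not planted:
        raise ValueError("carriers requested but planted chain empty")
    G = len(genes)
    patients = [f"PT{i:03d}" for i in range(1, spec.n_patients + 1)]
    normals = [f"NM{i:03d}" for i in range(1, spec.n_normals + 1)]

    # per-gene Gaussian reference: log-scale expression baselines
    mu = rng.uniform(4.0, 10.0, size=G)
    sigma = rng.uniform(0.5, 1.5, size=G)

    n_carriers = int(round(spec.carrier_fraction * spec.n_patients))
    carrier_idx = rng.choice(spec.n_patients, size=n_carriers, replace=False)
    is_carrier = np.zeros(spec.n_patients, dtype=bool)
    is_carrier[carrier_idx] = True

    rna_normal = rng.normal(mu[:, None], sigma[:, None], size=(G, spec.n_normals))
    rna_tumor = rng.normal(mu[:, None], sigma[:, None], size=(G, spec.n_patients))
    pmask = np.isin(genes, planted)
    if alter_rna:
        shift = spec.direction * spec.delta * sigma[pmask, None]
        rna_tumor[np.ix_(pmask, is_carrier)] += shift

    cna = np.zeros((G, spec.n_patients))
    bg = rng.random((G, spec.n_patients)) < spec.background_cna_prob
    cna[bg] = rng.choice([-0.1, 0.1], size=int(bg.sum()))
    if alter_cna:
        hit = rng.random((int(pmask.sum()), int(is_carrier.sum()))) < spec.cna_prob
        block = cna[np.ix_(pmask, is_carrier)]
        block[hit] = spec.direction * 0.5
        cna[np.ix_(pmask, is_carrier)] = block

    hazard = np.where(
        is_carrier,
        spec.baseline_hazard * spec.hazard_ratio,
        spec.baseline_hazard,
    )
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, spec.censor_horizon, size=spec.n_patients)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    truth = pd.DataFrame(
        {"patient": patients, "is_carrier": is_carrier}
    ).set_index("patient")
    survival = pd.DataFrame(
        {
            "patient": patients,
            "time": time,
            "event": event,
            "stratum": np.where(is_carrier, "carrier", "non-carrier"),
        }
    ).set_index("patient")
    return {
        "cna": pd.DataFrame(cna, index=genes, columns=patients),
        "rna_tumor": pd.DataFrame(rna_tumor, index=genes, columns=patients),
        "rna_normal": pd.DataFrame(rna_normal, index=genes, columns=normals),
        "truth": truth,
        "survival": survival,
        "planted": planted,
    }


def make_gene_sets(
    net: PathwayNetwork,
    planted: list[str],
    n_sets: int = 20,
    set_size: int = 10,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene-set collection for enrichment tests on a toy network.

    One set covers the planted genes (padded with random proteins up to
    ``set_size``); the rest are random draws from the network proteins.
    """
    rng = np.random.default_rng(seed)
    proteins = sorted(net.proteins())
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    planted_set = set(planted)
    pool = [p for p in proteins if p not in planted_set]
    pad = list(
        rng.choice(pool, size=max(0, min(len(pool), set_size - len(planted))), replace=False)
    )
    sets["SET_PLANTED"] = frozenset(planted_set | set(pad))
    desc["SET_PLANTED"] = "covers the planted alteration chain"
    for j in range(1, n_sets):
        name = f"SET{j:03d}"
        size = min(set_size, len(proteins))
        sets[name] = frozenset(rng.choice(proteins, size=size, replace=False))
        desc[name] = "random background set"
    return GeneSetCollection(sets=sets, descriptions=desc)
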