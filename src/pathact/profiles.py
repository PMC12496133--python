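"""Per-patient gene-set overrepresentation profiles and patient grouping.

For each patient, the altered entities (pathway state != 0, restricted
to proteins) are tested for overrepresentation in every gene set with
a one-sided Fisher exact test against the universe of all protein
entities in the pathway network.  P-values are Benjamini–Hochberg
adjusted across the sets of the collection (per patient), transformed
to -log10 and capped, and the resulting sets x patients matrix is the
patient's pathway-alteration profile.  Patients are grouped by Ward
hierarchical clustering of their profile columns.

The same machinery applies to CNA-state or RNA-state foregrounds, which
is how the single-omic comparison baselines are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .pathway_io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "GroupAssignment",
    "fisher_overrepresentation_p",
    "overrepresentation",
    "overrepresentation_cohort",
    "build_profile_matrix",
    "cluster_patients",
    "select_display_terms",
]


@dataclass
class EnrichmentResult:
    """Per-set raw/adjusted P-values and contingency counts for patients.

    Each frame is gene sets x patients; counts follow the 2x2 table
    (k = altered in set, K = set size in universe, n = altered total,
    N = universe size).
    """

    raw_p: pd.DataFrame
    adj_p: pd.DataFrame
    k: pd.DataFrame
    K: pd.Series
    n: pd.Series
    N: int
    no_overlap: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))


@dataclass
class GroupAssignment:
    """Patient -> group label (1..k) with method metadata."""

    labels: pd.Series
    k: int
    method: str = "ward-euclidean"

    def patients_in(self, group: int) -> list[str]:
        return [str(p) for p, g in self.labels.items() if g == group]


def fisher_overrepresentation_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided (greater) Fisher exact P for a 2x2 overlap table.

    Equals the hypergeometric upper tail P(X >= k) drawing n from a
    universe of N with K marked.
    """
    if not (0 <= k <= min(K, n) or k == 0):
        raise ValueError("inconsistent contingency counts")
    if K > N or n > N:
        raise ValueError("set or foreground larger than the universe")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _patient_pvalues(
    altered: frozenset[str],
    set_members: dict[str, frozenset[str]],
    universe_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(altered)
    raw = np.empty(len(set_members))
    kvec = np.empty(len(set_members), dtype=int)
    for j, (name, members) in enumerate(set_members.items()):
        k = len(altered & members)
        kvec[j] = k
        raw[j] = fisher_overrepresentation_p(k, len(members), n, universe_size)
    return raw, kvec


def overrepresentation(
    states: pd.Series,
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Enrichment for one patient: one row per gene set.

    ``states`` maps entity -> ternary state; the foreground is the
    universe members with nonzero state.  Sets are intersected with the
    universe first; a set with no overlap with the universe scores
    P = 1 and is flagged.  BH adjustment runs across all sets of the
    collection.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    members = {
        name: frozenset(genes & universe) for name, genes in sets.sets.items()
    }
    foreground = frozenset(
        e for e, s in states.items() if e in universe and not pd.isna(s) and s != 0
    )
    N = len(universe)
    rows = []
    for name, mem in members.items():
        k = len(foreground & mem)
        p = (
            1.0
            if not mem
            else fisher_overrepresentation_p(k, len(mem), len(foreground), N)
        )
        rows.append(
            {
                "set": name,
                "raw_p": p,
                "k": k,
                "K": len(mem),
                "n": len(foreground),
                "N": N,
                "no_overlap": not mem,
            }
        )
    df = pd.DataFrame(rows).set_index("set")
    df["adj_p"] = benjamini_hochberg(df["raw_p"].to_numpy())
    return df


def benjamini_hochberg(raw_p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted P-values (delegates to statsmodels)."""
    if len(raw_p) == 0:
        return np.asarray(raw_p)
    return multipletests(raw_p, method="fdr_bh")[1]


def overrepresentation_cohort(
    states: pd.DataFrame,
    sets: GeneSetCollection,
    universe: set[str],
) -> EnrichmentResult:
    """Per-patient one-sided Fisher tests with per-patient BH adjustment."""
    if not universe:
        raise ValueError("universe must be nonempty")
    members = {
        name: frozenset(genes & universe) for name, genes in sets.sets.items()
    }
    names = list(members)
    N = len(universe)
    raw = {}
    adj = {}
    kmat = {}
    nvec = {}
    state_in_universe = states.loc[[e for e in states.index if e in universe]]
    for patient in states.columns:
        col = state_in_universe[patient]
        altered = frozenset(col.index[(col != 0) & col.notna()])
        raw_p, kvec = _patient_pvalues(altered, members, N)
        raw_p = np.where([not members[nm] for nm in names], 1.0, raw_p)
        raw[patient] = raw_p
        adj[patient] = benjamini_hochberg(raw_p)
        kmat[patient] = kvec
        nvec[patient] = len(altered)
    return EnrichmentResult(
        raw_p=pd.DataFrame(raw, index=names),
        adj_p=pd.DataFrame(adj, index=names),
        k=pd.DataFrame(kmat, index=names),
        K=pd.Series({nm: len(m) for nm, m in members.items()}),
        n=pd.Series(nvec),
        N=N,
        no_overlap=pd.Series({nm: not m for nm, m in members.items()}),
    )


def build_profile_matrix(
    result: EnrichmentResult, cap: float = 10.0
) -> pd.DataFrame:
    """Profile entries: min(-log10(adjusted P), cap); P = 1 maps to 0."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    with np.errstate(divide="ignore"):
        prof = -np.log10(result.adj_p)
    return prof.clip(lower=0.0, upper=cap)


def cluster_patients(
    profile: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_resample: int = 0,
    resample_fraction: float = 0.8,
) -> GroupAssignment:
    """Group patients by their profile columns.

    Default: agglomerative Ward clustering on Euclidean distances, cut
    at ``k`` groups — deterministic given the inputs (the seed matters
    only for the optional consensus mode).  With ``n_resample > 0`` a
    consensus-resampling variant is used instead: patients are
    subsampled ``n_resample`` times, co-clustering frequencies are
    accumulated, and the consensus (1 - frequency) distance is
    hierarchically cut at k.
    """
    n_patients = profile.shape[1]
    if not (1 <= k <= n_patients):
        raise ValueError(f"k must be in 1..{n_patients}")
    X = profile.T.to_numpy(dtype=float)  # patients x sets
    patients = [str(c) for c in profile.columns]
    if k == 1:
        labels = np.ones(n_patients, dtype=int)
        method = "trivial"
    elif n_resample <= 0:
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
        method = "ward-euclidean"
    else:
        rng = np.random.default_rng(seed)
        co = np.zeros((n_patients, n_patients))
        cnt = np.zeros((n_patients, n_patients))
        m = max(k, int(round(resample_fraction * n_patients)))
        for _ in range(n_resample):
            idx = np.sort(rng.choice(n_patients, size=m, replace=False))
            Z = linkage(X[idx], method="ward")
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co[np.ix_(idx, idx)] += same
            cnt[np.ix_(idx, idx)] += 1
        with np.errstate(invalid="ignore"):
            freq = np.where(cnt > 0, co / np.maximum(cnt, 1), 0.0)
        dist = 1.0 - freq
        iu = np.triu_indices(n_patients, 1)
        Z = linkage(dist[iu], method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
        method = f"consensus-{n_resample}x{resample_fraction}"
    # relabel groups deterministically by first patient appearance
    remap: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out.append(remap[lab])
    return GroupAssignment(
        labels=pd.Series(out, index=patients, dtype=int), k=k, method=method
    )


def select_display_terms(
    adj_p: pd.DataFrame,
    groups: GroupAssignment,
    q_threshold: float = 0.05,
    frac_threshold: float = 0.9,
) -> dict[int, list[str]]:
    """Sets significant in at least ``frac_threshold`` of a group's patients.

    Lowering the fraction threshold can only enlarge each group's list.
    Empty groups yield empty lists.
    """
    if not (0 < frac_threshold <= 1):
        raise ValueError("frac_threshold must be in (0, 1]")
    out: dict[int, list[str]] = {}
    for g in range(1, groups.k + 1):
        members = groups.patients_in(g)
        if not members:
            out[g] = []
            continue
        sub = adj_p.loc[:, [c for c in adj_p.columns if str(c) in members]]
        frac = (sub < q_threshold).mean(axis=1)
        out[g] = sorted(frac.index[frac >= frac_threshold])
    return out
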