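"""Group-consensus submodules, key proteins, and survival association.

A *submodule* for a patient group is a connected set of pathway
entities (on the network's undirected skeleton) in which every entity
has a nonzero pathway state in **every** patient of the group.  Mixed
signs across patients are allowed for membership; a submodule must have
at least ``min_size`` entities, one of which is a protein with omic
observations.  A *key protein* of a submodule is one whose state is the
same nonzero value across all group patients (consistent direction).

Key proteins feed a simple clinical read-out: patients are stratified
by whether every listed protein has a strictly positive IPL, and the
two overall-survival (or progression-free) curves are compared with a
two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathway_io import PathwayNetwork

__all__ = [
    "Submodule",
    "find_submodules",
    "key_proteins",
    "stratify_by_activation",
    "logrank_test",
    "neighbor_state_table",
]


@dataclass
class Submodule:
    """A connected, consistently-altered entity set for one patient group."""

    entities: frozenset[str]
    group: int | str
    states: pd.DataFrame  # entities x group patients, ternary
    proteins: tuple[str, ...]          # all protein members
    observed_proteins: tuple[str, ...]  # protein members with omic data
    key: tuple[tuple[str, int], ...] = ()  # (protein, direction)

    def __len__(self) -> int:
        return len(self.entities)


def validate_submodule(
    sub: Submodule,
    net: PathwayNetwork,
    min_size: int = 5,
) -> None:
    """Independent re-check of the four defining constraints."""
    import networkx as nx

    if len(sub.entities) < min_size:
        raise ValueError("submodule below minimum size")
    skel = net.skeleton().subgraph(sub.entities)
    if not nx.is_connected(skel):
        raise ValueError("submodule is not connected")
    if not sub.observed_proteins:
        raise ValueError("submodule has no observed protein")
    block = sub.states.loc[sorted(sub.entities)]
    if block.isna().any().any() or (block == 0).any().any():
        raise ValueError("submodule entity with zero/missing state in a patient")


def find_submodules(
    net: PathwayNetwork,
    states: pd.DataFrame,
    group_patients: list[str],
    observed_genes: set[str],
    min_size: int = 5,
    require_constant_sign: bool = False,
) -> list[Submodule]:
    """Connected components of the always-altered entity restriction.

    The skeleton is restricted to entities whose state is nonzero in
    every group patient (with ``require_constant_sign=True``, addition-
    ally the same sign in every patient); components passing the size
    and observed-protein requirements are returned ordered by size
    descending, then by sorted name tuple.
    """
    import networkx as nx

    if not group_patients:
        raise ValueError("empty patient group")
    missing = [p for p in group_patients if p not in states.columns]
    if missing:
        raise ValueError(f"states missing for patients: {missing}")
    block = states.loc[:, group_patients]
    nonzero = (block != 0).all(axis=1) & block.notna().all(axis=1)
    if require_constant_sign:
        nonzero &= block.nunique(axis=1) == 1
    eligible = {e for e in states.index[nonzero] if e in net.entities}

    proteins = set(net.proteins())
    out: list[Submodule] = []
    skel = net.skeleton().subgraph(eligible)
    for comp in nx.connected_components(skel):
        if len(comp) < min_size:
            continue
        comp_proteins = tuple(sorted(comp & proteins))
        observed = tuple(p for p in comp_proteins if p in observed_genes)
        if not observed:
            continue
        sub = Submodule(
            entities=frozenset(comp),
            group="",
            states=block.loc[sorted(comp)],
            proteins=comp_proteins,
            observed_proteins=observed,
        )
        sub.key = tuple(key_proteins(sub))
        out.append(sub)
    out.sort(key=lambda s: (-len(s.entities), tuple(sorted(s.entities))))
    return out


def key_proteins(sub: Submodule) -> list[tuple[str, int]]:
    """Submodule proteins with one constant nonzero state in all patients.

    Returns (protein, direction) pairs, direction +1 or -1.  Proteins
    that flip sign between patients are excluded; non-protein entities
    are never keys.
    """
    out: list[tuple[str, int]] = []
    for p in sub.proteins:
        row = sub.states.loc[p]
        vals = set(row.dropna().astype(int))
        if len(vals) == 1:
            v = vals.pop()
            if v != 0:
                out.append((p, v))
    return out


def stratify_by_activation(
    ipls: pd.DataFrame,
    proteins: list[str],
    patients: list[str] | None = None,
) -> pd.Series:
    """Binary labels: 'activated' iff IPL > 0 for every listed protein.

    Zero or negative IPL for any listed protein puts the patient in
    'other'.  Strict positivity: a zero IPL is not activation.
    """
    if not proteins:
        raise ValueError("empty protein list")
    missing = [p for p in proteins if p not in ipls.index]
    if missing:
        raise ValueError(f"protein(s) missing from the IPL matrix: {missing}")
    cols = [str(c) for c in (patients if patients is not None else ipls.columns)]
    block = ipls.loc[proteins, cols]
    activated = (block > 0).all(axis=0)
    return pd.Series(
        np.where(activated, "activated", "other"), index=cols, name="stratum"
    )


def logrank_test(surv: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail P.

    ``surv`` needs columns ``time`` (>= 0), ``event`` (1 = event, 0 =
    censored) and ``stratum`` with exactly two levels.  With zero events
    the statistic is undefined: (0.0, 1.0) is returned with a warning.
    """
    import warnings

    from lifelines.statistics import logrank_test as _ll_logrank

    for col in ("time", "event", "stratum"):
        if col not in surv.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (surv["time"] < 0).any():
        raise ValueError("negative survival time")
    if not set(surv["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    strata = sorted(surv["stratum"].unique())
    if len(strata) != 2:
        raise ValueError(f"need exactly two strata, got {strata}")
    a = surv[surv["stratum"] == strata[0]]
    b = surv[surv["stratum"] == strata[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a stratum is empty")
    if surv["event"].sum() == 0:
        warnings.warn(
            "no events in either stratum; log-rank undefined, reporting P=1",
            stacklevel=2,
        )
        return 0.0, 1.0
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def neighbor_state_table(
    protein: str,
    net: PathwayNetwork,
    states: pd.DataFrame,
    cna_states: pd.DataFrame | None,
    rna_states: pd.DataFrame | None,
    patients: list[str] | None = None,
) -> pd.DataFrame:
    """Pathway states of a protein and its direct network neighbors.

    Rows: the focal protein, then its neighbors (both directions, any
    relation), each with a ``pathway`` state row; the focal protein and
    any observed neighbor proteins additionally get ``CNA`` / ``RNA``
    state rows.  Columns are patients.  The multi-index rows are
    (entity, layer).
    """
    if protein not in net.entities:
        raise ValueError(f"unknown protein {protein!r}")
    cols = [str(c) for c in (patients if patients is not None else states.columns)]
    entities = [protein] + net.neighbors(protein)
    protein_set = set(net.proteins())
    rows = {}
    for e in entities:
        if e in states.index:
            rows[(e, "pathway")] = states.loc[e, cols]
        else:
            rows[(e, "pathway")] = pd.Series(np.nan, index=cols)
        if e in protein_set:
            for label, omic in (("CNA", cna_states), ("RNA", rna_states)):
                if omic is not None and e in omic.index:
                    rows[(e, label)] = omic.loc[e, cols]
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["entity", "layer"])
    return out


def kaplan_meier_coordinates(surv: pd.DataFrame) -> pd.DataFrame:
    """Step-curve coordinates per stratum (time, survival), for export."""
    from lifelines import KaplanMeierFitter

    frames = []
    for label, grp in surv.groupby("stratum"):
        km = KaplanMeierFitter()
        km.fit(grp["time"], grp["event"], label=str(label))
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "stratum", str(label))
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)
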