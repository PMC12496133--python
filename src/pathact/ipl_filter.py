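"""Null-filtering of inferred pathway levels and pathway-state calls.

A real IPL is kept only when it departs from the patient's permutation
null: it is set to NA when it falls within ``k_mad`` (default 3) median
absolute deviations of the permuted IPLs for that (entity, patient).
The MAD is unscaled (no normal-consistency factor) and the boundary is
inclusive — exactly three MADs away is still filtered.  Among the
entities that survive, only the largest connected component of the
network's undirected skeleton is retained per patient; everything else
is set to a normal (zero) pathway state.  The final ternary pathway
state is the sign of the IPL inside the retained component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathway_io import PathwayNetwork
from .perm_null import patient_of_column

__all__ = [
    "NullSummary",
    "mad_filter",
    "mad_filter_matrix",
    "largest_component",
    "pathway_states",
    "summarize_null",
]

_EQ_TOL = 1e-12  # equality tolerance for the degenerate MAD = 0 case


@dataclass
class NullSummary:
    """Per-(entity, patient) permuted-IPL median, MAD and count."""

    median: pd.DataFrame
    mad: pd.DataFrame
    n_perm: pd.DataFrame


def summarize_null(perm_ipls: pd.DataFrame) -> NullSummary:
    """Median/MAD of permuted IPLs, grouped by the parent patient.

    ``perm_ipls`` columns follow the ``<patient>__perm<k>`` convention.
    """
    patients = [patient_of_column(c) for c in perm_ipls.columns]
    grouped = perm_ipls.T.groupby(pd.Series(patients, index=perm_ipls.columns))
    median = grouped.median().T
    mad = (
        perm_ipls.sub(median.loc[:, patients].set_axis(perm_ipls.columns, axis=1))
        .abs()
        .T.groupby(pd.Series(patients, index=perm_ipls.columns))
        .median()
        .T
    )
    n_perm = grouped.count().T
    return NullSummary(median=median, mad=mad, n_perm=n_perm)


def mad_filter(real: float, perms, k_mad: float = 3.0) -> float:
    """One (entity, patient) filter decision: NA inside the null band.

    Returns NaN iff |real - median(perms)| <= k_mad * MAD(perms)
    (inclusive, unscaled MAD), else passes the real value through.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    perms = np.asarray(perms, dtype=float)
    perms = perms[~np.isnan(perms)]
    if perms.size == 0:
        raise ValueError("mad_filter needs at least one permuted value")
    m = float(np.median(perms))
    mad = float(np.median(np.abs(perms - m)))
    if abs(real - m) <= k_mad * mad + _EQ_TOL:
        return float("nan")
    return float(real)


def mad_filter_matrix(
    real_ipls: pd.DataFrame,
    perm_ipls: pd.DataFrame,
    k_mad: float = 3.0,
) -> tuple[pd.DataFrame, NullSummary]:
    """Vectorized null filter over an entities x patients IPL matrix.

    Permuted columns must be ``<patient>__perm<k>`` for the patients in
    ``real_ipls``.  Entities with no permuted values stay unfiltered
    only if absent from the permuted matrix entirely (then NaN).
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    null = summarize_null(perm_ipls.reindex(real_ipls.index))
    med = null.median.reindex(columns=real_ipls.columns)
    mad = null.mad.reindex(columns=real_ipls.columns)
    dev = (real_ipls - med).abs()
    inside = dev.le(k_mad * mad + _EQ_TOL)
    filtered = real_ipls.where(~inside)
    filtered = filtered.where(~med.isna(), np.nan)  # no null -> no call
    return filtered, null


def largest_component(
    net: PathwayNetwork, kept_entities: set[str]
) -> frozenset[str]:
    """Maximum-cardinality connected component among the kept entities.

    Connectivity is on the undirected skeleton (all interaction types).
    Ties break to the component whose sorted name tuple is smallest.
    An empty kept set yields an empty retained set.
    """
    unknown = set(kept_entities) - set(net.entities)
    if unknown:
        raise ValueError(f"kept entities not in the network: {sorted(unknown)}")
    if not kept_entities:
        return frozenset()
    import networkx as nx

    sub = net.skeleton().subgraph(kept_entities)
    best: tuple[int, tuple[str, ...]] | None = None
    for comp in nx.connected_components(sub):
        key = (-len(comp), tuple(sorted(comp)))
        if best is None or key < best:
            best = key
    return frozenset(best[1])


def pathway_states(
    filtered_ipls: pd.DataFrame, net: PathwayNetwork
) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """Ternary pathway states after component retention.

    Per patient: entities outside the largest connected non-NA component
    (and NA-filtered entities) are set to 0; inside it, the state is the
    sign of the IPL.  Returns the state matrix and the retained
    component per patient (empty set flags a patient with nothing kept).
    """
    states = pd.DataFrame(
        0.0, index=filtered_ipls.index, columns=filtered_ipls.columns
    )
    retained: dict[str, frozenset[str]] = {}
    network_entities = set(net.entities)
    for patient in filtered_ipls.columns:
        col = filtered_ipls[patient]
        kept = set(col.dropna().index) & network_entities
        comp = largest_component(net, kept)
        retained[str(patient)] = comp
        if comp:
            members = [e for e in filtered_ipls.index if e in comp]
            states.loc[members, patient] = np.sign(col.loc[members])
    return states, retained
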