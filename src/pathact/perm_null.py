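"""Within-patient permutations of paired omic states.

The null model asks: what pathway activity would we infer if each
patient's (CNA, RNA) state pairs were assigned to genes at random?
Pairs are shuffled *between genes within one patient*, never split, so
every permuted sample preserves the patient's exact multiset of state
pairs — only the gene labels move.  Running inference on the permuted
samples yields a per-entity, per-patient background IPL distribution.

Seeds derive deterministically from (seed, patient, permutation index)
via ``numpy.random.SeedSequence``, so permuted samples can be generated
in any order or in parallel with identical results.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PermutationPlan",
    "permute_patient_states",
    "generate_permutations",
]


@dataclass(frozen=True)
class PermutationPlan:
    """How many permuted samples per patient, and the master seed."""

    n_perm: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")

    def derived_seed(self, patient: str, index: int) -> np.random.SeedSequence:
        """Reproducible per-(patient, index) seed, order-independent."""
        patient_key = zlib.crc32(str(patient).encode("utf-8"))
        return np.random.SeedSequence([self.seed, patient_key, index])


def permute_patient_states(
    cna_col: pd.Series,
    rna_col: pd.Series,
    seed: int | np.random.SeedSequence,
) -> tuple[pd.Series, pd.Series]:
    """Shuffle one patient's (CNA, RNA) pairs uniformly between genes.

    Genes missing both states are left in place (they carry no
    information); all other genes — including those missing one of the
    two states, whose missingness travels with the pair — take part in
    a single uniform permutation.
    """
    if not cna_col.index.equals(rna_col.index):
        raise ValueError("CNA and RNA columns must share the same gene axis")
    rng = np.random.default_rng(seed)
    cna = cna_col.to_numpy(dtype=float).copy()
    rna = rna_col.to_numpy(dtype=float).copy()
    informative = ~(np.isnan(cna) & np.isnan(rna))
    idx = np.flatnonzero(informative)
    perm = rng.permutation(len(idx))
    cna[idx] = cna[idx][perm]
    rna[idx] = rna[idx][perm]
    return (
        pd.Series(cna, index=cna_col.index, name=cna_col.name),
        pd.Series(rna, index=rna_col.index, name=rna_col.name),
    )


def generate_permutations(
    cna_states: pd.DataFrame,
    rna_states: pd.DataFrame,
    plan: PermutationPlan,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permuted cohort: n_patients x n_perm pseudo-samples.

    Output columns are named ``<patient>__perm<k>`` with k in
    0..n_perm-1; each is an independent within-patient pair shuffle.
    The result is a pure function of (states, plan.seed).
    """
    if not cna_states.index.equals(rna_states.index):
        raise ValueError("CNA and RNA matrices must share the same gene axis")
    if list(cna_states.columns) != list(rna_states.columns):
        raise ValueError("CNA and RNA matrices must share the same patients")
    cna_cols: dict[str, pd.Series] = {}
    rna_cols: dict[str, pd.Series] = {}
    for patient in cna_states.columns:
        for k in range(plan.n_perm):
            tag = f"{patient}__perm{k}"
            pc, pr = permute_patient_states(
                cna_states[patient],
                rna_states[patient],
                plan.derived_seed(str(patient), k),
            )
            cna_cols[tag] = pc
            rna_cols[tag] = pr
    if not cna_cols:
        empty = pd.DataFrame(index=cna_states.index)
        return empty, empty.copy()
    return (
        pd.DataFrame(cna_cols, index=cna_states.index),
        pd.DataFrame(rna_cols, index=rna_states.index),
    )


def patient_of_column(column: str) -> str:
    """Patient id from a permuted-sample column name."""
    return column.rsplit("__perm", 1)[0]
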