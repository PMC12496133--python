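"""Ternary omic states from copy-number and RNA-seq matrices.

Copy-number alteration (CNA) focal scores discretize by sign: positive
scores are activated (+1), exactly zero is normal (0), negative is
repressed (-1).  RNA expression (log scale, e.g. log10(FPKM+1)) is
compared against a per-gene Gaussian reference fit to normal-tissue
samples: a tumor value more than ``k_sd`` standard deviations from the
normal mean is called activated/repressed, otherwise normal.  The
default ``k_sd = 2`` corresponds to a two-sided Gaussian tail mass of
about 0.0455, i.e. the conventional P < .05 significance level.

Matrices are pandas DataFrames, genes as rows and samples as columns;
missing entries are NaN.  Ternary state matrices use float dtype so NaN
can encode missingness alongside {-1, 0, +1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RnaReference",
    "cna_state",
    "fit_rna_reference",
    "rna_state",
    "read_matrix",
    "write_matrix",
]

TERNARY_VALUES = (-1.0, 0.0, 1.0)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene symbol, header row).

    Empty cells and ``NA`` are missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    return df.astype(float)

def write_matrix(df: pd.DataFrame, path: str | Path, label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=label, na_rep="NA")


def _check_numeric(values: pd.DataFrame, what: str) -> None:
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        raise TypeError(f"{what} matrix must be numeric")
    if not values.index.is_unique or not values.columns.is_unique:
        raise ValueError(f"{what} matrix has duplicate gene or sample labels")


def cna_state(cna: pd.DataFrame) -> pd.DataFrame:
    """Ternary CNA state: sign of the focal score; missing stays missing.

    Odd function of the input: ``cna_state(-M) == -cna_state(M)``.
    """
    _check_numeric(cna, "CNA")
    return pd.DataFrame(
        np.sign(cna.to_numpy(dtype=float)), index=cna.index, columns=cna.columns
    )


@dataclass
class RnaReference:
    """Per-gene Gaussian reference fit to normal-tissue expression.

    ``usable`` is False for genes with fewer than two non-missing normal
    samples; ``degenerate`` flags usable genes with zero variance, which
    cannot support the tail test and yield missing states.
    """

    mean: pd.Series
    sd: pd.Series
    n_normal: pd.Series
    usable: pd.Series
    degenerate: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.mean.index


def fit_rna_reference(normal_expr: pd.DataFrame) -> RnaReference:
    """Per-gene sample mean and SD (denominator n-1) over normal samples.

    Genes with <2 non-missing normals are flagged unusable rather than
    raising; all-missing genes likewise.
    """
    _check_numeric(normal_expr, "normal RNA")
    vals = normal_expr.to_numpy(dtype=float)
    n = np.sum(~np.isnan(vals), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    usable = n >= 2
    mean = np.where(usable, mean, np.nan)
    sd = np.where(usable, sd, np.nan)
    degenerate = usable & (sd == 0)
    idx = normal_expr.index
    return RnaReference(
        mean=pd.Series(mean, index=idx),
        sd=pd.Series(sd, index=idx),
        n_normal=pd.Series(n, index=idx),
        usable=pd.Series(usable, index=idx),
        degenerate=pd.Series(degenerate, index=idx),
    )


def rna_state(
    tumor_expr: pd.DataFrame, ref: RnaReference, k_sd: float = 2.0
) -> pd.DataFrame:
    """Ternary RNA state against the normal-tissue Gaussian reference.

    +1 if x > mean + k_sd*sd, -1 if x < mean - k_sd*sd, else 0 (values
    exactly on a boundary are normal).  Genes absent from the reference,
    unusable or degenerate (sd == 0) get missing states.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    _check_numeric(tumor_expr, "tumor RNA")

    missing_genes = tumor_expr.index.difference(ref.genes)
    if len(missing_genes):
        warnings.warn(
            f"{len(missing_genes)} tumor gene(s) absent from the RNA "
            "reference; their states are missing",
            stacklevel=2,
        )
    mean = ref.mean.reindex(tumor_expr.index).to_numpy()[:, None]
    sd = ref.sd.reindex(tumor_expr.index).to_numpy()[:, None]
    ok = (
        ref.usable.reindex(tumor_expr.index, fill_value=False)
        & ~ref.degenerate.reindex(tumor_expr.index, fill_value=False)
    ).to_numpy()[:, None]

    x = tumor_expr.to_numpy(dtype=float)
    hi = mean + k_sd * sd
    lo = mean - k_sd * sd
    state = np.where(x > hi, 1.0, np.where(x < lo, -1.0, 0.0))
    state = np.where(np.isnan(x) | ~ok, np.nan, state)
    return pd.DataFrame(state, index=tumor_expr.index, columns=tumor_expr.columns)
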