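"""Core in-memory containers.

The package works on three kinds of objects:

* :class:`CommunityTable` — a samples × taxa abundance matrix (counts or
  relative abundances) wrapping a :class:`pandas.DataFrame` whose index is
  the sample IDs and whose columns are the taxon (ASV) IDs.
* sample metadata — a plain :class:`pandas.DataFrame` indexed by sample ID
  (see :mod:`ecoassembly.io` for the validated reader).
* distance matrices — square symmetric :class:`pandas.DataFrame` objects
  with zero diagonal, identical index and columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class CommunityTable:
    """Samples × taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample IDs as index, taxon IDs as columns, and
        nonnegative numeric abundances.
    standardized:
        Whether rows have already been standardized (relative abundance or
        rarefied); raw read counts carry ``False``.
    provenance:
        Free-form notes on how the table was produced (standardization
        mode, seed, ...), carried through the pipeline for audit.
    """

    data: pd.DataFrame
    standardized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon IDs: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("community table must be numeric")
        if np.isnan(values).any():
            raise ValidationError("community table contains missing values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        rowsums = values.sum(axis=1)
        if (rowsums == 0).any():
            bad = df.index[rowsums == 0].tolist()
            raise ValidationError(f"all-zero sample rows: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def counts_are_integer(self) -> bool:
        values = self.data.to_numpy()
        return bool(np.all(np.mod(values, 1) == 0))


def check_distance_matrix(dm: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Validate a square symmetric zero-diagonal distance matrix.

    Returns the matrix unchanged; raises :class:`ValidationError` otherwise.
    """
    if dm.shape[0] != dm.shape[1] or not dm.index.equals(dm.columns):
        raise ValidationError("distance matrix must be square with matching index/columns")
    values = dm.to_numpy(dtype=float)
    if np.abs(values - values.T).max(initial=0.0) > tol:
        raise ValidationError(f"distance matrix asymmetric beyond tolerance {tol}")
    if np.abs(np.diag(values)).max(initial=0.0) > tol:
        raise ValidationError("distance matrix diagonal not zero")
    if values.min(initial=0.0) < -tol:
        raise ValidationError("distance matrix has negative entries")
    return dm


def upper_triangle(dm: pd.DataFrame) -> np.ndarray:
    """Strict upper-triangle entries of a square matrix, row-major order."""
    values = dm.to_numpy(dtype=float)
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]
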