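"""Table standardization, alpha diversity, Bray-Curtis, Hellinger, PCoA.

Conventions stated once, used everywhere: Shannon entropy is reported in
natural log units (nats); Faith's phylogenetic diversity includes the
path to the root by default; principal-coordinates analysis reports
negative eigenvalues rather than correcting them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._rng import rng_stream
from .containers import CommunityTable, check_distance_matrix
from .errors import ConsistencyError, ValidationError
from .trees import faith_pd as _faith_pd
from .trees import tip_labels


def standardize_table(
    table: CommunityTable,
    mode: str = "relative",
    depth: int | None = None,
    seed: int = 0,
) -> CommunityTable:
    """Standardize a counts table.

    ``relative`` divides each row by its sum.  ``rarefy`` subsamples each
    row without replacement (multivariate hypergeometric) to ``depth``
    reads, defaulting to the minimum row sum; it requires integer counts
    and errors if ``depth`` exceeds any row sum.
    """
    df = table.data
    values = df.to_numpy(dtype=float)
    if mode == "relative":
        out = values / values.sum(axis=1, keepdims=True)
    elif mode == "rarefy":
        if not table.counts_are_integer():
            raise ValidationError("rarefaction requires integer counts")
        counts = df.to_numpy(dtype=np.int64)
        rowsums = counts.sum(axis=1)
        if depth is None:
            depth = int(rowsums.min())
        if depth < 1:
            raise ValidationError("rarefaction depth must be >= 1")
        shallow = df.index[rowsums < depth].tolist()
        if shallow:
            raise ValidationError(
                f"rarefaction depth {depth} exceeds row sums of samples: {shallow}")
        rng = rng_stream(seed)
        out = np.empty_like(counts)
        for i in range(counts.shape[0]):
            out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    else:
        raise ValidationError(f"unknown standardization mode {mode!r}")
    prov = dict(table.provenance, standardization=mode,
                **({"rarefaction_depth": depth, "seed": seed} if mode == "rarefy" else {}))
    return CommunityTable(data=pd.DataFrame(out, index=df.index, columns=df.columns),
                          standardized=True, provenance=prov)


def hellinger_transform(table: CommunityTable) -> CommunityTable:
    """Square root of row-relative abundances; each row gets unit 2-norm."""
    values = table.data.to_numpy(dtype=float)
    rowsums = values.sum(axis=1, keepdims=True)
    if (rowsums == 0).any():
        bad = table.data.index[(rowsums == 0).ravel()].tolist()
        raise ValidationError(f"all-zero rows cannot be Hellinger-transformed: {bad}")
    out = np.sqrt(values / rowsums)
    return CommunityTable(
        data=pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        standardized=True,
        provenance=dict(table.provenance, transform="hellinger"))


def alpha_diversity(table: CommunityTable, tree=None,
                    include_root_path: bool = True) -> pd.DataFrame:
    """Per-sample richness, Shannon index (nats), and optionally Faith PD.

    Richness counts nonzero entries; Shannon is −Σ p ln p over the row's
    relative abundances; Faith PD (branch-length units) is the minimal
    spanning subtree of the present taxa, anchored at the root unless
    ``include_root_path`` is off.
    """
    df = table.data
    values = df.to_numpy(dtype=float)
    rowsums = values.sum(axis=1, keepdims=True)
    if (rowsums == 0).any():
        raise ValidationError("all-zero sample rows have undefined diversity")
    p = values / rowsums
    richness = (values > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    out = pd.DataFrame({"richness": richness, "shannon": shannon}, index=df.index)
    if tree is not None:
        tips = set(tip_labels(tree))
        missing = set(df.columns) - tips
        if missing:
            raise ConsistencyError(
                f"taxa missing from tree (align inputs first): {sorted(missing)[:5]}")
        out["faith_pd"] = [
            _faith_pd(tree, set(df.columns[values[i] > 0]), include_root_path)
            for i in range(values.shape[0])
        ]
    return out


def bray_curtis_matrix(table: CommunityTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = Σ|x−y| / Σ(x+y)."""
    values = table.data.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        raise ValidationError("all-zero rows have undefined Bray-Curtis distance")
    dm = squareform(pdist(values, metric="braycurtis"))
    ids = table.data.index
    return pd.DataFrame(dm, index=ids, columns=ids)


@dataclass
class PcoaResult:
    """Principal-coordinates (classical MDS) decomposition.

    ``coordinates`` holds one column per retained positive-eigenvalue
    axis, already scaled by sqrt(eigenvalue).  ``proportion_explained`` is
    each positive eigenvalue over the sum of positive eigenvalues.
    Negative eigenvalues (non-Euclidean input) are counted and reported,
    not corrected.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int


def pcoa(dist: pd.DataFrame, n_axes: int | None = None) -> PcoaResult:
    """PCoA via Gower double-centering of −½ D²."""
    check_distance_matrix(dist)
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    if n_axes is None:
        n_axes = n - 1
    if n_axes < 1:
        raise ValidationError("n_axes must be >= 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, abs(eigvals[0]))
    n_negative = int((eigvals < -tol).sum())
    positive = eigvals > tol
    k = min(n_axes, int(positive.sum()))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    coordinates = pd.DataFrame(
        coords, index=dist.index, columns=[f"PCo{i + 1}" for i in range(k)])
    return PcoaResult(coordinates=coordinates, eigenvalues=eigvals,
                      proportion_explained=proportion, n_negative_eigenvalues=n_negative)
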