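"""Geographic and environmental distances, distance-decay, Mantel tests."""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from ._rng import rng_stream
from .containers import check_distance_matrix, upper_triangle
from .errors import ConsistencyError, ValidationError

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two points in decimal degrees."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def haversine_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances (km) between samples' lat/lon."""
    for col in ("lat", "lon"):
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks column {col!r}")
    missing = meta.index[meta[["lat", "lon"]].isna().any(axis=1)].tolist()
    if missing:
        raise ValidationError(f"samples missing coordinates: {missing}")
    lat = np.radians(meta["lat"].to_numpy(dtype=float))
    lon = np.radians(meta["lon"].to_numpy(dtype=float))
    dp = lat[:, None] - lat[None, :]
    dl = lon[:, None] - lon[None, :]
    a = np.sin(dp / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dl / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=meta.index, columns=meta.index)


def environmental_distance(meta: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Euclidean distance over z-scored environmental variables.

    Each variable is centred and scaled by its sample (n−1) standard
    deviation across the retained samples, so the matrix is invariant to
    per-variable rescaling.  Samples with a missing value in any chosen
    variable are excluded (logged).
    """
    if not variables:
        raise ValidationError("at least one environmental variable is required")
    for v in variables:
        if v not in meta.columns:
            raise ValidationError(f"metadata lacks variable {v!r}")
    sub = meta[list(variables)].apply(pd.to_numeric)
    keep = sub.dropna()
    dropped = sorted(set(sub.index) - set(keep.index))
    if dropped:
        log.info("environmental_distance: excluding %d sample(s) with missing "
                 "values: %s", len(dropped), dropped)
    if keep.shape[0] < 2:
        raise ValidationError("fewer than 2 samples with complete environmental data")
    sd = keep.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValidationError(f"zero-variance environmental variable(s): {flat}")
    z = (keep - keep.mean()) / sd
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=keep.index, columns=keep.index)


@dataclass
class RegressionResult:
    """OLS fit of community similarity (or distance) on pairwise distance.

    The units of observation are sample *pairs* (the strict upper
    triangle), which are not independent — p-values are optimistic, as in
    any distance-decay regression; pair with a Mantel test for inference.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    response: str = "similarity"


def distance_decay(comm_dist: pd.DataFrame, geo_dist: pd.DataFrame,
                   response: str = "similarity") -> RegressionResult:
    """Distance-decay OLS of 1 − dissimilarity (default) on distance."""
    check_distance_matrix(comm_dist)
    if set(comm_dist.index) != set(geo_dist.index):
        raise ConsistencyError("community and geographic matrices have different samples")
    geo = geo_dist.loc[comm_dist.index, comm_dist.index]
    check_distance_matrix(geo)
    if comm_dist.shape[0] < 4:
        raise ValidationError("distance-decay needs at least 4 samples")
    x = upper_triangle(geo)
    y = upper_triangle(comm_dist)
    if response == "similarity":
        y = 1.0 - y
    elif response != "distance":
        raise ValidationError("response must be 'similarity' or 'distance'")
    if np.ptp(x) == 0:
        raise ValidationError("all pairwise distances identical: regression undefined")
    if np.ptp(y) == 0:
        # constant response: flat fit, no explained variance
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                p_value=1.0, n=len(x), response=response)
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue),
                            n=len(x), response=response)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    tail: str
    n_samples: int


def mantel_test(d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 999,
                seed: int = 0, tail: str = "upper",
                exhaustive: bool = False) -> MantelResult:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the strict upper triangles; the
    null jointly permutes rows and columns of ``d2``.  The default upper
    tail tests for positive association with the +1-corrected p-value
    ``(#(r_perm ≥ r_obs) + 1)/(n_perm + 1)``; ``exhaustive=True``
    enumerates all relabelings instead (p = exact fraction, identity
    included).
    """
    check_distance_matrix(d1)
    if set(d1.index) != set(d2.index):
        raise ConsistencyError("matrices have different sample sets")
    d2 = d2.loc[d1.index, d1.index]
    check_distance_matrix(d2)
    if not exhaustive and n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if tail not in ("upper", "two-sided"):
        raise ValidationError("tail must be 'upper' or 'two-sided'")
    x = upper_triangle(d1)
    y2 = d2.to_numpy(dtype=float)
    y = upper_triangle(d2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant distance triangle: Mantel r undefined")
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(vec):
        return float(np.corrcoef(x, vec)[0, 1])

    r_obs = corr(y)

    def extreme(r_p):
        if tail == "upper":
            return r_p >= r_obs - 1e-12
        return abs(r_p) >= abs(r_obs) - 1e-12

    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            r_p = corr(y2[np.ix_(idx, idx)][iu])
            count += extreme(r_p)
            total += 1
        p = count / total
        n_used = total - 1
    else:
        rng = rng_stream(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            r_p = corr(y2[np.ix_(idx, idx)][iu])
            count += extreme(r_p)
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_used,
                        tail=tail, n_samples=n)
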