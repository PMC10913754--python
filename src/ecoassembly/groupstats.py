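"""Group-comparison statistics, diel variability, and trophic summaries.

PERMANOVA is single-factor by design: multi-factor designs over
non-orthogonal oceanographic factors (station, depth, irradiance zone)
are analysed one factor at a time, which must be kept in mind when
comparing their R² values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sympy.utilities.iterables import multiset_permutations

from ._rng import rng_stream
from .containers import CommunityTable, check_distance_matrix
from .errors import ValidationError

log = logging.getLogger(__name__)

TROPHIC_GROUPS = ("autotroph", "mixotroph", "parasite", "osmotroph",
                  "phagotroph", "heterotroph", "unknown")


@dataclass
class PermanovaResult:
    term: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int
    df_among: int
    df_within: int


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Among/within sums of squares from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    return ss_total, ss_within


def permanova(dist: pd.DataFrame, grouping, n_perm: int = 999, seed: int = 0,
              term: str = "group", exhaustive: bool = False) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    pseudo-F = (SS_among/df_among) / (SS_within/df_within) from the
    distance-based decomposition SS_total = Σ d²/n; the p-value permutes
    group labels with the +1 correction, or enumerates every distinct
    labelling when ``exhaustive`` is set (p = exact fraction, observed
    labelling included).
    """
    check_distance_matrix(dist)
    labels = pd.Series(grouping).reindex(dist.index) if not isinstance(grouping, pd.Series) \
        else grouping.reindex(dist.index)
    if labels.isna().any():
        raise ValidationError(
            f"grouping missing for samples: {labels.index[labels.isna()].tolist()}")
    cats, codes = np.unique(labels.to_numpy(), return_inverse=True)
    a = len(cats)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = cats[sizes < 2].tolist()
        raise ValidationError(f"groups with fewer than 2 samples: {small}")
    n = dist.shape[0]
    d2 = dist.to_numpy(dtype=float) ** 2
    df_among, df_within = a - 1, n - a

    def pseudo_f(code_vec):
        ss_total, ss_within = _permanova_ss(d2, code_vec, a)
        ss_among = ss_total - ss_within
        return (ss_among / df_among) / (ss_within / df_within), ss_among, ss_total

    f_obs, ss_among, ss_total = pseudo_f(codes)
    r2 = ss_among / ss_total

    if exhaustive:
        count = total = 0
        for perm in multiset_permutations(list(codes)):
            f_p, _, _ = pseudo_f(np.asarray(perm))
            count += f_p >= f_obs - 1e-12
            total += 1
        p = count / total
        n_used = total - 1
    else:
        rng = rng_stream(seed)
        count = 0
        for _ in range(n_perm):
            f_p, _, _ = pseudo_f(rng.permutation(codes))
            count += f_p >= f_obs - 1e-12
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
    return PermanovaResult(term=term, pseudo_f=float(f_obs), r_squared=float(r2),
                           p_value=float(p), n_permutations=n_used, n_samples=n,
                           df_among=df_among, df_within=df_within)


@dataclass
class GroupComparisonResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    group_means: dict
    test: str
    tukey: pd.DataFrame | None = field(default=None, repr=False)


def welch_t_test(x, y) -> GroupComparisonResult:
    """Welch two-sample t-test (unequal variances, Welch–Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValidationError("both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparisonResult(
        statistic=float(res.statistic), degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        group_means={"x": float(x.mean()), "y": float(y.mean())}, test="welch_t")


def anova_tukey(values, grouping, alpha: float = 0.05) -> GroupComparisonResult:
    """One-way ANOVA followed by Tukey–Kramer pairwise comparisons.

    The Tukey table reports, per pair, the mean difference and the
    studentized-range adjusted p-value (pooled within-group variance).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(grouping)
    if len(values) != len(labels):
        raise ValidationError("values and grouping differ in length")
    cats = pd.unique(labels)
    groups = [values[labels == c] for c in cats]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        empty = [str(c) for c, g in zip(cats, groups) if len(g) < 2]
        raise ValidationError(f"groups with fewer than 2 observations: {empty}")
    f_stat, p = stats.f_oneway(*groups)
    hsd = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            rows.append(dict(group_a=str(cats[i]), group_b=str(cats[j]),
                             mean_difference=float(groups[i].mean() - groups[j].mean()),
                             p_adjusted=float(hsd.pvalue[i, j]),
                             significant=bool(hsd.pvalue[i, j] < alpha)))
    means = {str(c): float(g.mean()) for c, g in zip(cats, groups)}
    return GroupComparisonResult(
        statistic=float(f_stat), degrees_of_freedom=float(len(cats) - 1),
        p_value=float(p), group_means=means, test="anova",
        tukey=pd.DataFrame(rows))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("Pearson correlation needs matched n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def diel_cv(table: CommunityTable, meta: pd.DataFrame,
            unit_mapping: dict | pd.Series) -> pd.DataFrame:
    """Coefficient of variation of unit relative abundance across time points.

    Samples are grouped by ``depth_m``; within each depth the relative
    abundance of each unit (taxonomic order or trophic group, via
    ``unit_mapping``: taxon → unit) is tracked across ``time_point``
    values, and CV = sample sd / mean is reported.  Depths with a single
    time point are excluded with a warning; units absent at a depth at
    all times are NaN (undefined), never 0.
    """
    if "time_point" not in meta.columns:
        raise ValidationError("metadata lacks 'time_point'")
    grouped = group_relative_abundance(_as_relative(table), unit_mapping)
    meta = meta.loc[grouped.data.index]
    records = {}
    for depth, sub in meta.groupby("depth_m"):
        tp = sub["time_point"].nunique()
        if tp < 2:
            warnings.warn(f"depth {depth} has a single time point; excluded",
                          stacklevel=2)
            continue
        # average replicate samples within a time point first
        by_time = grouped.data.loc[sub.index].groupby(sub["time_point"]).mean()
        mean = by_time.mean(axis=0)
        sd = by_time.std(axis=0, ddof=1)
        cv = sd / mean
        cv[mean == 0] = np.nan
        records[depth] = cv
    if not records:
        raise ValidationError("no depth has >= 2 time points")
    out = pd.DataFrame(records).T
    out.index.name = "depth_m"
    return out


def _as_relative(table: CommunityTable) -> CommunityTable:
    if table.standardized:
        return table
    values = table.data.to_numpy(dtype=float)
    rel = values / values.sum(axis=1, keepdims=True)
    return CommunityTable(pd.DataFrame(rel, index=table.data.index,
                                       columns=table.data.columns),
                          standardized=True, provenance=dict(table.provenance))


def assign_trophic_groups(taxonomy: dict, lookup: dict) -> dict:
    """Map each taxon to a trophic group via its taxonomy ranks.

    ``taxonomy`` maps taxon ID → ordered rank-name list (shallow to
    deep); the deepest rank with a lookup entry wins; taxa with no match
    (or an empty rank list) get ``"unknown"``.  Total function: never
    raises on unmatched input.
    """
    if not lookup:
        raise ValidationError("functional lookup is empty")
    out = {}
    for taxon, ranks in taxonomy.items():
        group = "unknown"
        for rank in reversed(list(ranks)):
            if rank in lookup:
                group = lookup[rank]
                break
        out[taxon] = group
    return out


def group_relative_abundance(table: CommunityTable, mapping) -> CommunityTable:
    """Sum a standardized table's columns by group (samples × groups).

    Taxa absent from the mapping are assigned ``"unknown"`` and logged.
    Row totals are conserved exactly.
    """
    if not table.standardized:
        raise ValidationError("group_relative_abundance expects a standardized table")
    mapping = dict(mapping) if not isinstance(mapping, dict) else mapping
    unmapped = [t for t in table.data.columns if t not in mapping]
    if unmapped:
        log.info("group_relative_abundance: %d unmapped taxa -> 'unknown': %s",
                 len(unmapped), unmapped[:10])
    groups = [mapping.get(t, "unknown") for t in table.data.columns]
    summed = table.data.T.groupby(pd.Index(groups, name="group")).sum().T
    summed = summed.reindex(sorted(summed.columns), axis=1)
    return CommunityTable(data=summed, standardized=True,
                          provenance=dict(table.provenance, grouped=True))
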