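"""Phylogenetic and taxonomic null models of community assembly.

The inference chain quantifies, for every pair of communities, how far
their observed phylogenetic turnover (βMNTD) and compositional turnover
(Bray-Curtis) deviate from expectation under ecological null models, and
maps the deviations onto assembly processes:

1. ``pairwise_bmntd`` — abundance-weighted β mean-nearest-taxon distance,
   βMNTD(k, m) = ½ Σ_{i∈k} f_ik · min_{j∈m} d_ij
               + ½ Σ_{j∈m} f_jm · min_{i∈k} d_ij,
   with d the patristic distance and f relative abundances.
2. ``bnti_matrix`` — βNTI, the z-score of observed βMNTD against a null
   that shuffles taxon identities across *all* tips of the tree (the
   regional pool), breaking phylogenetic niche signal while preserving
   composition and tree shape.
3. ``rc_bray_matrix`` — abundance-based Raup-Crick: the observed
   Bray-Curtis of each pair is ranked within a null that reassembles both
   communities preserving their richness and read totals, drawing species
   occurrences ∝ regional occupancy and reads ∝ regional relative
   abundance; RC = 2 · (P(null < obs) + ½ P(null = obs) − ½) ∈ [−1, 1].
4. ``classify_assembly`` — |βNTI| > 2 ⇒ selection (sign gives variable
   vs homogeneous); otherwise RC > +0.95 ⇒ dispersal limitation,
   RC < −0.95 ⇒ homogenizing dispersal, else undominated.  All
   inequalities strict: boundary values fall through to the stochastic /
   undominated side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CommunityTable, upper_triangle
from .errors import ConsistencyError, ValidationError
from .trees import cophenetic_matrix, tip_labels

log = logging.getLogger(__name__)

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class BetaMntdMatrix:
    values: pd.DataFrame
    abundance_weighted: bool


@dataclass
class BetaNtiMatrix:
    values: pd.DataFrame          # NaN where the null sd was zero
    bmntd_observed: pd.DataFrame
    n_null: int
    seed: int
    abundance_weighted: bool = True


@dataclass
class RcMatrix:
    values: pd.DataFrame
    n_null: int
    seed: int


def _weights(values: np.ndarray, abundance_weighted: bool) -> np.ndarray:
    rowsums = values.sum(axis=1, keepdims=True)
    if (rowsums == 0).any():
        raise ValidationError("samples with zero total abundance")
    if abundance_weighted:
        return values / rowsums
    presence = (values > 0).astype(float)
    return presence / presence.sum(axis=1, keepdims=True)


def _bmntd_all_pairs(weights: np.ndarray, supports: list[np.ndarray],
                     dist: np.ndarray) -> np.ndarray:
    """βMNTD for all sample pairs at once.

    ``dmin[m, i]`` is taxon i's distance to its nearest relative in
    sample m; the double sum then collapses to a matrix product.
    """
    n = weights.shape[0]
    dmin = np.empty((n, dist.shape[0]))
    for m in range(n):
        dmin[m] = dist[:, supports[m]].min(axis=1)
    t = weights @ dmin.T          # t[k, m] = Σ_i f_ik · dmin_m[i]
    return 0.5 * (t + t.T)


def pairwise_bmntd(table: CommunityTable, tree=None, dist: pd.DataFrame | None = None,
                   abundance_weighted: bool = True) -> BetaMntdMatrix:
    """Observed βMNTD between every pair of samples.

    Provide either the tree or a precomputed cophenetic matrix (``dist``);
    rows are normalized to relative abundance internally, or to uniform
    weights over present taxa when ``abundance_weighted`` is off.
    """
    if dist is None:
        if tree is None:
            raise ValidationError("pairwise_bmntd needs a tree or a cophenetic matrix")
        dist = cophenetic_matrix(tree)
    missing = set(table.data.columns) - set(dist.index)
    if missing:
        raise ConsistencyError(
            f"taxa missing from tree (align inputs first): {sorted(missing)[:5]}")
    d = dist.loc[table.data.columns, table.data.columns].to_numpy(dtype=float)
    values = table.data.to_numpy(dtype=float)
    weights = _weights(values, abundance_weighted)
    supports = [np.flatnonzero(values[m] > 0) for m in range(values.shape[0])]
    bm = _bmntd_all_pairs(weights, supports, d)
    np.fill_diagonal(bm, 0.0)
    ids = table.data.index
    return BetaMntdMatrix(values=pd.DataFrame(bm, index=ids, columns=ids),
                          abundance_weighted=abundance_weighted)


def bnti_matrix(table: CommunityTable, tree=None, n_null: int = 999, seed: int = 0,
                abundance_weighted: bool = True, dist: pd.DataFrame | None = None,
                joint_shuffle: bool = True) -> BetaNtiMatrix:
    """βNTI: z-score of observed βMNTD against the tip-shuffle null.

    Each null replicate applies one random permutation of taxon
    identities across all tree tips.  By default the permutation is
    shared by every pair within a replicate (cheap, and preserves the
    null's between-pair correlation structure); ``joint_shuffle=False``
    draws an independent permutation per pair instead.  Null mean and sd
    use the n−1 (sample) convention; pairs whose null sd is zero are
    returned as NaN and must be excluded from downstream fractions.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    if dist is None:
        if tree is None:
            raise ValidationError("bnti_matrix needs a tree or a cophenetic matrix")
        dist = cophenetic_matrix(tree)
    missing = set(table.data.columns) - set(dist.index)
    if missing:
        raise ConsistencyError(
            f"taxa missing from tree (align inputs first): {sorted(missing)[:5]}")
    d = dist.loc[table.data.columns, table.data.columns].to_numpy(dtype=float)
    values = table.data.to_numpy(dtype=float)
    weights = _weights(values, abundance_weighted)
    supports = [np.flatnonzero(values[m] > 0) for m in range(values.shape[0])]
    n = values.shape[0]
    s = d.shape[0]
    obs = _bmntd_all_pairs(weights, supports, d)
    np.fill_diagonal(obs, 0.0)

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    if joint_shuffle:
        nulls = np.empty((n_null, n, n))
        for r in range(n_null):
            perm = rng.permutation(s)
            nulls[r] = _bmntd_all_pairs(weights, supports, d[np.ix_(perm, perm)])
        null_mean = nulls.mean(axis=0)
        null_sd = nulls.std(axis=0, ddof=1)
    else:
        null_mean = np.zeros((n, n))
        null_sd = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        for k, m in zip(*iu):
            w = weights[[k, m]]
            sup = [supports[k], supports[m]]
            draws = np.empty(n_null)
            for r in range(n_null):
                perm = rng.permutation(s)
                draws[r] = _bmntd_all_pairs(w, sup, d[np.ix_(perm, perm)])[0, 1]
            null_mean[k, m] = null_mean[m, k] = draws.mean()
            null_sd[k, m] = null_sd[m, k] = draws.std(ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - null_mean) / null_sd
    np.fill_diagonal(bnti, 0.0)
    degenerate = ~np.isfinite(bnti)
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        n_bad = int(degenerate.sum() // 2)
        log.info("bnti_matrix: %d pair(s) with zero null sd flagged non-finite", n_bad)
        bnti[degenerate] = np.nan
    ids = table.data.index
    return BetaNtiMatrix(values=pd.DataFrame(bnti, index=ids, columns=ids),
                         bmntd_observed=pd.DataFrame(obs, index=ids, columns=ids),
                         n_null=n_null, seed=seed, abundance_weighted=abundance_weighted)


def rc_null_community(rng: np.random.Generator, richness: int, reads: int,
                      occupancy_weights: np.ndarray,
                      abundance_weights: np.ndarray) -> np.ndarray:
    """One null community preserving richness and total reads.

    Species occurrences are drawn without replacement with probability ∝
    regional occupancy; each drawn species receives one read, and the
    remaining reads are assigned multinomially ∝ regional relative
    abundance within the drawn species.
    """
    s = len(occupancy_weights)
    if not 1 <= richness <= s:
        raise ValidationError("richness must be in [1, n_taxa]")
    if reads < richness:
        raise ValidationError("reads must be >= richness")
    p = occupancy_weights / occupancy_weights.sum()
    chosen = rng.choice(s, size=richness, replace=False, p=p)
    counts = np.zeros(s, dtype=np.int64)
    counts[chosen] = 1
    remaining = reads - richness
    if remaining > 0:
        w = abundance_weights[chosen].astype(float)
        if w.sum() <= 0:
            w = np.ones(richness)
        counts[chosen] += rng.multinomial(remaining, w / w.sum())
    return counts


def _bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(x - y).sum() / (x + y).sum())


def rc_bray_matrix(table: CommunityTable, n_null: int = 999, seed: int = 0,
                   occupancy_weights: np.ndarray | None = None,
                   abundance_weights: np.ndarray | None = None) -> RcMatrix:
    """Abundance-based Raup-Crick matrix from a raw counts table.

    Regional occupancy (fraction of samples occupied) and regional
    relative abundance default to the table's own empirical values; both
    can be overridden, e.g. for calibration against a known regional
    pool.  Ties between null and observed Bray-Curtis count half.
    """
    if not table.counts_are_integer():
        raise ValidationError(
            "Raup-Crick needs raw integer counts; pass the unstandardized table")
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    values = table.data.to_numpy(dtype=np.int64)
    n, s = values.shape
    occ = (values > 0).mean(axis=0) if occupancy_weights is None \
        else np.asarray(occupancy_weights, dtype=float)
    abund = values.sum(axis=0) / values.sum() if abundance_weights is None \
        else np.asarray(abundance_weights, dtype=float)
    if len(occ) != s or len(abund) != s:
        raise ConsistencyError("weight vectors must match the number of taxa")
    richness = (values > 0).sum(axis=1)
    reads = values.sum(axis=1)

    rc = np.zeros((n, n))
    pair_index = 0
    tol = 1e-10
    for k in range(n):
        for m in range(k + 1, n):
            rng = np.random.default_rng(
                np.random.SeedSequence(int(seed), spawn_key=(pair_index,)))
            pair_index += 1
            obs = _bray_curtis_pair(values[k].astype(float), values[m].astype(float))
            less = equal = 0
            for _ in range(n_null):
                a = rc_null_community(rng, int(richness[k]), int(reads[k]), occ, abund)
                b = rc_null_community(rng, int(richness[m]), int(reads[m]), occ, abund)
                bc = _bray_curtis_pair(a.astype(float), b.astype(float))
                if bc < obs - tol:
                    less += 1
                elif abs(bc - obs) <= tol:
                    equal += 1
            rc[k, m] = rc[m, k] = ((less + 0.5 * equal) / n_null - 0.5) * 2.0
    ids = table.data.index
    return RcMatrix(values=pd.DataFrame(rc, index=ids, columns=ids),
                    n_null=n_null, seed=seed)


def _subset_probability(subset: tuple[int, ...], weights: np.ndarray) -> float:
    """Probability of drawing ``subset`` (unordered) by weighted sampling
    without replacement — sum over all draw orders."""
    import itertools

    total = weights.sum()
    p = 0.0
    for order in itertools.permutations(subset):
        q, remaining = 1.0, total
        for i in order:
            q *= weights[i] / remaining
            remaining -= weights[i]
        p += q
    return p


def rc_exact_pair(x: np.ndarray, y: np.ndarray,
                  occupancy_weights: np.ndarray,
                  abundance_weights: np.ndarray | None = None) -> float:
    """Exact Raup-Crick for a pair whose null is fully enumerable.

    Valid when each sample's total reads equal its richness (every
    present taxon has exactly one read), so a null community is just a
    weighted subset draw and the null Bray-Curtis distribution can be
    enumerated over all subset pairs.  Used to validate the Monte-Carlo
    estimator on toy problems.
    """
    import itertools

    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    for v in (x, y):
        if v.sum() != (v > 0).sum():
            raise ValidationError("exact RC requires one read per present taxon")
    occ = np.asarray(occupancy_weights, dtype=float)
    s = len(occ)
    obs = _bray_curtis_pair(x.astype(float), y.astype(float))
    rx, ry = int((x > 0).sum()), int((y > 0).sum())
    tol = 1e-12
    less = equal = 0.0
    for sub_a in itertools.combinations(range(s), rx):
        pa = _subset_probability(sub_a, occ)
        a = np.zeros(s)
        a[list(sub_a)] = 1.0
        for sub_b in itertools.combinations(range(s), ry):
            pb = _subset_probability(sub_b, occ)
            b = np.zeros(s)
            b[list(sub_b)] = 1.0
            bc = _bray_curtis_pair(a, b)
            if bc < obs - tol:
                less += pa * pb
            elif abs(bc - obs) <= tol:
                equal += pa * pb
    return float(((less + 0.5 * equal) - 0.5) * 2.0)


def classify_pair(bnti: float, rc: float) -> str | None:
    """Assembly process for one pair; None when βNTI is non-finite."""
    if not np.isfinite(bnti):
        return None
    if bnti > 2.0:
        return "variable_selection"
    if bnti < -2.0:
        return "homogeneous_selection"
    if np.isfinite(rc):
        if rc > 0.95:
            return "dispersal_limitation"
        if rc < -0.95:
            return "homogenizing_dispersal"
    return "undominated"


@dataclass
class AssemblyResult:
    """Per-pair process calls plus exclusion bookkeeping.

    ``pairs`` has one row per unordered sample pair with columns
    sample_a, sample_b, bmntd_obs (optional), bnti, rc, process; pairs
    whose βNTI was non-finite carry process = NaN and are excluded from
    all fraction denominators (their count is reported).
    """

    pairs: pd.DataFrame
    n_excluded: int = 0
    settings: dict = field(default_factory=dict)


def classify_assembly(bnti: BetaNtiMatrix, rc: RcMatrix) -> AssemblyResult:
    """Combine βNTI and RC matrices into per-pair process labels."""
    ids = list(bnti.values.index)
    if set(ids) != set(rc.values.index):
        raise ConsistencyError("βNTI and RC matrices cover different samples")
    rcv = rc.values.loc[ids, ids]
    rows = []
    n_excluded = 0
    bn = bnti.values.to_numpy()
    bm = bnti.bmntd_observed.to_numpy()
    rv = rcv.to_numpy()
    n = len(ids)
    for k in range(n):
        for m in range(k + 1, n):
            process = classify_pair(bn[k, m], rv[k, m])
            if process is None:
                n_excluded += 1
            rows.append(dict(sample_a=ids[k], sample_b=ids[m],
                             bmntd_obs=bm[k, m], bnti=bn[k, m], rc=rv[k, m],
                             process=process if process is not None else np.nan))
    pairs = pd.DataFrame(rows)
    if n_excluded:
        log.info("classify_assembly: %d pair(s) excluded (non-finite βNTI)", n_excluded)
    return AssemblyResult(pairs=pairs, n_excluded=n_excluded,
                          settings=dict(n_null_bnti=bnti.n_null, n_null_rc=rc.n_null,
                                        seed_bnti=bnti.seed, seed_rc=rc.seed))


def zone_strata(meta: pd.DataFrame, zone_column: str = "irradiance_zone",
                photic_label: str = "photic") -> "callable":
    """Pair → stratum rule from per-sample irradiance zones.

    A pair is ``euphotic`` when both samples are photic, ``aphotic`` when
    both are aphotic, ``mixed`` otherwise; the summary always reports the
    ``entire`` stratum over all pairs in addition.
    """
    zones = meta[zone_column]

    def stratum(sample_a: str, sample_b: str) -> str:
        za, zb = zones.loc[sample_a], zones.loc[sample_b]
        if za == photic_label and zb == photic_label:
            return "euphotic"
        if za != photic_label and zb != photic_label:
            return "aphotic"
        return "mixed"

    return stratum


def summarize_process_fractions(result: AssemblyResult, strata=None) -> pd.DataFrame:
    """Per-stratum fraction of pairs assigned to each process.

    ``strata`` is a callable (sample_a, sample_b) → stratum name or a
    dict keyed by (sample_a, sample_b); omitted, all pairs fall in the
    single ``entire`` stratum.  The ``entire`` stratum over all pairs is
    always included.  Excluded (non-finite βNTI) pairs are dropped from
    denominators; ``n_pairs`` counts the retained pairs per stratum and
    ``n_excluded`` the dropped ones.
    """
    pairs = result.pairs.copy()
    if strata is None:
        pairs["stratum"] = "entire"
    elif callable(strata):
        pairs["stratum"] = [strata(a, b) for a, b in zip(pairs.sample_a, pairs.sample_b)]
    else:
        pairs["stratum"] = [strata[(a, b)] for a, b in zip(pairs.sample_a, pairs.sample_b)]

    def fractions(sub: pd.DataFrame, name: str) -> dict:
        valid = sub[sub.process.notna()]
        row = dict(stratum=name, n_pairs=len(valid),
                   n_excluded=int(sub.process.isna().sum()))
        for process in PROCESSES:
            row[process] = (float((valid.process == process).mean())
                            if len(valid) else np.nan)
        return row

    rows = [fractions(pairs, "entire")]
    if strata is not None:
        for name, sub in pairs.groupby("stratum"):
            if name == "entire":
                continue
            rows.append(fractions(sub, str(name)))
    return pd.DataFrame(rows).set_index("stratum")


def assembly_long_table(result: AssemblyResult, strata=None) -> pd.DataFrame:
    """Long-format per-pair table (sample_a, sample_b, bmntd_obs, bnti, rc,
    process, stratum) for TSV export."""
    pairs = result.pairs.copy()
    if strata is None:
        pairs["stratum"] = "entire"
    elif callable(strata):
        pairs["stratum"] = [strata(a, b) for a, b in zip(pairs.sample_a, pairs.sample_b)]
    else:
        pairs["stratum"] = [strata[(a, b)] for a, b in zip(pairs.sample_a, pairs.sample_b)]
    return pairs
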