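# Methods

`ecoassembly` implements the statistical core of a community-ecology
analysis of marine amplicon surveys: alpha/beta diversity, ordination,
spatial and group statistics, and — at its centre — null-model inference
of community assembly processes from per-pair phylogenetic (βNTI) and
taxonomic (Raup-Crick) turnover. A synthetic metacommunity generator
provides ground truth for every stage, so the whole chain is verifiable
without any sequencing data.

## Assembly inference

### βMNTD and βNTI

For communities *k*, *m* with relative abundances *f* and patristic
distance *d* between taxa,

    βMNTD(k,m) = ½ Σ_{i∈k} f_ik · min_{j∈m} d_ij
               + ½ Σ_{j∈m} f_jm · min_{i∈k} d_ij .

Abundance weighting is the default (the pipeline consumes a standardized
abundance table); a presence-based mode (uniform weights over present
taxa) is kept for diagnostics. Identical implementations in the
literature (picante's `comdistnt`) agree with ours to machine precision
on shared inputs; an independent brute-force double loop is the test
oracle.

βNTI is the z-score of observed βMNTD against a null that randomly
permutes taxon identities across **all** tips of the tree — the regional
pool — thereby destroying phylogenetic niche signal while preserving
tree shape, composition, and richness:

    βNTI(k,m) = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null ,

with the sample (n−1) standard deviation over `n_null` replicates
(default 999). By default one joint tip permutation per replicate is
shared by all pairs; this leaves each pair's marginal null untouched
(verified by a self-consistency test: data generated independently of
the phylogeny give mean βNTI ≈ 0, sd ≈ 1) while costing a single βMNTD
evaluation per replicate. Per-pair independent permutations are
available via `joint_shuffle=False`. Pairs whose null sd is zero —
e.g. identical supports, or a star phylogeny where all distances are
equal — are flagged non-finite, excluded from every downstream fraction,
and counted in the output.

### Abundance-based Raup-Crick

For each pair, each null replicate reassembles both communities
preserving their observed richness and read totals: occurrences are
drawn without replacement with probability proportional to regional
occupancy (fraction of samples occupied), each drawn taxon receives one
read, and the remaining reads are assigned multinomially in proportion
to regional relative abundance among the drawn taxa. Bray-Curtis is
computed per replicate and

    RC = 2 · ( (#null < obs) + ½·(#null = obs) ) / n_null − 1  ∈ [−1, 1],

ties counting half (tie tolerance 1e-10 on Bray-Curtis). RC always uses
the raw counts table even though βNTI uses relative abundances.
Regional occupancy and abundance default to the analysed table's own
empirical values and can be overridden for calibration; an exact
enumeration mode (`rc_exact_pair`) covers toys where every present taxon
has exactly one read, and validates the Monte-Carlo estimator.

### Classification

Per pair, with strict inequalities so that boundary values fall through
to the stochastic/undominated side:

| condition | process |
|---|---|
| βNTI > +2 | variable selection |
| βNTI < −2 | homogeneous selection |
| else RC > +0.95 | dispersal limitation |
| else RC < −0.95 | homogenizing dispersal |
| otherwise | undominated |

Zone-stratified summaries call a pair *euphotic* when both samples lie
in the photic zone, *aphotic* when both are aphotic; mixed pairs count
only toward the *entire* stratum. This pair-stratification rule is a
package convention and is recorded in the output.

## Synthetic metacommunities

The generator emulates the *derived* data level of a depth-structured
open-ocean survey — an ASV count table over a known phylogeny with
station × depth metadata — under five generative regimes matching the
classifier's process categories. Common machinery:

* **Phylogeny** — a Yule (pure-birth) tree, ultrametric, total height
  rescaled to 1; tips are the ASVs.
* **Niche traits** — Brownian motion from a root value of 0. Scenario
  traits use an early-burst variant (diffusion rate ∝ exp(−a·t),
  default a = 10): on small height-1 trees, plain BM yields weak and
  seed-unstable niche conservatism, while the early burst concentrates
  divergence on deep branches so that clades form coherent trait
  clusters — the structure nearest-taxon statistics are designed to
  detect. Trait optima are min-max rescaled to [0, 1] before use.
* **Regional pool** — fixed log-normal(0, 2) relative abundances. The
  heavy skew is deliberate: it reproduces the real-data property that
  per-sample richness is far below pool richness, which both null
  models need (with an even pool every taxon occurs in every sample,
  occupancy weighting is vacuous, and identical supports make βMNTD
  degenerate).
* **Environment** — a normalized depth proxy in [0, 1] from the
  metadata; depth is the dominant axis of vertical ocean structure.
* **RNG** — every stream derives from the single scenario seed via
  `SeedSequence(seed, spawn_key)` (tree/traits/metadata/community), so
  sub-components are independently reproducible.

Regimes (see `ScenarioSpec.for_regime` for the numeric defaults):

* **Selection** (homogeneous / variable): sampling weight
  `pool^w · exp(−s(x−e)²/(2σ²)) · lottery · recruit`. The per-site
  log-normal lottery and Bernoulli recruitment filter model demographic
  stochasticity and priority effects; without them all sites under one
  environment converge on the same ASVs and there is no turnover for
  βNTI to evaluate. Under strong selection the regional-abundance prior
  is flattened (`pool_weight` 0–0.25): local fitness, not regional
  commonness, decides. Homogeneous selection places every site at the
  environment where the pool carries maximal kernel mass (the
  best-adapted radiation); variable selection spreads sites across the
  full gradient.
* **Dispersal limitation**: no selection; the pool is partitioned into
  per-site blocks, mixed with the full pool at weight `m` (default
  0.02), then sampled multinomially — local drift on disjoint-biased
  pools.
* **Homogenizing dispersal**: one shared realized community; each site
  keeps 90 % of its individuals and resamples 10 % (hypergeometric
  retention + multinomial replacement). Between-site variance thus
  falls *below* the full-resampling noise floor, which is the only
  signature of overwhelming exchange that a self-referential null can
  detect: a full multinomial resample is statistically identical to the
  RC null's own assembly process and yields RC ≈ 0.
* **Drift**: independent multinomial draws from the pool.

What the generator does **not** emulate: sequence-level artefacts (PCR
bias, chimeras, copy-number variation), temporal autocorrelation,
spatially autocorrelated dispersal kernels (dispersal-limited site pools
are spatially random, so distance-decay slopes are near zero by
construction), and mixtures of processes within one table. Passing
recovery tests therefore show that the inference chain identifies each
process *in isolation at desk scale*, not that it resolves mixed
assembly in field data.

## Diversity, spatial and group statistics

* Standardization: relative abundance by default (rarefaction via
  multivariate hypergeometric subsampling is available and seeded); the
  choice is recorded in each table's provenance.
* Shannon entropy is reported in **nats**; richness is a nonzero count;
  Faith's PD sums the branch lengths of the minimal subtree spanning
  the present taxa **including the path to the root** (the common
  default of the tool family; switchable) — the tree is used rooted as
  written, never re-rooted.
* Bray-Curtis via `scipy`'s implementation; PCoA by Gower
  double-centering of −½D² with eigendecomposition; negative
  eigenvalues are counted and reported, never corrected; proportions
  explained are relative to the sum of positive eigenvalues; asymmetry
  beyond 1e-8 is an error.
* Geographic distance: haversine with Earth radius 6371.0088 km.
  Environmental distance: per-variable z-scores (sample, n−1, sd) then
  Euclidean; samples with missing values are excluded and logged;
  zero-variance variables are an error.
* Distance-decay regresses **similarity** (1 − Bray-Curtis) on distance
  over the strict upper triangle (a distance-response mode exists).
  Pairs are the units and are not independent; p-values carry that
  caveat. A constant response returns slope 0, R² 0 rather than NaN.
* Mantel: Pearson correlation of upper triangles; the null jointly
  permutes rows and columns of the second matrix; upper one-sided tail
  by default, two-sided by flag; permutation p-values use the +1
  correction, `(c+1)/(n_perm+1)`, so p ≥ 1/(n_perm+1). An exhaustive
  mode enumerates all relabelings and returns the exact fraction.
* PERMANOVA is single-factor: pseudo-F from the distance-based
  sum-of-squares decomposition (SS_T = Σd²/n), label-permutation p with
  the +1 correction, exhaustive enumeration for tiny designs.
  Multi-factor designs are analysed one factor at a time; the factors
  of a survey design (station, depth, zone) are not orthogonal, so
  their separate R² values must not be added.
* Welch t (Welch–Satterthwaite df), one-way ANOVA with Tukey-Kramer HSD
  (studentized range, pooled variance), Pearson correlation — all via
  scipy, wrapped with the package's validation and result types.
* Diel variability: per depth and unit (taxonomic order or trophic
  group), CV = sample sd / mean of relative abundance across time
  points, replicates within a time point averaged first; zero-mean
  units are undefined (NaN), never 0; single-time-point depths are
  excluded with a warning.
* Trophic groups: deepest taxonomic rank with a lookup entry wins;
  unmatched taxa are `unknown`; group abundances conserve totals
  exactly.

## Study conditions used by the acceptance checks

Problem sizes were chosen to keep every check inside a desk-scale
compute budget while leaving the statistics meaningful: βMNTD oracle
instances ≤ 6 taxa × 4 samples (30 instances); βNTI self-consistency on
100 pairs from 10 independent 50-taxon tables with 999 null replicates;
RC calibration on 210 pairs (21 samples from its own null process, 299
replicates); regime recovery at 60 taxa × 12 sites × 5000 reads with
299 null replicates; permutation-test calibration on 500 simulations of
12-sample (PERMANOVA) and 8-sample (Mantel) designs at 199 permutations.

The regime-recovery scenarios use a fixed generator seed (2016, set
once in advance as part of the study conditions) because recovery rates
at this problem size are tree-shape dependent. Measured across ten
arbitrary seeds, homogeneous-selection recovery has median ≈ 0.73 and
variable-selection ≈ 0.78, with roughly three seeds in ten falling
below 0.70 for either regime: at 60 taxa, βNTI for even ideally
clade-restricted communities concentrates near the ±2 threshold, so a
fixed-seed run can sit below a 70 % recovery target without any defect
in the classifier. At the frozen seed, homogeneous selection recovers
≈ 0.58 of pairs (the corresponding acceptance assertion is left
failing rather than re-tuned), while the other three regimes recover
0.77–0.97.

## Known limitations

* βNTI at small pool sizes (≲ 100 taxa) has limited power to detect
  homogeneous selection; magnitudes scale roughly with the square root
  of sample richness.
* RC cannot flag homogenizing dispersal when the homogenized community
  coincides with the table-wide regional expectation (self-referential
  null); the generator documents this and models exchange as partial
  individual turnover instead.
* The pipeline's PERMANOVA is single-factor by design; sequential
  multi-term decompositions are out of scope.
* Distance-decay p-values treat non-independent pairs as observations,
  as is conventional; use the Mantel permutation p for inference.
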