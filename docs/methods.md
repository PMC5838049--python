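# Methods

This note records the models and procedures implemented in
`commassembly`, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Community structure: weighted MPD and its null model

The structure of an assemblage is scored by the mean pairwise distance
among its individuals, computed on either a functional (Gower) or a
phylogenetic (patristic) distance matrix over the regional species
pool. With relative abundances `f_i`, the abundance-weighted statistic
is

    MPD = Σ_{i≠j} f_i f_j d_ij / Σ_{i≠j} f_i f_j ,

the expected distance between two individuals *of different species*
drawn by abundance. Conspecific pairs (distance zero) are excluded by
default; `include_conspecific=True` gives the Rao quadratic-entropy
variant that keeps them (this is what picante's abundance-weighted MPD
computes, and it is the flavour our picante cross-check test uses).
With equal abundances the weighted and unweighted statistics coincide.

The null model is the *taxa labels* randomization: species names are
shuffled uniformly across the rows/columns of the full pool distance
matrix while community membership and abundances stay fixed, so each
null draw evaluates the same community on a random relabelling of the
pool. The standardized effect size uses the sample (n−1) standard
deviation of `n_null` (default 999) null values and flips the sign so
that clustering is positive:

    ses = −(observed − mean_null) / sd_null .

Per-assemblage inference is the mid-ranked, add-one-corrected null
quantile

    p = (#{null < obs} + ½·#{null = obs} + 1) / (n_null + 1) ,

which is uniform on its grid under the null regardless of the null
distribution's shape; small p means clustering, large p
overdispersion, and a two-sided α-level test rejects outside
(α/2, 1−α/2). When the null has zero spread (all distances equal, or
the community is the whole pool, where every relabelling returns the
same value) the effect size is reported as missing with a
"degenerate null" status rather than ±∞.

The classical statistics in `compare_seasons` — paired t across plots
between seasons, Pearson r between the functional and phylogenetic
effect sizes, one-sample t of a set of effect sizes against zero — are
secondary descriptive outputs. A per-assemblage one-sample t against
zero is not well defined on a single effect-size value, so the
rank-based p above is the primary per-assemblage inference.

## Phylogenetic signal

**Blomberg's K** (continuous traits). With `V` the Brownian
variance–covariance matrix of the tree (`V[i,j]` = root-to-MRCA path
length), the GLS ancestral state is `â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1)`, and

    K = (MSE0 / MSE) / E[MSE0/MSE] ,
    MSE0 = (x−â)ᵀ(x−â)/(n−1),  MSE = (x−â)ᵀV⁻¹(x−â)/(n−1),
    E[MSE0/MSE] = (tr V − n/Σ_ij(V⁻¹)_ij)/(n−1) .

K is exactly 1 on a star phylogeny and invariant to affine transforms
of the trait. The permutation test shuffles trait values across tips
and reports the one-sided (greater) add-one-corrected p of K itself;
under tip exchangeability this is equivalent in distribution to
permuting the data relative to the tree. V is factorized once by
Cholesky; a singular V (duplicate zero-length tips) raises an error
suggesting branch-length jitter rather than silently regularizing.

**Fritz–Purvis D** (binary traits). The observed statistic `d_obs` is
the sum of sister-clade differences: tips-to-root, each internal node
takes the unweighted mean of its daughters' values and contributes the
summed absolute deviation of the daughters from that mean (for a
bifurcation, simply |left − right|; polytomies contribute one term per
daughter). It is scaled between two simulated nulls,

    D = (d_obs − mean d_Brownian) / (mean d_random − mean d_Brownian),

where the random null permutes trait values across tips and the
Brownian null thresholds simulated Brownian liabilities at the
quantile matching the observed prevalence (matched-prevalence
threshold model), `n_sim` = 1000 draws each. D ≈ 1 for phylogenetically
random traits, ≈ 0 under threshold-Brownian evolution, and < 0 for
hyper-conserved traits; `p_random = P(d_random ≤ d_obs)` and
`p_brownian = P(d_Brownian ≥ d_obs)` with add-one correction. Both
nulls are evaluated in a single vectorized postorder pass over all
draws.

## Diversity panel

- **SR, SE**: richness is the count of species with positive
  abundance; Pielou's evenness is Shannon entropy over relative
  abundances divided by ln SR, reported as missing for SR = 1 (the
  ratio is 0/0, not 0 or 1).
- **Faith's PD**: total branch length of the minimal spanning subtree
  of the community; `include_root=True` (default) keeps the path from
  the community MRCA to the root, matching the convention of the
  standard implementation, with the flag exposed.
- **FRic**: convex-hull volume of the community's species in the first
  m principal-coordinate axes of the Gower matrix. The Gower
  dissimilarity is generally not Euclidean-embeddable, so when the
  double-centred Gram matrix has a meaningfully negative eigenvalue
  the off-diagonal distances are square-root transformed first (which
  restores embeddability for Gower coefficients). By default
  m = min(s_min − 1, 6), where s_min is the smallest community size: a
  nondegenerate m-dimensional hull needs more than m points, and
  capping at 6 keeps hull volumes comparable and cheap. A community
  with ≤ m species is measured in its own (size − 1)-dimensional
  subspace with a warning; fully degenerate point sets get volume 0.
  Because the axis count and correction materially change FRic's
  scale, FRic values are comparable only within one analysis run.
- **Ordination**: relative abundances are square-root transformed and
  Wisconsin double standardized (each species column divided by its
  maximum, then each row by its total) before Bray–Curtis distances
  and nonmetric MDS. NMDS minimizes Kruskal stress-1 by SMACOF with
  isotonic regression (primary/weak tie handling), best of 16 random
  starts, deterministic given the seed.

## Gower dissimilarity

    d(a,b) = Σ_k w_k δ_k s_k(a,b) / Σ_k w_k δ_k

with `s_k = |x_a − x_b| / range_k` for continuous traits (range over
the whole table, so distances are comparable across assemblages from
one pool) and the mismatch indicator for binary traits; `δ_k = 1` only
when both species have trait k recorded (pairwise deletion, Gower's
original rule). Binary traits are scored symmetrically (0/0 counts as
agreement) because the emulated trait coding uses non-mutually-
exclusive presence attributes; a Jaccard-style asymmetric mode is
available. Weights default to 1 per column; a weight vector lets users
downweight groups of binary columns that expand one conceptual trait
(e.g. 1/5 per diet column). Constant continuous traits are excluded
with a warning (their range is zero); a species pair sharing no usable
trait is an error naming the pair.

## Trees

`Phylogeny` is a flat postorder array structure (children lists,
edge lengths, labels) supporting polytomies everywhere. Patristic
distances and the Brownian VCV come from one pass computing root-to-
node depths and per-node tip partitions; `d_ij = depth_i + depth_j −
2·V_ij`. Pruning collapses degree-2 nodes and sums their edge lengths,
so patristic distances among kept tips are preserved exactly.
Ultrametricity is flagged with relative tolerance 1e-6 on root-to-tip
depths (float round-trips through newick).

Majority-rule consensus counts *rooted clades* (tip sets below
internal nodes), retaining those in strictly more than the threshold
fraction of trees (threshold ∈ [0.5, 1], default 0.5, which guarantees
pairwise compatibility). Since the inputs carry branch lengths and
downstream PD/MPD needs them, each retained edge gets the mean of its
length over the trees containing the clade (median behind a flag) —
the source procedure left this unspecified, so it is this package's
documented choice. Clade support is recorded on internal node labels
and in `clade_support`.

## Synthetic data generator

The generator emulates a three-plot, two-season transect survey of a
~125-species passerine pool and is the package's test substrate.

- **Tree**: pure-birth (Yule) with per-lineage rate 1; after the n-th
  birth an extra Exp(n·λ) waiting time elapses before the present so
  every pendant edge is strictly positive and V is nonsingular.
- **Traits**: k traits drawn with covariance `λ·V_offdiag + diag(V)`
  (Pagel-λ), simulated exactly as `√λ·BM + √(1−λ)·independent`; λ = 1
  is pure Brownian motion, λ = 0 independent tips. Binary traits
  threshold a λ-Brownian liability at the empirical quantile giving
  the target prevalence exactly (default 0.5). Defaults: 2 continuous
  + 15 binary traits, λ = 1 (the emulated study found strong signal in
  all 17 traits).
- **Assembly**: filtering samples richness species without replacement
  with weight `exp(−strength·‖x − optimum‖²)` on z-scored traits
  (Gumbel top-k, so strength 0 is exactly uniform); limiting
  similarity grows the assemblage sequentially with weight
  `exp(strength · min Gower distance to the already-selected)`;
  neutral is uniform. Default regimes mirror the emulated gradient:
  strong filtering at the high-elevation plot, neutral mid, weak
  limiting similarity low; default richness values are the six
  observed community sizes (35–57).
- **Abundance**: i.i.d. ceil-discretized lognormal(0, σ = 1) ≥ 1. The
  emulated study reports abundance-weighted metrics but no abundance
  model; a lognormal species-abundance distribution is the standard
  community-ecology default.
- **Survey**: each species' abundance is allocated to 3 transects
  uniformly (multinomial); each of 8 repeats independently detects
  each allocated individual with probability 0.8 (binomial). The
  abundance estimator takes, per transect, the elementwise maximum
  count over repeats and sums transects — the estimator the emulated
  survey protocol uses.

Every simulator derives one `numpy` Generator from its seed and is
bit-reproducible; `simulate_dataset` spawns independent per-stage
seeds from the master seed so each stage can be replayed alone.

What the generator does **not** emulate: detection heterogeneity
between species or observers, spatial territory structure, seasonal
migration dynamics, and trait correlations beyond shared phylogeny.
Passing calibration tests therefore demonstrates that the estimators
are unbiased and correctly scaled under the stated generative model,
not that real surveys meet those assumptions.

## Calibration choices and problem sizes

The test suite pins: mean Blomberg K ≈ 1 over 200 Brownian traits and
mean D ≈ 0 / ≈ 1 over 200 threshold-Brownian / tip-permuted traits on
a 128-tip tree (tolerance ±0.1 and ±0.15); the SES null centred at 0
with sd in [0.8, 1.2] over 300 pool-random assemblages (999 nulls
each); exact (≤1e-12) agreement of Gower, weighted MPD, Faith's PD and
patristic distances with brute-force oracles on ≤15-species instances;
Monte-Carlo vs exhaustive 4!-relabelling null agreement within
moment-based standard errors; and regime recovery (strength 30,
richness 30 from a 125-species pool: filtering detected as NRI > 0
with p < 0.05 in ≥80% of 20 runs, limiting similarity as NRI < 0 in
the majority, neutral type-I error within 5% ± 4 points over 400
runs). Replication counts were sized so the Monte-Carlo standard error
of each checked quantity is small against its tolerance band.

`scripts/acceptance.py` re-runs the two D-statistic calibrations from
scratch with user-supplied seeding.

## Known limitations

- Consensus requires threshold ≥ 0.5; sub-majority greedy consensus is
  out of scope.
- FRic is sensitive to the number of retained axes; absolute values
  are not comparable across studies that chose different axis counts.
- The filtering regime acts on trait space; its phylogenetic signature
  (NRI) is indirect and weakens at large richness-to-pool ratios.
- K's permutation test assumes tip exchangeability under the null;
  Pagel's λ likelihood estimation and other transforms are not
  implemented.
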