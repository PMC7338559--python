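# Methods

This note records the models, numerical conventions and design choices
behind `assemblyscape`, and what the synthetic-data tests do and do not
establish.

## 1. βMNTD / βNTI

**Statistic.** Abundance-weighted β mean nearest-taxon distance on relative
abundances within each sample; only taxa with count > 0 participate. No
rarefaction is applied before βNTI (relative abundances make depths
comparable); rarefaction is reserved for the Raup–Crick stage.

**Null.** One uniformly random tip-label permutation per repetition, shared
by all sample pairs, applied to the cophenetic matrix of the analysed data
split. Sharing one permutation across pairs makes the full matrix
reproducible from a single seed and matches common implementations of the
framework; shuffling within the analysed split (rather than some larger
pool) means a taxon-subset analysis asks "is turnover structured *within
this group*". Defaults: 999 repetitions, sd with the n−1 denominator.

**Degenerate nulls.** If sd(βMNTD_null) = 0 (e.g. a star phylogeny, or two
samples with identical taxon support, where every permutation returns the
same value), βNTI is NaN and the pair is flagged `degenerate_null`; it is
classified `unclassified` downstream, never silently dropped.

**Vectorization.** For sample k the vector m_k(i) = min_{j present in k}
d(i,j) is computed once per (permutation, sample); βMNTD for all pairs is
then one matrix product, ½(F Mᵀ + (F Mᵀ)ᵀ). This is exactly equal (≤ 1e−12)
to the per-pair reference implementation, which is kept and tested against.

## 2. Abundance-weighted Raup–Crick (RC_Bray)

**Null assemblage.** Per sample: draw the observed richness without
replacement with probability ∝ occupancy; give each drawn taxon one
individual; distribute the remaining depth − richness individuals
multinomially ∝ regional relative abundance renormalized over the drawn
taxa. Occupancy and regional abundance default to the analysed
(post-rarefaction, post-split) table and are isolated in
`NullAssemblyWeights`; both engines accept a `weights` override for cases
where the regional pool is known externally. Ties between null and observed
Bray–Curtis count ½ (classical convention); RC_raw is rescaled to [−1, 1].

**Engines.** The naive engine draws independent null pairs for every sample
pair (quadratic; kept as the reference). The fast engine draws one null
assemblage per sample per repetition and computes the whole pairwise
Bray–Curtis matrix once per repetition; per-repetition RNG substreams are
spawned from the master seed and the accumulated counts are integers, so
results are bit-identical for any worker count. The two engines are
bit-identical when fed the same null draws, and agree within Monte-Carlo
error (binomial error of RC_raw ≈ 0.016 at 999 reps) otherwise.

**Calibration caveat — read this before interpreting RC < −0.95.** The
occupancy-weighted species draw cannot distinguish a dominant taxon from any
other widely occurring taxon: in a cohesive community where many taxa occur
everywhere, null assemblages randomly omit abundant taxa, which inflates
null dissimilarity. Communities assembled by plain iid multinomial sampling
from one pool are therefore systematically scored as "more similar than
expected" (RC ≈ −1) — the null is only centred against *its own* generative
model (verified by the exchangeability test in the acceptance suite, which
draws observed communities from the null with fixed weights: mean RC ≈ 0,
P(|RC| > 0.95) ≈ 0.05). Interpreting RC < −0.95 as homogenizing dispersal
presumes, as the framework does, that the null's assembly model is the
appropriate stochastic baseline. This behaviour is intrinsic to the method,
not an implementation artifact.

## 3. Process classification

Strict inequalities on both thresholds (|βNTI| > 2 for selection, |RC| >
0.95 for the dispersal categories); boundary values fall through to the
stochastic / undominated side, a conservative choice since the thresholds
are conventions. The selection branch is evaluated first, so a pair with
βNTI > 2 is `variable_selection` regardless of its RC value. NaN βNTI →
`unclassified`, excluded from fraction denominators but reported in counts.

Scenario filters reproduce the standard conditioning analyses: same/different
sampling occasion ("within/between months"), spatial–temporal windows
(e.g. < 2 m & > 150 days), and upper/lower quartiles of per-pair
environmental differences. Quartiles use the median-unbiased quantile
estimator and boundary-inclusive membership, computed within the analysed
pair table. Group means of fractions carry a normal-approximation 95% CI
(1.96·SE over groups).

## 4. Synthetic communities

The generator states a world and the inference side must recover it; its
defaults mirror an intensively sampled grassland plot (10 m × 10 m grid, six
occasions, 360 sites) while tests run reduced sizes (30–60 sites, 300 OTUs).

- **Regional pool:** lognormal relative abundances (μ = 0, σ = 2 — strongly
  uneven, as microbial SADs are). 1000 reads per sample (a modest rarefied
  depth; calibration results were checked up to depth 10⁴ and do not depend
  on it).
- **Phylogeny:** pure-birth (Yule) tree rescaled to unit root height, so
  βMNTD magnitudes are comparable across OTU counts.
- **Traits:** Brownian motion from root value 0. A `conservatism` parameter
  applies an early-burst rate decay exp(−c · depth); with c = 0 the process
  is exact BM. The selection presets use c = 8 (rate rescaled to keep tip
  variance ≈ 1) because under plain BM the within-clade trait variance at
  the tips is large enough that a narrow trait band mixes unrelated
  lineages, making the phylogenetic signature of selection depend on the
  luck of the tree draw.
- **Assembly:** per site, sampling weights w_i ∝ pool_i ·
  exp(−(trait_i − env)² / 2σ²); the site pool mixes the regional pool
  (weight `dispersal_mix`) with a site-private pool drifted by
  `drift_generations` rounds of multinomial resampling at size = reads
  (Wright–Fisher-like; meaningful drift needs generations of order N =
  reads). `mass_effect` copies that fraction of every community
  deterministically from one shared realized community — the generative
  signature of mass effects, which shared-pool sampling alone cannot
  produce (iid draws from one pool are approximately the RC null's own
  model, hence centred, not RC < −0.95).

**Presets.** Each preset realizes its defining regime robustly across tree
and pool realizations:

| preset | key settings | detected via |
|---|---|---|
| homogenizing_dispersal | mass_effect 0.9, no selection/drift | RC ≈ −1 |
| dispersal_limitation_drift | mix 0.3, drift 1000 | RC ≈ +1 |
| variable_selection | σ 0.25, gradient spanning the niches of two abundant derived clades (`span_tips`) | βNTI > +2 |
| homogeneous_selection | σ 0.10, uniform optimum at an abundant derived clade's niche (`derived_tip`) | βNTI < −2 |
| undominated | mix 0.8, drift 300, σ 3 | everything inside thresholds |

Two generative findings shaped the presets. First, *complete* isolation
(mix = 0) is undetectable: the null's weights are re-estimated from the
analysed table, so fully drifted, mutually disjoint communities produce
equally disjoint null assemblages and the divergence signal vanishes —
dispersal limitation is only visible against a persisting shared regional
core. Second, the anchoring rules (`derived_tip`, `span_tips`) pin selective
optima to trait regions that are both clade-coherent (clearly derived —
near-ancestral trait values mix unrelated lineages that regressed to the
root value) and well populated (carried by abundant taxa); without
anchoring, whether the optimum lands in such a region is luck.

**What a green recovery test establishes.** That the full chain — simulate,
βNTI, RC, classify — attributes the dominant generating force correctly at
desk scale, for every preset and three seeds. It does not establish
calibration on real data: real communities mix processes continuously, have
10⁴–10⁵ OTUs, taxon-dependent detection (16S copy number, primer bias),
and phylogenies estimated with error — none of which the generator emulates.

## 5. Diversity statistics

- Hill numbers for q ∈ {0, 2} only (the orders used in practice at this
  scale; q = 1 is out of scope). Interpolation of ⁰D uses the exact
  hypergeometric expectation; extrapolation uses the Chao1-bounded form
  with the bias-corrected f₀ when doubletons are absent; ²D uses the
  closed-form size-corrected estimator, which reduces exactly to the
  observed 1/Σp² at m = n. Reference size defaults to twice the smallest
  sample total.
- CoV equality: the Feltz–Miller asymptotic χ²(k−1) statistic on sd/mean
  (n−1 denominator). The modified signed-likelihood-ratio variant is not
  implemented (flagged; the asymptotic test is the one exercised here, and
  the two are reported to agree in typical use).
- Resident = occupancy n; transient = occupancy < 10% of n (threshold
  configurable). The abundance–frequency relation is an OLS fit of
  log₁₀ mean relative abundance on log₁₀ occupancy fraction.

## 6. β-diversity

- **LCBD** via Gower-centring of the dissimilarity matrix. Bray–Curtis is
  not Euclidean-embeddable and raw centring can yield negative diagonal
  entries; the default therefore centres √(Bray–Curtis) (the usual remedy),
  keeping every LCBD ≥ 0 and Σ LCBD = 1. `use_sqrt=False` restores raw
  centring. Significance by permuting each OTU column independently
  (999 default), one-sided (large LCBD = unusual composition), Holm-adjusted
  (FDR available).
- **Sørensen partition** uses the multiple-site formulas on pairwise
  min/max unique-species counts; β_SNE is computed as β_SOR − β_SIM, so the
  additivity identity holds to machine precision by construction, and
  β_SOR ≥ β_SIM guarantees β_SNE ≥ 0.
- **Mantel**: Spearman on upper triangles, permuting the second matrix's
  rows and columns jointly; two-sided p with the +1 correction. A joint
  permutation of a symmetric matrix leaves the off-diagonal multiset
  invariant, so ranks are computed once and each permutation reduces to a
  dot product (ties handled correctly because the multiset is invariant).

## 7. Pipeline

`run_pipeline` is deterministic given its config, including across worker
counts; the manifest records package version, every seed, thresholds,
input checksums, and stage timings. With `phylogenetic=False` the run
degrades to RC-only classification over the three stochastic labels and
carries a prominent caveat — selection is undetectable without βNTI.

## Known limitations

- The RC null's negative lean against simple multinomial sampling (§2)
  means "homogenizing dispersal" fractions should be read relative to the
  null's assembly model, not as evidence against neutral sampling.
- βNTI assumes phylogenetic niche conservatism; where traits are labile the
  selection categories lose meaning. The generator makes conservatism a
  dial; real data offer no such knob.
- Permutation LCBD p-values test column-independence, which ignores
  compositional coupling between OTUs.
- No coverage-based (as opposed to size-based) standardization, no
  bootstrap confidence bands on diversity estimates, no per-OTU process
  attribution.
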