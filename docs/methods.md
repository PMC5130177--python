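# Methods

## Study design and what the generator emulates

The pipeline analyses a three-arm perturbation design on a single cell
population: vehicle control (NT), drug (MET), and drug plus a kinase
inhibitor (METCC).  The inhibitor arm exists to partition drug-responsive
features into AMPK-dependent responses (reverting when the kinase is
blocked) and AMPK-independent ones (persisting).  Because the scale of a
real study — tens of thousands of genes and peaks from deep sequencing of
donor hepatocytes, plus four proprietary liver eQTL cohorts — is not
reproducible at desk scale, every stage here is validated against
synthetic data with planted, known effects.

`SimulationConfig` defaults define those study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_replicates_per_condition` | 3 | cultures treated in triplicate |
| `planted_pattern_fractions` | up-dep 0.15, up-indep 0.05, down-dep 0.04, down-indep 0.06, null 0.70 | responder mix mirroring the observed dominance of up-regulated AMPK-dependent responses |
| `effect_log2fc` | 2.0 | planted treated-vs-control shift (log2) |
| `dispersion` | 0.05 | NB dispersion α, variance m + αm² |
| `base_mean_log_range` | (1, 3) | log10 of NB base means: 10–1000 counts |
| `size_factor_log_range` | (0.7, 1.4) | log-uniform sequencing-depth variation |
| `cohort_sizes` | (200, 300, 300, 380) | four liver cohorts totalling 1,180 samples |
| `n_covariates_per_cohort` | (2, 3, 4, 5) | dataset-specific covariates |
| `maf`, `genetic_beta`, `noise_sd` | 0.3, 0.5, 1.0 | eQTL allele frequency, additive effect, residual noise |

Pattern assignment is deterministic by feature index (the first ⌈f₁N⌉
features get pattern 1, and so on), so truth tables realize the configured
fractions exactly and tests can assert exact planted counts.
AMPK-dependent patterns plant *full* reversion (METCC mean = NT mean);
independent patterns plant *zero* reversion (METCC mean = MET mean).  These
are the maximally separable idealizations of the verbal definitions; real
data sits between them, so label-recovery rates measured here are upper
bounds on what partial reversion would give.  The generator also omits
other features of real data — no correlation between genes, no GC or
length biases, no LD between variants, no read-level error — so passing
tests demonstrate correctness of the estimators and algebra, not
robustness to those artefacts.

One seed fully determines all outputs; per-stage child seeds are spawned
from it (`numpy.random.SeedSequence`) so toggling pipeline stages does not
shift the streams of other stages.

## Differential testing

Counts are modelled NB with mean `s_j · μ_c(i)` (sample size factor times
condition mean) and variance `m + α_i m²`.

- **Size factors**: median-of-ratios over features positive in all
  samples, rescaled to geometric mean exactly 1.
- **Dispersion**: per-feature method of moments on normalized counts,
  pooling within-condition residual variance: `α̂ = max(ε, (s² − m̄)/m̄²)`
  with ε = 1e-4, then shrunk halfway toward the across-feature mean of the
  raw estimates.  This is a deliberately simple, testable estimator rather
  than an empirical-Bayes fit; its bias at 3 replicates is the main driver
  of the Wald test's mild anticonservativeness (~0.06 observed type-I at
  nominal 0.05, within the accepted (0.03, 0.08) band).
- **Wald test**: condition means by NB maximum likelihood at fixed α̂
  (damped Newton on the score; with equal size factors the MLE equals the
  sample mean for any α).  `se(log2FC)` from the observed Fisher
  information of log μ per group; two-sided p from the standard normal (no
  small-sample t correction, matching large-sample convention).  Features
  with all-zero counts in both groups are retained with `log2FC = 0, p =
  1` and an `untestable` flag so row alignment survives into clustering;
  a group that is all-zero on one side only gets a half-count floor
  (0.5/Σs_j) for a finite estimate with an appropriately huge SE.
- **Multiple testing**: Benjamini–Hochberg step-up (statsmodels), verified
  against a brute-force implementation of the definition.
- **Expressed filter**: features enter the testable universe when their
  mean normalized count over all samples is ≥ 1 (config knob
  `min_base_mean`; no published threshold exists, this is the package's
  documented choice).
- **Significant set**: defined by the treated-vs-untreated contrast (MET
  vs NT) at FDR ≤ 0.05.  Both contrasts' tables are always computed; the
  union of the two lists is available
  (`significance_contrasts=None`) but is not the default because a union
  of two FDR-controlled lists no longer controls the FDR of the combined
  list — on the synthetic fixture it roughly doubled the realized
  false-positive fraction of the clustered set.

The variance-stabilizing transform feeding clustering is
`log2(count/s_j + c)` with c = 1: a shifted log, documented as an
approximation to regularized-log shrinkage.  Clustering consumes
per-feature z-scores, so the residual mean-variance trend the shifted log
leaves behind is largely removed by the standardization.

## Response clustering and AMPK-dependence labels

Significant features are z-scored across samples (sample sd, ddof 1;
zero-variance features are flagged and excluded), clustered by
agglomerative hierarchical clustering (complete linkage, Euclidean
distance — the defaults of the classic `hclust` workflow; both exposed in
config), and the tree is cut into K groups (10 is the gene-profile
convention, 4 the peak-profile one; the cut count is a parameter, not
estimated).  Labels are assigned at cluster level from the cluster's mean
standardized profile and inherited by members:

- direction: sign of μ_MET − μ_NT, AMBIGUOUS if |μ_MET − μ_NT| < δ
  (default δ = 0.5 standardized units);
- dependence: reversion ratio ρ = (μ_MET − μ_METCC)/(μ_MET − μ_NT);
  dependent iff ρ ≥ 0.5.

ρ is invariant to shifting all three means and to positive scaling; the δ
gate is on the data scale, so it scales with the data.  The 0.5 defaults
quantify "greatly reduced" / "remains elevated", which have no published
numeric definition; both are config.  Ties in the linkage are resolved by
scipy's deterministic ordering, so a fixed input order gives a fixed
partition, and permuting feature order permutes labels consistently.

## Interval algebra and metaprofiles

Coordinates are 0-based half-open (BED) throughout.  Merge unions
overlapping or bookended intervals (gap ≤ `max_gap`, default 0, meaning
touching intervals merge — the behaviour of the standard merge tool);
intersection is a sweep over start-sorted intervals with an end-ordered
active heap, reporting pairs with ≥ `min_overlap` shared bases (default
1).  The Venn partition labels each interval of the merged union of 2–3
named sets by which inputs overlap it; counts are reported per label
combination on that union space (one documented convention; reciprocal
per-peak overlap would give different counts).  Promoters are strand-aware
windows [TSS − upstream, TSS + downstream) for `+` genes, mirrored for
`−`, clipped at 0; defaults 1000/500 bases are a documented choice, as no
published promoter definition exists for this workflow.

TSS metaprofiles average per-base bedGraph coverage in bins of `binsize`
across [TSS − window, TSS + window) (defaults ±2000/50), reversing the
base vector for minus-strand genes so "downstream of the TSS" always plots
right of centre; sites whose window leaves the contig are excluded and
counted.  All of merge/intersect/partition are tested against brute-force
base-occupancy oracles on random instances.

## Permutation enrichment

The observed statistic is the fraction of query peaks overlapping the
target region set by ≥ 1 base (fraction-of-query-peaks; the statistic
choice is config-visible in the result object).  The null resamples the
annotation *set*: |foreground| genes drawn without replacement from the
expressed-gene background (or |designated| peaks from the reference peak
universe), n_perm = 2000 times, recomputing the fraction.  Coordinate
shuffling along the genome is deliberately not implemented — the null of
interest is "a random gene set of this size", not "a random genomic
position".  Empirical p uses the add-one rule, is bounded below by
1/(n_perm + 1), and the test direction (enrichment or depletion) is
declared a priori.  The implementation is validated against exhaustive
enumeration on a 6-gene universe, a uniformity check of p over replicate
null simulations, and a power check at a planted two-fold enrichment.

## cis-eQTL meta-analysis

Per cohort, OLS of expression on intercept + dosage + covariates after
listwise deletion, with t = β̂/se on the dosage term and residual df =
n − #covariates − 2.  Rank-deficient or zero-residual fits are flagged
degenerate and excluded from combination.  Cohorts are combined by the
sample-size-weighted statistic t_meta = (Σwᵢtᵢ)/√(Σwᵢ²) with
wᵢ = √(nᵢ − #covariatesᵢ − 1), referred to the standard normal,
two-sided; p-values are floored at the smallest positive double rather
than underflowing to 0.  Per-study t's are treated as asymptotically
normal when combined; a per-study p, if wanted, should use the t
distribution with the study's df — the distinction only matters for small
cohorts.  Candidate pairs keep variants within [gene start − flank, gene
end + flank], inclusive, flank 100 kb.  No heterogeneity statistic is
computed.  With the default cohort sizes the combined statistic is
well calibrated (observed type-I ≈ 0.05 at 500 null pairs, KS distance to
N(0,1) < 0.07), and flipping dosage coding (2 − g) in all cohorts negates
t_meta to floating-point precision.

## Problem sizes in the test suite and acceptance script

The bundled checks run at sizes a laptop handles in seconds, chosen as the
smallest scales at which the statistical assertions are stable: 1,000
genes for the clustering fixture, 2,000 features for the DE null, 500
variant–gene pairs for the meta null, 100–500 replicate runs for
permutation power/calibration, and hundreds of random instances for the
interval oracles.

## Known limitations

- The dispersion estimator is method-of-moments with fixed-weight
  shrinkage, not an empirical-Bayes trend fit; at 2–3 replicates the Wald
  test runs slightly anticonservative (~0.06 at nominal 0.05).
- The shifted-log transform does not shrink low-count fold changes the way
  the full regularized-log estimator does; it is adequate here only
  because profiles are re-standardized before clustering.
- Cluster count K is supplied, not selected; no gap statistic or similar.
- The Venn partition counts merged-union intervals, which need not match
  per-peak reciprocal-overlap counts when peaks chain across conditions.
- Allele harmonization, imputation quality weights and cross-cohort probe
  mapping are out of scope for the eQTL stage; dosages are assumed
  pre-oriented to the same allele.
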