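# metresponse

Analysis pipeline for three-condition drug-response genomics in the liver:
primary hepatocytes treated with **vehicle control (NT)**, **metformin
(MET)**, or **metformin plus an AMPK inhibitor (METCC)**.  The third arm
separates responses that require AMP-activated protein kinase (AMPK)
signalling from those that do not: an **AMPK-dependent** gene or regulatory
element changes under metformin and reverts toward baseline when the
inhibitor is co-administered, while an **AMPK-independent** response
persists.

The package covers every stage of such a study on count and interval data,
and ships a synthetic-data generator that plants known effects so each
stage is verifiable end to end without external downloads:

- **Differential testing** (`metresponse.detest`) — median-of-ratios size
  factors; per-feature NB dispersion `α` (method of moments, shrunk halfway
  to the across-feature mean, floored at 1e-4); per-contrast Wald test on
  `log2(μ̂_cond/μ̂_ref)` from NB maximum-likelihood condition means at fixed
  `α` (variance `m + αm²`); Benjamini–Hochberg FDR.  The same engine runs
  on gene counts and on histone-mark peak counts.
- **Response clustering** (`metresponse.clustering`) — per-feature z-scores
  of the variance-stabilized matrix, complete-linkage hierarchical
  clustering cut into K groups, and a four-way label per cluster from the
  reversion ratio ρ = (μ_MET − μ_METCC)/(μ_MET − μ_NT): dependent if
  ρ ≥ 0.5, up/down by the sign of μ_MET − μ_NT.
- **Interval algebra** (`metresponse.intervals`) — BED-convention (0-based,
  half-open) merge with bookend semantics, sweep-line intersection,
  two/three-set Venn partition on the merged union space, strand-aware
  promoter windows, and TSS metaprofiles from bedGraph coverage.
- **Permutation enrichment** (`metresponse.enrichment`) — overlap of a peak
  set with promoters of a gene set (or with a designated peak subset)
  against a null that resamples the gene/peak *set* from its background
  universe; add-one empirical p-values, n = 2000 permutations by default.
- **cis-eQTL meta-analysis** (`metresponse.eqtl`) — per-cohort OLS of
  expression on intercept + dosage + covariates within a ±100 kb cis
  window, combined across cohorts as

      t_meta = (Σᵢ wᵢ tᵢ) / √(Σᵢ wᵢ²),   wᵢ = √(nᵢ − #covariatesᵢ − 1)

  with two-sided normal p-values.

## Worked example

Simulate the default study (1,000 genes, triplicate conditions, planted
response patterns at |log2FC| = 2), test, cluster and classify:

```python
import metresponse as mr

cfg = mr.SimulationConfig(seed=1)
counts, design, truth = mr.simulate_count_experiment(cfg)
tester = mr.NBDifferentialTester().fit(counts, design)
print(f"significant features (FDR<=0.05): {tester.significant_.sum()} / {len(counts)}")

clusterer = mr.ResponseClusterer(n_clusters=4).fit(
    tester.transform(counts), design, features=tester.significant_features_)
print(clusterer.summary().round(2).to_string())

planted = truth.features.loc[clusterer.feature_labels_.index, "pattern"]
print(f"planted-label agreement: {(clusterer.feature_labels_ == planted).mean():.3f}")
```

prints

```
significant features (FDR<=0.05): 323 / 1000
         size  mu_NT  mu_MET  mu_METCC       response_label
cluster
1          64   1.21   -0.64     -0.57  MET_DOWN_AMPK_INDEP
2          55   0.67   -1.18      0.52    MET_DOWN_AMPK_DEP
3          54  -1.25    0.53      0.72    MET_UP_AMPK_INDEP
4         150  -0.64    1.24     -0.60      MET_UP_AMPK_DEP
planted-label agreement: 0.913
```

Each cluster's mean standardized profile (μ_NT, μ_MET, μ_METCC) drives its
label: cluster 2 drops under metformin and reverts under the inhibitor
(AMPK-dependent decrease), cluster 3 rises and stays up (AMPK-independent
increase).  91% of the significant features inherit exactly the response
pattern that was planted for them; the shortfall is dominated by
false-positive null features, consistent with the 5% FDR target.

The same stages are available from the shell:

```bash
metresponse simulate --seed 1 --outdir run/inputs
metresponse de --counts run/inputs/counts.tsv --samples run/inputs/samples.csv --out run/de.tsv
metresponse run-all --seed 1 --outdir run   # everything, one manifest
```

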