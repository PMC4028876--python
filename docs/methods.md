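# Methods

## Model

Let each individual be genotyped at *q* biallelic SNPs with alleles coded
1/2, and let a haplotype be the ordered allele vector across the q sites
(rendered `1-2-…`). With p + 1 distinct observed haplotypes and the most
common one, h₀, taken as reference, the combined analysis is the logistic
model

    logit P(y_ij = 1 | H_ij) = α + H_ij′ β ,

where H_ij is the p-vector of *haplotype weighted counts* of row (i, j)
and β the log haplotype odds ratios (HOR) versus h₀. Rows come from two
sources. Each of n₁ trios contributes two rows: the affected child as a
case (y = 1) and a pseudo-control (y = 0) carrying the two parental
haplotypes *not* transmitted to the child (Falk–Rubenstein construction).
Each of n₂ cases and n₃ controls contributes one row, so N = 2n₁ + n₂ + n₃.

### Weighted counts

A weighted count is the posterior expectation of the number of copies
(0, 1, 2) of a haplotype carried by an individual, taken over all
genotype-compatible diplotypes weighted by Hardy–Weinberg probabilities
at the estimated frequencies. Rows therefore always sum to 2, and are
integer exactly when the genotype has at most one heterozygous site.
We use the full posterior expectation (expectation substitution), not the
single most likely phase reconstruction; the difference matters only for
multi-heterozygous genotypes.

Frequencies are estimated separately per source:

* **Unrelated samples** — the classical multinomial EM under HWE.
  Deduplicated genotype classes make the E-step a vectorized gather, so
  cohorts of thousands phase in milliseconds at small q.
* **Trios** — EM over all (father phase, mother phase, transmission)
  configurations consistent with the three genotypes, the four parental
  haplotypes i.i.d. from the frequency vector (random mating). Each trio
  contributes four parental slots to the M-step. Ascertainment on the
  affected child is ignored in frequency estimation, as is standard for
  trio phasing.

Both EMs initialize deterministically at the product of marginal allele
frequencies and stop when the observed-data log-likelihood increment
falls below 1e-8 (max 1000 iterations); non-convergence is flagged, never
silent. The log-likelihood trace is retained and is non-decreasing.
Haplotypes unobserved in one source keep a coordinate with frequency 0 so
that both sources share one index space (the sorted union of supports).

### Fitting and tests

The GLM is fitted by Newton/IRLS (statsmodels `Logit`). Weighted counts
enter as **fixed** covariates: phasing uncertainty is not propagated into
the standard errors. This is intrinsic to the two-stage expectation-
substitution design and slightly understates variance for highly
ambiguous genotypes. Haplotype-specific tests are two-sided Wald tests;
confidence intervals are z-based on the log-odds scale (default level
0.95). The global test is the likelihood-ratio chi-square against the
intercept-only model on p degrees of freedom; a multivariate Wald variant
is available (`global_test="wald"`). Design columns whose pooled
frequency is numerically zero (< 1e-8) are dropped — EM supports can
carry haplotypes at ~1e-13 mass whose all-but-zero columns only corrupt
the Hessian — and an optional `rare_threshold` pools genuinely rare
haplotypes into one column. Separation or a singular/indefinite observed
information marks the fit non-converged; the replicate harness excludes
and counts such fits.

For family-only data the matched-pair conditional-logistic model (CLG) is
provided: the conditional likelihood of each case/pseudo-control pair
reduces to a no-intercept logistic model on the within-pair count
difference, and uninformative (zero-difference) columns are dropped.

### Combinability (stratification detection)

The mean weighted-count vector of a source divided by two estimates that
source's haplotype frequencies, so a one-way MANOVA of rows on source
tests frequency equality between trios and case-control samples. With
two groups every classical MANOVA statistic is a function of Hotelling's
T², and the F approximation for Pillai's trace (the default; Wilks'
lambda by flag) is exact: F = (N−p−1)/p · V/(1−V) on (p, N−p−1) df.
Per-haplotype one-way ANOVA F tests accompany the overall test. All
pseudo-individual rows enter (trio cases + pseudo-controls vs unrelated
cases + controls), without subsetting by phenotype. A rejection means
"do not pool the sources directly"; it cannot distinguish confounding by
stratification from true effect heterogeneity.

**Known miscalibration.** The F reference distribution assumes
independent rows. Weighted-count rows are not exchangeable-independent:
double-heterozygotes share one EM-derived weight, case/pseudo-control
rows of a phase-ambiguous trio share a posterior, and the case-control
generator re-pairs haplotypes from finite status pools. Measured under a
homogeneous (no-stratification) simulation at n₁=n₂=n₃=100 this inflates
the variance of the source-mean difference by ≈ 1.2× and the rejection
rate at the 5% level to ≈ 0.08–0.11 per haplotype and ≈ 0.15 for the
overall MANOVA. The tests are therefore mildly anti-conservative and
should be read as screening indicators. A label-permutation test on the
fixed count matrix is exactly calibrated (this is what the unit tests
verify); the F forms are kept because they are the published procedure.

### M-HGLM (stratification correction)

Pipeline: column-standardize the unrelated samples' genotype matrix
(mean 0, sd 1 with the n−1 denominator; constant columns to 0) → cluster
on Euclidean distance with Ward's method (Ward.D2 dialect: each merge
minimizes the increase in total within-cluster SSE; deterministic) or
K-means (10 seeded restarts, best inertia) into K user-chosen clusters
(default 2, matching the two-subpopulation admixture setting) →
re-estimate frequencies and weighted counts within each cluster → stack
with the trio rows over the union space → refit. Trios are never
clustered; the within-family pseudo-control contrast is already immune to
stratification.

The refit includes **cluster main effects**: one indicator column per
cluster beyond the first (trio rows share the baseline with cluster 1),
so inferred-subgroup differences in baseline disease odds are absorbed —
the standard stratified-analysis remedy. The global haplotype test then
compares against the reduced model that keeps the cluster terms, so its
degrees of freedom remain p. With K = 1 the design is bit-identical to
the unmodified combined fit. We add the indicator columns because
re-estimating weighted counts within clusters alone cannot shift the
unambiguous (integer) rows at all — for 2-SNP data K-means places all
double-heterozygotes in a single cluster, making the cluster-wise design
an almost-identical perturbation of the uncorrected one — so without the
indicators the "corrected" fit inherits the uncorrected false-positive
rate essentially unchanged (verified numerically). Even with the
indicators the correction is partial when clusters are inferred from
very few markers (see Limitations).

## Simulation design

The generator's defaults are the study conditions the package is
validated against.

* **2-SNP pool.** 20,000 haplotype sequences with frequencies
  (0.5, 0.1, 0.3, 0.1) over 1-1/1-2/2-1/2-2; reference 1-1. HOR vectors:
  null (1, 1, 1); mild (1.207, 1.421, 1.525); moderate (1, 2.067, 2.067).
* **5-SNP pool.** 100,000 sequences over six haplotypes with frequencies
  (0.264, 0.169, 0.067, 0.050, 0.212, 0.237) — printed values sum to
  0.999 and are renormalized — reference 1-2-1-2-2 and HORs
  (1.467, 3.811, 1.528, 1.309, 1.501) for the other five.
* **Intercept calibration.** α solves
  Σ_d P_HWE(d)·expit(α + x(d)′β) = 0.06 by bisection (achieved prevalence
  within 1e-6; the null-model solution is logit(0.06) ≈ −2.7515), keeping
  disease rates in the 5–7% band for every model.
* **Case-control data** follow a two-step pool mechanism: sequences are
  paired into individuals, affection is assigned by the logistic model on
  haplotype dosages, haplotypes are split into case and control pools by
  their carrier's status, and each output case (control) draws two
  haplotypes from the case (control) pool (with replacement). This
  induces HWE within each pool.
* **Trios.** Ascertained on an affected child: the child's diplotype is
  generated first from the case diplotype distribution, proportional to
  f(h₁)f(h₂)·expit(α + β_{h₁} + β_{h₂}), and each parent is completed
  with one untransmitted haplotype drawn from the population frequencies
  (random mating). Under the null all pairs are equally likely and
  transmission is symmetric. Construction guarantees Mendelian
  consistency.
* **Admixture scenarios.** Two subpopulations: A with frequencies
  (0.5, 0.1, 0.3, 0.1) and prevalence 7%, B with (0.4, 0.3, 0.15, 0.15)
  and prevalence 18%; no within-subpopulation haplotype association
  (all HOR = 1). A pool of 10,000 individuals is drawn from the 50/50
  mixture (70/30 also supported), each with both haplotypes from its own
  subpopulation and affection Bernoulli at its subpopulation's
  prevalence; n₂ cases and n₃ controls are sampled from the affected and
  unaffected pool members without replacement. By Bayes' rule cases are
  72% subpopulation B and controls 47%. Scenario 1 draws trios from
  subpopulation B only; scenario 2 draws whole trio families from the
  admixture. Truth records retain each sample's subpopulation and
  diplotype.
* **Seeding.** Replicate r of a campaign uses base_seed + r; one
  `numpy.random.Generator` carries all randomness within a replicate, so
  campaigns are bit-reproducible.

The replicate harness (`evaluation`) runs population-only, family-only
and combined analyses through one code path differing only in the rows
supplied, records per-replicate p-values/HORs/CIs, and aggregates FPR or
power (rejection fraction at 0.05 among converged replicates), bias and
MSE of the HOR on the odds-ratio scale (log scale by flag), and 95% CI
coverage. `scripts/acceptance.py` runs the full campaigns at 1000
replicates; the test suite uses 100–400 replicate smoke versions of the
same cells with Monte-Carlo-widened tolerance bands to stay fast.

## What the simulations do and do not establish

The synthetic data match the published study conditions but are idealized:
complete genotypes, exactly two or five SNPs, known trio structure, no
genotyping error, no linkage-disequilibrium decay (haplotypes are drawn
directly from a fixed pool), and admixture with exactly two source
populations. Passing tests show the estimators and tests behave
correctly under these conditions; they do not establish robustness to
missingness, larger pedigrees, or many-marker haplotypes (the EM here
enumerates diplotypes, which is exponential in the number of
heterozygous sites and intended for small q).

Under these mechanisms the package reproduces the published
no-stratification results closely (null FPRs ≈ 0.05, mild-model combined
overall power ≈ 50%, moderate-model ≈ 99%, 5-SNP strong-haplotype power
≈ 100%). The admixture-scenario *directions* also reproduce (combinability
tests have high power in scenario 1 and near-null behaviour in scenario
2; the uncorrected combined fit is anti-conservative; cluster correction
reduces the inflation), but the published *magnitudes* of the
uncorrected-fit inflation do not follow from the stated generating
mechanism: with prevalences 7%/18% under 50/50 mixing, the case-control
frequency gap is 0.25·(f_A − f_B) per haplotype, which bounds the
spurious Wald statistics far below the published small-sample rates, and
implies inflation that *grows* with sample size rather than shrinking.
The package reports what the stated mechanism actually produces (overall
uncorrected-test rejection ≈ 0.10 at n₁ = n₂ = n₃ = 100, growing to
≈ 0.88 at n₁ = 500, n₂ = n₃ = 1000, at 1000 replicates), and the
corresponding acceptance checks are expected to disagree with the
published table values.

## Limitations

* Phasing uncertainty is not propagated into standard errors (two-stage
  design); SEs are slightly optimistic for multi-heterozygous genotypes.
* Case and pseudo-control rows of one trio are treated as independent in
  the GLM likelihood; the CLG comparator provides the matched analysis.
* The combinability F tests are mildly anti-conservative (above).
* Cluster correction with K inferred from very few SNPs is partial:
  with 2 SNPs the K-means misassignment rate versus the true
  subpopulation is ≈ 40–47%, and cluster main effects can only absorb
  what the clusters capture.
* Missing genotypes, half-calls, multi-allelic markers, sex chromosomes,
  covariates, quantitative traits and pedigrees beyond trios are out of
  scope.
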