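# Methods

## The screen

The screen targets CpG sites whose methylation acquires a *genetic* signal
under drug treatment. Its premise: if a transcription-factor binding site
harbours a SNP and the drug changes the activity of proteins binding
there, the SNP's alleles differentiate expression — and hence local
methylation — only under treatment. An active genotype effect is a
variance component, so it simultaneously raises the trait's variance and
the resemblance of relatives. The screen therefore looks for sites that
are upper-tail outliers of **both** the post-treatment variability (SD)
and familiality (sibling Spearman correlation, *scor*) distributions while
being outliers of **neither** pre-treatment distribution.

Key estimation choices:

- **SD** is the sample standard deviation (n−1 denominator) over all
  phase individuals, relatives included, with no family adjustment. Every
  site is estimated on the same sample and only ranks are consumed, so the
  (site-constant) efficiency loss from non-independence cancels.
- **scor** uses Spearman rather than Pearson correlation because beta
  values are bounded and non-normal; rank statistics are invariant to any
  monotone rescaling of the measurement. Pair members are ordered by birth
  order (ties and missing birth orders broken by individual id) so the
  correlation is well defined without double-counting pairs. All distinct
  full-sib pairs contribute (a sibship of k gives k(k−1)/2 pairs); a
  `one_pair_per_sibship` switch keeps only the two earliest-born for
  sensitivity analyses. Sites with fewer than `min_pairs` (default 10)
  complete pairs are not estimated.
- 2·scor is reported as an upper bound on h², clipped to [0, 1]; shared
  sibling environment inflates it, which is why it is a bound.
- **Ranks** are descending (1 = largest), ties broken by site id, missing
  last — every ranking is a permutation, so a tail fraction f selects
  exactly `round(f·N)` sites (450 of 450,000 at the default 0.1%). If the
  candidate set is empty the screen retries at 0.5% and then 1%,
  recording the level that produced candidates.
- The analysis runs on the full pre- and post-treatment samples by
  default (maximum power for each phase's estimates);
  `sample_mode="common"` restricts both phases to the shared individuals
  and pairs for the consistent-sample variant.

## The cis-meQTL mixed model

For each candidate site, methylation y over n pedigree members is modelled
as y ~ N(Xβ, σ²_g·R + σ²_e·I) with R = 2Φ, the expected additive
relatedness from the pedigree (tabular kinship recursion; any externally
estimated PSD relatedness matrix is accepted in its place). With
R = U S Uᵀ computed once, the rotated model has diagonal covariance
σ²_g(S + δI), δ = σ²_e/σ²_g, so for each δ the GLS fixed effects and the
profiled σ²_g are closed-form and the log-likelihood costs O(n). δ is
maximised on a 100-point log grid spanning 1e−5…1e5 (the endpoints encode
the σ²_g→0 and σ²_e→0 limits as finite caps) refined by bounded Brent
search. ML is the default; REML is a flag.

Each window SNP (±1 Mb of the CpG, closed interval; MAF strictly > 1%;
missing dosages mean-imputed per SNP) is appended to the covariates and
the fixed effects re-estimated *at the null δ̂* — one weighted solve per
SNP, the standard acceleration that makes large scans tractable
(`refit_per_snp` re-optimises the variance components per SNP for small
problems). The Wald statistic β/se is referred to the standard normal
under ML, and to Student-t with the residual degrees of freedom under
REML, which makes the test collapse exactly onto the classical regression
t-test when R = I. p-values are reported raw; a Bonferroni-within-window
column is optional. The lead SNP per site is the minimum p, ties broken by
genomic position. No covariates are included by default; a covariate table
(e.g. age, sex) can be supplied.

Null calibration was checked by simulation: 2,000 pedigree-structured
traits (σ²_g = σ²_e = 0.5, 50 sib-pair families, n = 200) tested against
permuted SNPs give a rejection rate of ≈0.05 at α = 0.05 and a
Kolmogorov–Smirnov distance from uniformity of ≈0.013
(`methscreen.experiments.lmm_null_calibration`).

## The synthetic-data generator

`methscreen.simulate` generates the study the screen assumes. Latent
trait, per individual i, site j, phase:

```
z_ij = μ_j + β_phase,j·(d_ij − d̄_j) + a_ij + c_fj + 1[post]·batch_shift + e_ij
beta_ij = logistic(z_ij)
```

- μ_j ~ N(0, mu_sd²), mu_sd = 1.0: site baselines spread over the logistic
  scale so beta means range widely, as on a real array.
- a ~ MVN(0, σ²_a·2Φ) per pedigree and c ~ N(0, σ²_c) shared within a full
  sibship (founders get independent draws of the same variance) are drawn
  **once** and reused in both phases — genetic and shared-environment
  components do not change with treatment. Residuals e ~ N(0, σ²_e) are
  phase-specific. Defaults σ²_a = 0.2, σ²_c = 0.05, σ²_e = 0.75 give unit
  background variance and a null-site sibling correlation of 0.15 on the
  latent scale (Spearman ≈ 0.14), a plausible blood-methylation
  familiality level.
- Site classes: *null* (no SNP effect), *constitutive meQTL*
  (β_pre = β_post), *responsive* (β_pre = 0, β_post > 0 — the
  genotype×treatment effect the screen hunts). The causal dosage is
  mean-centred so μ_j stays the baseline. Default allele effect 4.0 latent
  units with causal MAF in [0.3, 0.5] puts ~87–89% of a responsive site's
  post-treatment latent variance on the SNP: a deliberately strong,
  clearly-detectable planted signal (the drug-response effect size is a
  free parameter with no empirical anchor).
- Genotypes: founder alleles Bernoulli(MAF) under HWE, children receive
  one uniformly chosen allele per parent (gene dropping). Each non-null
  site gets its causal SNP within ±50 kb plus 19 independent decoy SNPs
  (MAF 0.05–0.5) in its ±1 Mb window. Sites are laid out 3 Mb apart so
  windows never overlap. No linkage disequilibrium is modelled.
- batch_shift (default 0.5 latent units) is added to every post-treatment
  value, emulating a batch effect perfectly confounded with treatment —
  the failure mode that motivates the indirect design.
- Post-treatment attrition drops whole pedigrees (default retention 0.73,
  mirroring a 163→119-style loss of sibling pairs) so surviving pairs stay
  intact; the screen consumes pair counts, not individual counts.
- Pedigrees are nuclear families (2 founders + sibship of 1–3 by
  default, expected ≈0.9 all-pairs per pedigree so 182 pedigrees yield
  ≈163 sibling pairs). Extended pedigrees are supported by the kinship
  and LMM code but not generated.

### What the generator does and does not emulate

It reproduces the statistical structure the method relies on: bounded
bimodal-capable beta values, familial correlation through a true
relatedness structure, cis genotype effects with Mendelian transmission,
phase-confounded batch shift, and pair attrition. It does **not** model
probe-specific measurement error, cell-type composition, LD, inbreeding,
or realistic genome-wide SD heterogeneity beyond the baseline spread μ_j.
Passing tests therefore demonstrate correctness of the computations and
adequate power under the planted-effect regime, not performance on real
array data.

### Known limitation: batch shift and bounded-scale SD

A constant latent shift preserves each site's within-phase ordering of
individuals, so sibling Spearman correlations are *exactly* invariant to
the batch shift (asserted to 1e−12), and latent-scale SDs are untouched.
Beta-scale SDs are not: SD(beta) ≈ p(1−p)·σ peaks at a latent baseline of
0, so a 0.5 shift reorders sites whose baselines straddle the peak
(null-site SD rank correlation between shifted and unshifted runs ≈ 0.66;
≈ 0.90 pre vs post without any shift, i.e. sampling noise alone). The
variability half of the screen is therefore genuinely more batch-sensitive
than the familiality half — an inherent property of variability screening
on a bounded scale, not an implementation artefact.

## Validation experiments and problem sizes

`methscreen.experiments` packages the validation studies used by the test
suite and `scripts/acceptance.py`; sizes were chosen to give tight Monte
Carlo error on one core in seconds to a few minutes:

- **Oracle agreement**: sibling Spearman vs a from-scratch average-rank +
  Pearson computation on 1,000 random vectors with and without ties
  (agreement to 1e−12); spectral profiled likelihood vs dense
  multivariate-normal density on n ≤ 60 pedigree fixtures (1e−6); tabular
  kinship vs a 100,000-replicate gene-dropping IBD Monte Carlo on a
  10-member three-generation pedigree (±0.01).
- **Closed forms**: mean null-site sibling Spearman vs
  (6/π)·asin(ρ_latent/2) at 2,000 sib pairs × 200 sites (±0.03); beta-SD
  vs the delta-method prediction p(1−p)·σ at σ = 0.3 and baselines
  μ ∈ {−1, 0, 1}, 3,600 individuals × 40 sites per baseline (within 10%).
- **Recovery**: 10 studies of 5,000 sites, 150 pedigrees (sibships of 2–3,
  30/70 mix), 20 responsive sites, screened at 0.5%: mean recall ≈ 0.87
  with essentially no null-class candidates.
- **Localization**: 50 scans of a 400-individual sib-pair study with one
  causal SNP explaining ~30% of latent variance among 19 decoys: the lead
  SNP is the causal SNP in ≈100% of runs.

## Degenerate inputs and numerical conventions

Pedigree cycles, single-known-parent records and duplicate ids are
rejected at parse time. Non-PSD or asymmetric relatedness matrices, zero-
variance traits, and SNPs monomorphic after imputation raise typed errors;
small negative eigenvalues from round-off are clipped to zero. All
randomness flows through `numpy.random.default_rng(seed)`; identical
configurations produce byte-identical output files (fixed float formats,
sorted orderings). p-values are floored at the smallest positive double so
they remain in (0, 1].
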