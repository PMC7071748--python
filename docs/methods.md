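# Methods

This note documents the statistical procedures implemented in `aspugwas`,
the modeling assumptions behind them, the synthetic-data generator used to
validate them, and the numerical and design choices that were genuinely
open.

## Univariate association and phenotype handling

Each trait is analyzed per analytic subgroup with ordinary least squares
under an additive genetic model: trait on coded-allele dosage plus linear
covariates (a sex indicator, age-like and principal-component-like scores
in the simulated data).  Computation uses the Frisch–Waugh–Lovell
decomposition — trait and all dosage columns are residualized on the
covariate design once, after which every variant's slope, standard error,
and Wald z follow from simple-regression formulas with residual degrees of
freedom `n − p − 2` (intercept, p covariates, dosage).  This is
algebraically identical to the full multiple regression per variant and is
checked against a brute-force normal-equations solve in the tests.

p-values use the normal approximation to the Wald statistic, the behavior
of standard GWAS software at GWAS sample sizes; Student's t is available
via `use_t=True` and matters only at toy n.  A p-value floor of 1e-300
protects downstream log-space work.  Analysis is complete-case per trait:
per-trait sample sizes legitimately differ, and no phenotype imputation is
attempted.  Samples related by family structure are out of scope — the
generator produces unrelated individuals, so OLS rather than GEE is the
correct model for every dataset the package can produce.

Phenotype QC removes trait values more than 4 SD from the trait mean.  The
mean and SD are those of the pooled study population (supplied via
`pooled_trait_stats` across subgroups), not the subgroup, so a value
ordinary within an extreme subgroup can still be excluded; a flag at call
level allows subgroup-specific statistics instead.  Variant inclusion
requires imputation quality ≥ 0.4 and effective heterozygosity
`2·CAF·(1−CAF)·N·quality ≥ 35`; both boundaries are inclusive because the
exclusion rules are stated as strict inequalities ("< 0.4", "< 35").

## Meta-analysis

Fixed-effect inverse-variance weighting: `w_i = 1/se_i²`,
`β̂ = Σw_iβ_i/Σw_i`, `se = (Σw_i)^{-1/2}`, with Cochran's Q
(`Σw_i(β_i − β̂)²` on `k−1` df) reported but never used to filter.  No
random-effects model is offered.  Allele coding is harmonized to the first
contributing study: a coded/other swap negates the effect and reflects the
frequency; complement alleles are treated as strand flips; A/T and C/G
palindromes with CAF in [0.4, 0.6] cannot be resolved and are dropped.
Genomic control reports `λ = median(z²)/0.4549364` plus QQ coordinates; no
λ-based correction or exclusion is applied.

Studies in which a variant is monomorphic (or filtered out) contribute
nothing; a variant with no contributing study gets a missing-z row so the
multi-trait stage can see it was untestable rather than null.

## The adaptive sum-of-powered-scores test

Power family: `SPU(γ) = Σ_k z_k^γ` for γ = 1…8 plus `SPU(∞) = max|z_k|`.
γ = 0 is excluded by default because `SPU(0) ≡ K` for every variant: its
Monte-Carlo p-value is exactly 1 under the tie rule and can never win the
adaptive minimum; `gamma_set` accepts 0 for literal fidelity, with
provably identical results (asserted in the tests).

Null model: `z ~ N_K(0, Σ)` with Σ the correlation of null z-scores
across traits.  Σ̂ is estimated on the z-matrix actually being tested,
from variants with |z| < 2 in every trait (true signals are sparse, so
trimming them leaves the correlation essentially unbiased; the all-variant
fallback is available and the selection is logged).  Pairwise-complete
correlations are repaired to the nearest positive-semidefinite correlation
matrix by eigenvalue clipping when missingness makes that necessary.

Monte-Carlo machinery, with B the reference size:

* observed per-γ p: `(1 + #{null |SPU| ≥ observed |SPU|}) / (B + 1)` —
  absolute values on both sides make odd-γ tests two-sided;
* each null draw's leave-one-out per-γ p: `(1 + #{j≠i: |SPU_j| ≥ |SPU_i|}) / B`,
  computed for all draws at once from descending ranks in `O(B log B)`;
* `p_aSPU = (1 + #{i: min_γ p_iγ ≤ min_γ p_obs,γ}) / (B + 1)`.

These conventions guarantee `p ∈ [1/(1+B), 1]` and
`p_aSPU ≥ min_γ p_obs,γ` (the adaptive p cannot beat its best component).
The rank-based path is validated against an independent `O(B²)` double
loop, exactly, for B ≤ 500.  One reference is drawn per (Σ̂, B, seed) and
shared by all variants; a memory budget refuses references that would not
fit, rather than silently thrashing.

A missing trait z (variant absent or monomorphic in every subgroup
contributing to that trait) is substituted with 0 and counted in a
`MissingTraits` flag: the variant stays testable on the traits where it
was observed — essential for ancestry-specific variants — and the flag
supports sensitivity reruns.  A variant missing in all traits yields no
result, with a log record.

Staged escalation: every variant is evaluated at the smallest B in the
schedule (default 10³, 10⁴, …, B_max) and promoted to the next stage when
`p ≤ 10/B`.  The promotion margin is wide relative to Monte-Carlo noise at
the threshold (~9 SDs), and the two-mode comparison test confirms the
promoted set contains every variant the full-B run calls significant.
The default desk B_max is 10⁶; production-scale analyses use larger
schedules, and the p floor `1/(1+B)` should always be compared to the
significance threshold in use — a threshold below the floor is
unreachable by construction.

## Conditional analysis, loci, generalization

Round 0 scans unconditioned and seeds the lead set with the top significant
variant per fixed 10-Mb tile (anchored at position 1) per chromosome —
tiling is deterministic; a sliding alternative would be equally defensible
but harder to reproduce.  Each later round refits every trait's regression
with all current lead dosages on the tested variant's chromosome as extra
covariates, re-runs meta-analysis and aSPU on the conditioned summaries
(Σ̂ re-estimated from the conditioned z-panel), and promotes the most
significant remaining variant while it stays below the threshold.
Constant or collinear conditioning columns are dropped with a warning, so
conditioning twice on the same lead is a no-op (tested).  Ties in p — which
at finite B happen at the Monte-Carlo floor — break by z-vector squared
magnitude, then position; at production B ties are practically impossible
and the rule is inert.

Signals within 500 kb merge transitively (single-linkage per chromosome)
into loci, so a chain of nearby independent signals reports as one locus
spanning more than 1 Mb, matching how multi-signal regions are described
in practice.  Generalization of a previously reported region requires the
best p within 500 kb of the reported variant to beat 0.05/466 = 1.07E-4,
the Bonferroni bound for the number of previously implicated 1-Mb regions.

## The synthetic-data generator

The generator emulates the features of a multi-ethnic cohort design that
the downstream statistics are sensitive to, with known ground truth:

* **Genotypes**: two haploid alleles per sample drawn by thresholding
  latent Gaussians at each variant's subgroup frequency — Hardy–Weinberg
  by construction.  Local LD comes from an AR(1) autocorrelation `ld_rho`
  among latent variables within blocks of `ld_block_size` variants,
  independent across blocks: adjacent-variant r² is tunable, distant
  variants are exactly independent, which is what the conditioning and
  proxy logic need.  Dosage-scale r² is attenuated relative to the latent
  correlation (binary thresholding loses information), roughly 0.15 at
  latent ρ = 0.6 for common alleles.
* **Imputation uncertainty**: deterministic shrinkage of each dosage
  toward its expectation `2·CAF` in proportion to `1 − quality`.  This
  preserves allele-frequency estimates, reduces per-variant information,
  and keeps the effective-heterozygosity filter exercisable and exactly
  reproducible; it does not mimic the heteroscedastic error of real
  imputation posteriors.
* **Ancestry-specific variants**: a per-subgroup fraction (or an explicit
  assignment) of variants forced monomorphic, dosage constant 0.
* **Phenotypes**: K traits on the standardized scale; each is the sum of
  planted per-allele effects on centered dosages, shared linear covariate
  effects, and a multivariate-normal residual with the configured
  correlation matrix.  The default 7-trait matrix is anchored at the
  strongly coupled HCT–HGB pair (0.94), the near-independent HCT–MCHC
  pair (−0.02), and HGB–RBCC (0.68), with the remaining entries set from
  the physiological coupling of the derived indices and projected to the
  nearest positive-definite correlation matrix (smallest eigenvalue
  7e-4).  Physical units are irrelevant to every downstream statistic, so
  none are simulated.
* **Defaults**: subgroup coded-allele frequencies uniform on (0.05, 0.5),
  imputation quality uniform on (0.7, 1.0), four covariates with effect
  0.1, LD blocks of 10 variants, one chromosome with 5-kb variant
  spacing.  Effect sizes are configuration, not assumption: no particular
  effect-size–frequency relationship is imposed, though configurations in
  the tests plant larger effects at lower frequencies where that matters.

What passing tests on this generator do *not* show: behavior under
realistic human LD (haplotype blocks, hotspots), admixture, relatedness,
genotyping batch effects, non-normal trait distributions, or imputation
error correlated with frequency.  The generator's purpose is to verify the
statistical machinery against known truth, not to imitate any particular
cohort.

## Numerical choices and degenerate inputs

* Monte-Carlo tie rule `(1 + count)/(B + 1)` everywhere: p is never 0.
* Zero-variance dosage among complete cases → record with missing beta/se,
  p = 1, `zero_dosage_variance` flag (never an exception mid-scan).
* A perfect fit (trait duplicating dosage) gives se = 0 and p at the
  1e-300 floor — reported, not flagged, since the dosage varies.
* `genomic_lambda` of all-zero z is 0 by the definition; empty input is an
  error.
* Random-number discipline: a single master seed; subgroup generation,
  covariates/residuals, and the Monte-Carlo reference each use
  deterministic child streams (`SeedSequence` spawning), so identical
  configurations produce byte-identical output files.
* Reported problem sizes in the validation suites — e.g. B = 10⁴
  references, 5000-variant null panels, 80-variant regions with n = 1800 —
  were chosen so that each property has enough resolution to fail
  informatively (type-I error within 3 binomial SEs, recovery across 20
  seeds) while the whole suite stays comfortably interactive.

## Known limitations

* Conditioning requires individual-level dosages; summary-statistic
  conditioning with an external LD reference (COJO-style) is out of scope.
* Fixed-effect meta-analysis only; heterogeneity is reported, never
  modeled.
* The adaptive test's p resolution is bounded by B; claims below the floor
  `1/(1+B)` are impossible, and thresholds must be chosen accordingly.
* Σ̂ estimation assumes sparse true signals; a panel saturated with signal
  would bias the null correlation (the |z| < 2 trimming mitigates but
  cannot eliminate this).
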