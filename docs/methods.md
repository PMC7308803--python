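# Methods

## Scope

The package implements an age-stratified polygenic-risk analysis for a
late-onset disease with a dominant single locus (APOE) whose effect
declines with age: variant QC, LD pruning, polygenic scoring with region
exclusion, APOE diplotype calling, and logistic/Poisson association with
likelihood-ratio comparison — plus a synthetic-cohort generator that
provides the statistical structure these stages assume. Out of scope by
design: genotype imputation, computation of genetic principal components
(PCs are consumed as covariates), sample-level QC (relatedness,
heterozygosity, ancestry), survival/Cox modelling of onset age, haplotype
phase-based LD measures, multi-allelic variants, and binary genotype
container formats (BGEN/PGEN/bed).

## The generative model

**Genotypes.** Haplotypes are binary vectors thresholded from a latent
Gaussian copula. Variants are partitioned into contiguous blocks;
within a block the latent process is AR(1), across blocks independent.
Two details matter:

- *Calibration.* Thresholding attenuates correlation, so the latent AR
  coefficient for each adjacent pair is solved (bisection on the
  monotone map latent-ρ → indicator φ-correlation, evaluated by
  Gauss–Legendre quadrature of the bivariate normal orthant probability)
  so that the realized **genotype** correlation, not the latent one,
  approximates `within_block_r`. Pairs whose margins cannot reach the
  target even at latent ρ ≈ 1 are clamped.
- *Frequencies.* Per-variant allele frequencies are uniform draws from
  `maf_range`, sorted within each block. Tightly linked real variants
  necessarily have similar frequencies; sorting preserves the marginal
  distribution while keeping the correlation target attainable.

The variant map (frequencies, allele labels, positions) is a function of
the seed only, so the discovery and target cohorts share it exactly while
their genotype draws are independent (no sample overlap between cohorts).

**APOE.** rs429358 (chr19:44,908,684, T>C) and rs7412 (chr19:44,908,822,
C>T; GRCh38 coordinates, build configurable — the analysis only uses the
region label) are attached as diplotypes of ε2/ε3/ε4 haplotype draws at
frequencies 0.084/0.779/0.137, which guarantees two-SNP phase consistency:
no simulated genotype pair can imply the ε1 = (C, T) haplotype.

**Phenotype.** Liability = scaled polygenic term (variance `h2_poly`)
+ `β_ε4(age)·d4 + β_ε2·d2` + N(0, 1 − h2_poly) noise; the ε4 effect is a
step function at `age_cutoff` (matching a two-stratum analysis; a
continuous decline is deliberately not the default). Status is a cut at
the empirical (1 − prevalence) liability quantile, so the realized case
fraction matches the configured prevalence by construction.

**Discovery summary statistics.** An independent cohort of `n_discovery`
samples is simulated under the same variant map and architecture; each
variant receives a one-step logistic score test against the intercept-only
null (`β = U/V`, `se = 1/√V`, normal p from `U/√V`). This is fast,
well-calibrated under the null, and produces exactly the kind of noisy
marginal weights a PRS is built from.

**Parents.** Each child haplotype is the transmitted haplotype of one
parent (haplotype 0 paternal, 1 maternal); the parent's second haplotype
is a fresh population draw (copula for the block variants, ε-haplotype for
the APOE SNPs). This yields parent-child dosage correlation ≈ 0.5 per
variant without modelling recombination within blocks. Parental status
comes from the same liability model evaluated at parental ages; parental
age at death is the recorded age shifted by `survival_shift_e4` years per
parental ε4 allele (the shift applies to death ages only).

## Default study conditions

| Parameter | Default | Why |
|---|---|---|
| `prevalence` | 0.10 | lifetime dementia-risk scale; also keeps proxy attenuation near its small-effect value 0.5·(1−q) |
| `beta_e4_young / beta_e4_old` | 0.5 / 0.2 | liability-scale step reproducing the observed stronger-ε4-before-80 pattern |
| `beta_e2` | −0.15 | mildly protective ε2 |
| `h2_poly` | 0.3 | common-variant heritability scale for the polygenic background |
| `n_causal / n_variants` | 100 / 400 | weights are noisy (discovery-estimated), as in practice |
| `within_block_r` | 0.7 | strong enough LD that pruning is consequential |
| `age_distribution` | N(75, 8) | participant ages bracketing the 80-year cutoff |
| `parent_age_distribution` | N(78, 8), clipped at 60 | parental last-recorded/death ages |
| `parent_death_prob` | 0.6 | a majority of parents of elderly participants are deceased |
| `survival_shift_e4` | −1.0 yr/allele | the 12-month earlier death of ε4 carriers the survival tables probe |
| `apoe_freqs` | 0.084/0.779/0.137 | worldwide ε2/ε3/ε4 frequencies |

What the generator deliberately does **not** emulate: realistic human LD
maps and recombination hotspots, population structure (the `pc*` columns
are pure noise stand-ins for covariate plumbing), imputation uncertainty
(INFO is 1.0 for simulated data), X-chromosome inheritance, ascertainment,
or parental-sex effects (the maternal and paternal models are exchangeable
by construction). Passing tests therefore demonstrate the correctness and
calibration of the *analysis machinery* under the stated model — not
robustness to confounding or data pathologies absent from the generator.

## Analysis-side choices

**QC.** Boundary senses follow the conventional quotes exactly: MAF
strictly below 0.01 fails; missingness strictly above the profile maximum
(0.02 array, 0.05 imputed) fails; HWE exact p at or below 1e−6 fails;
INFO at or below 0.4 fails (imputed profile only). The HWE test is the
standard two-sided exact test without mid-p, computed on all samples by
default (a controls-only flag exists). For dosages without genotype
probabilities the hard-call rule takes the implied posterior of the
nearest integer genotype as `1 − 2|d − round(d)|`; calls at or below the
posterior threshold become missing (a no-op for hard-called data). A
variant failing several filters is attributed to each, with a separate
deduplicated total.

**HWE numerics.** Up to 5,000 diploids the conditional distribution of the
heterozygote count is computed in exact integer arithmetic (`comb`-based
weights; the returned float is the correctly rounded rational). Above
that, a log-gamma floating path with `logsumexp` normalization and a
1e−12 relative tie tolerance takes over; the two paths agree to better
than 1e−10 where they overlap.

**Pruning.** Greedy by ascending discovery p (ties broken by chromosome,
position, id — fully deterministic); a candidate is kept iff its r² with
every kept variant on the same chromosome within ±`window_bp` (symmetric
pairwise distance between positions, the standard distance-clumping
reading) is at most `r2_max`. r² is the squared Pearson correlation of
dosage columns over jointly non-missing samples, optionally on a seeded
reference subsample (`ref_n`). Monomorphic columns give r² = 0 with a
warning rather than NaN.

**Scoring.** Plain weighted sum (not divided by allele count —
standardization makes the scale immaterial). Allele orientation is
reconciled per variant (panel counting the discovery "other" allele
contributes `2 − dose`); unresolvable mismatches are dropped, warned
about, and counted. Missing dosages: cohort-mean substitution by default;
an omit-with-per-sample-renormalization policy is selectable. ε2 and ε4
doses enter association as two separate count covariates, never collapsed
into the score: the stratified tables report β_APOE and β_PRS separately,
which is only meaningful if the terms are separate (adding the doses into
the score remains possible by scoring the two SNPs like any others with
region exclusion off). Adjustment is OLS residualization on covariates
with intercept; a rank-deficient design is an error naming the collinear
columns, and a (near-)zero residual SD is flagged rather than silently
producing infinities.

**Association.** GLM fits are IRLS via statsmodels (binomial-logit,
Poisson-log), tolerance 1e−8, 100 iterations; separation is flagged when
any |β| exceeds 30. Wald p-values accompany every coefficient; the LRT
compares joint vs APOE-only per stratum. AUC is the exact normalized
Mann–Whitney U of the linear predictor; for the 0/1/2 parental count the
binarization is "at least one affected parent vs none" (the AUC of a
count outcome is otherwise undefined; the choice is recorded with the
model). Age exactly at the cutoff goes to the upper stratum. Strata with
fewer than 10 outcome events are skipped with a warning. Scores are
pre-adjusted for covariates by default; age and sex can additionally be
included as predictors via the model spec. The 0/1/2 parental count
weights single- and both-parent histories identically (a pure count);
per-parent logistic models are provided alongside.

**Coordinates and formats.** 1-based inclusive coordinates everywhere
internally (VCF convention); BED input (0-based half-open) is converted at
the boundary; chromosome labels are normalized by stripping a leading
`chr`. Readers reject malformed values with line context; writers produce
files their paired readers parse losslessly. VCF parsing uses cyvcf2;
PLINK text dialects (.raw with a sibling .map, .ped/.map) are small
hand-rolled parsers since no maintained text-dialect reader is available
as a dependency.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence checks run exhaustively where cheap (every HWE table up
to 200 diploids; 500 random ≤20-variant panels against a brute-force
pruning oracle). Calibration and parameter-recovery checks use Monte
Carlo at sizes chosen to make their tolerances meaningful: 200 null
replicates of n = 10,000 for GLM calibration; 100 replicates of n = 40,000
(≈20,000 per age stratum) for the ε4 age-reversal recovery; single cohorts
of 50,000 children for proxy attenuation and 25,000 children (50,000
parents) for the survival tables. `scripts/acceptance.py` uses 20,000
case-control and 25,000 proxy participants with a 200-variant map.

## Known limitations

- The ε4-carrier vs ε2-carrier death-age contrast is well powered at these
  sizes, but the child-homozygote stratum contrast (ε4ε4 vs ε2ε2 children)
  rests on the rare ε2ε2 diplotype (frequency ≈ 0.7%), so its gap estimate
  carries a Monte-Carlo SE of roughly half a year at 50,000 parents; the
  tests treat that contrast directionally.
- The one-step score test used for discovery weights is a null
  approximation; for very large effects its β underestimates the full
  logistic MLE. This mimics, rather than distorts, real summary
  statistics, but the weights should not be read as liability-scale
  effects.
- Observed-scale (logistic) coefficients are attenuated relative to
  liability-scale generative values by the threshold transformation;
  parameter-recovery tests therefore compare strata or use
  simulation-derived expectations rather than asserting liability values.
- `.raw` files do not record the non-counted allele; panels read from
  `.raw` carry a placeholder other-allele and are suitable for scoring
  only after orientation has been fixed upstream.
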