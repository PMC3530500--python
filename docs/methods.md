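# Methods

## Models

All tests are covariate-adjusted logistic regressions for binary disease
status fit by maximum likelihood within each study; individuals are never
pooled across studies (study-level estimates are meta-analyzed instead, so
between-study differences in baseline risk and covariate distributions
cannot confound the genetic terms). Study center, when present, enters as
indicator covariates within a study.

For two SNPs with additive dosages G₁, G₂ ∈ [0, 2] and covariates X:

- **Marginal**: logit P(d) = β₀ + βG + δ'X; 1-df Wald on β.
- **ARDI**: logit P(d) = β₀ + β₁G₁ + β₂G₂ + γ̄·c(G₁)c(G₂) + δ'X, where
  c(·) is the carrier score. The single parameter γ̄ is the common
  log-odds deviation shared by all four non-reference genotype-combination
  cells, i.e. the average interaction effect; 1-df Wald. Wald (not LRT) is
  used for all 1-df tests because meta-analysis needs (β̂, SE) pairs.
- **Multiplicative**: interaction covariate G₁·G₂ instead of the carrier
  product. This is the classical log-additive interaction model; it
  implies the double-homozygote cell deviates by 4γ where the
  double-heterozygote deviates by γ.
- **Unrestricted**: 2-df indicator mains per SNP plus four free cell
  parameters γ_jk, j,k ∈ {1,2}; likelihood-ratio chi-square against the
  mains-only model, nominally 4 df. Empty cells drop their γ_jk and reduce
  the df, with the reduction flagged on the estimate.
- **ARDI with unrestricted mains**: the carrier-product interaction on top
  of 2-df indicator mains. Used by the inflation guard (below): when a
  SNP's true main effect is not log-additive, the additive coding leaves a
  residual main effect that loads onto any carrier-product interaction
  term and inflates the interaction test; indicator mains absorb it.

### Carrier score

c(G) is the probability of carrying at least one count allele. With
genotype probabilities it is exactly P(1) + P(2); from a hard call it is
I(G ≥ 1); from a bare dosage it is min(d, 1), which is exact whenever the
minor-homozygote posterior is zero and a bounded approximation otherwise.
The carrier indicator is deliberately asymmetric in the two alleles, so
ARDI is *not* invariant to flipping which allele a SNP counts; the
marginal and multiplicative tests are invariant (their design spans are
unchanged by d → 2−d). Allele harmonization across studies therefore
matters and is done explicitly, never by frequency matching:
strand-ambiguous A/T and C/G SNPs are flagged rather than flipped, because
frequency-based resolution is unreliable as the MAF approaches 0.5.

## Logistic engine

IRLS with step-halving, log-likelihood tolerance 1e-8, at most 100
iterations. Degenerate outcomes, rank-deficient designs, non-positive-
definite information, divergence of any coefficient beyond ±30 on the
logit scale (separation), and iteration exhaustion all return
`converged=False` with a message; downstream code treats such estimates as
missing rather than propagating silent numbers. An optional Firth penalty
(Jeffreys-prior modified score) is available for sparse-cell fits; it is
off by default so the default estimates are plain MLEs.

## Meta-analysis

Fixed effects by inverse-variance weighting: w_i = 1/se_i²,
β̄ = Σw_iβ_i/Σw_i, se = (Σw_i)^(−1/2). Heterogeneity by Cochran's
Q = Σw_i(β_i − β̄)² against chi-square with k−1 df; Q and its p-value are
always computed from the fixed-effect weights, also when random effects
are reported. Random effects by DerSimonian–Laird:
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), re-weighting by 1/(se_i² + τ²).
95% CIs are exp(β̄ ± 1.96·se). Estimates that failed to converge or have
SE > 10 on the log-OR scale (separation artifacts) are excluded with a
logged count. Phase-wise summaries report discovery (phase 1),
replication (phase 2), and combined sets; adenoma studies are displayed
but enter the combined analysis only on request. Imputation quality needs
no extra weighting: dosage uncertainty inflates the per-study SE, which
inverse-variance weighting already downweights (verified by simulation in
the test suite).

## Search strategies

**Known-locus scan.** Each panel locus is tested against every SNP passing
MAF > 0.05 and mean imputation R² > 0.3 (genotyped SNPs count as quality
1; values slightly above 1 from imputation software clamp to 1). Partners
in LD with the locus itself (r² > 0.8) are excluded — an "interaction"
between two copies of the same signal is not meaningful. Phase-1 p < 1e-6
selects pairs for replication; among selected partners in mutual LD only
the most significant is reported.

**Two-stage all-pairs scan.** Stage 1 is the marginal meta-analysis; SNPs
are kept when MAF > 0.05, mean R² > 0.3, and *both* the fixed- and
random-effect meta p are below 1e-4 (requiring both avoids candidates
whose signal is driven by a few studies). Survivors are ranked by p
(ties by chromosome, then position — a deterministic total order) and
greedily LD-pruned: starting from the strongest signal, every later SNP
with r² > 0.8 to the current one is removed, then the sweep moves to the
next survivor. Stage 2 tests all C(n,2) pairs of the pruned panel;
phase-1 p < 5e-5 flags pairs for replication and the Bonferroni threshold
is α/C(n,2) on the combined p. Heterogeneity is reported, not filtered
(an optional minimum-P_het flag exists but is off by default). LD r² is
the squared Pearson correlation of dosages over pooled *control* samples:
controls approximate the source population, whereas case enrichment under
a disease model can distort LD. Replication calls additionally check that
the phase-2 OR lies on the same side of 1 as phase 1.

## Inflation diagnostics

λ = median(χ²)/0.4549 over the 1-df interaction statistics of one locus's
genome-wide scan (or of a pair scan's p-values). λ ≤ 1.05 keeps the
additive-main ARDI; larger λ triggers a rerun of that locus with
unrestricted main effects, reporting both λ values. The 1.05 threshold is
configurable; the boundary is strict (exactly 1.05 keeps additive). QQ
data pair sorted observed −log10 p with uniform plotting quantiles
(i − 0.5)/n. No genomic-control correction is applied to p-values: the
diagnostic drives a recoding, not an adjustment.

## Pattern tables

Tables require discrete genotypes, so dosages are hard-called by rounding.
Crude tables are cross-product odds ratios of each cell against the
double-reference cell with Woolf log-method CIs; cells with a zero count
show counts but no OR. Adjusted tables refit the saturated indicator
logistic model with covariates; with no covariates this reproduces the
crude values exactly (saturated-model identity, verified to 1e-4 in
tests). Stratified views re-baseline each row (or column) at its
reference cell, and crude stratified ORs recombine exactly:
joint(g₁,g₂) = row_main(g₁) × stratified(g₂|g₁). The carrier-collapsed
2×2 view merges heterozygote and minor-homozygote cells of both SNPs and
recomputes from merged counts. Cell-level interaction ORs —
joint/(row_main × col_main) — are reported at full precision but the
reference worked examples compare at 2 decimals because their printed
inputs are 2-decimal roundings.

## Simulator

Genotypes are drawn under HWE ((1−q)², 2q(1−q), q²). LD pairs come from
two-locus haplotypes with positive disequilibrium D chosen so the
population allelic r² hits the target; infeasible targets raise an error
naming the maximum achievable r² for the given MAFs. Disease models are
either a 3×3 relative-risk penetrance table (presets: null,
multiplicative, ardi_carrier, dominant_dominant, recessive_recessive,
threshold, checkerboard — parameterized families covering the qualitative
interaction shapes of interest, with baseline double-reference risk 0.05)
or an explicit logistic model, optionally with non-additive
(per-genotype) main effects for misspecification experiments. Covariates
are standardized age and sex. Case/control quotas are filled by rejection
sampling from the population model — simple and exact at desk scale;
ascertainment only shifts the intercept, so slope parameters including γ̄
remain consistent. Imputation noise degrades a dosage to a target quality
R² as m + R²(d − m) + e with e ~ N(0, R²(1−R²)var(d)): imputed dosages
are posterior means, so both their squared correlation with the truth and
their relative variance equal R². Every stochastic operation takes an
explicit seed; a consortium derives per-study child seeds from a master
seed via `numpy.random.SeedSequence`.

The simulator emulates: multi-study designs with differing intercepts,
HWE genotypes with pairwise LD, configurable two-locus effects,
covariate-disease association, and dosage uncertainty. It does not
emulate genome-scale LD structure, population stratification (PCs are
consumed as covariates, never computed), relatedness, genotyping batch
effects, or missingness patterns — so passing tests demonstrate the
statistical machinery is correct under its stated model, not that every
artifact of real consortium data is handled.

## Validation experiment sizes

The statistical acceptance tests run at desk scale, chosen to keep the
whole suite in a few minutes while leaving the checks well-powered: size
of the three interaction tests over 500 null replicates at n=2000/2000
(MAFs 0.30/0.25) against the exact binomial 99% interval; screening
independence over 3000 null replicates at n=800/800 (|r| < 0.05, noise SD
≈ 0.018); the inflation guard on one het-only-main locus (log-OR 0.5,
MAF 0.3, n=1500/1500) scanned against 2500 null partners (median-based λ
has SD ≈ 2.3/√M, so M=2500 gives SD ≈ 0.05); CI coverage of exp(γ̄)=0.75
over 100 seeds at n=5000/5000.

## Known limitations

- The case-only interaction estimator is deliberately out of scope.
- ARDI's carrier coding makes it sensitive to which allele is counted;
  the convention here is to count the minor/ALT allele consistently across
  studies after harmonization.
- min(d, 1) carrier scores from bare dosages understate carrier
  probability for poorly imputed common variants; genotype probabilities
  are preferred when the source VCF carries GP.
- Greedy LD pruning depends on the p-value ranking; a different ranking
  can keep a different representative of a cluster (the tie-break makes
  this deterministic, not canonical).
- The unrestricted 4-df test needs all nine genotype cells populated;
  with rare variants it silently loses df (flagged on the estimate) and
  power comparisons against 1-df tests should account for that.
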