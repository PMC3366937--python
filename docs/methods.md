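# Methods

hapghost implements the statistical chain needed to discover a
genome-wide-significant *imputed* association and then demonstrate that it is
a ghost: markers that merely tag, through a long-range haplotype, a distant
rare causal variant that the array never typed and the imputation engine
could not recover. This note documents the models, their assumptions, the
tunable parameters, the synthetic-data generator, and the numerical and
design choices.

## Linkage disequilibrium from unphased genotypes

For two biallelic loci the four haplotype frequencies (f_AB, f_Ab, f_aB,
f_ab) are estimated by EM over the double-heterozygote phase ambiguity,
assuming Hardy–Weinberg equilibrium and random mating. Initialization is at
linkage equilibrium (f_AB = p_A p_B); iterations stop when the largest
frequency change falls below `tol = 1e-8` or after `max_iter = 1000`
rounds. The log-likelihood is non-decreasing at every step (a property the
tests assert) and on small tables the solution matches a dense grid search
of the multinomial likelihood. From the fitted frequencies,

- D = f_AB − p_A p_B,
- D′ = D / D_max, with D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
  min(p_A p_B, (1−p_A)(1−p_B)) otherwise; the sign of D′ is reported,
- r² = D² / (p_A(1−p_A) p_B(1−p_B)).

Monomorphic loci are a hard error (LD undefined). Matrix summaries (median,
90th percentile of r²) are computed over the strict upper triangle with
linear interpolation between order statistics.

## Single-SNP association

Case/control status is regressed on allele dosage (0–2 copies of the
counted allele) by maximum-likelihood logistic regression, fitted by
Newton–Raphson/IRLS with step halving (max 100 iterations, tolerance 1e-10
on the deviance, separation flagged when any |β| exceeds 15; the iteration
trace travels with the error). The reported p-value is the likelihood-ratio
test of the dosage term — the convention of dosage-association software —
with the Wald p and the observed-information standard error retained because
inverse-variance meta-analysis consumes (β, se). All p-values are
two-sided. Conditional analyses enter adjustment SNPs (dosages or hard
genotypes, including columns merged from different sources per stratum) as
covariates; a target with R² > 1 − 1e-8 on the adjustment set is a
collinearity error, and constant adjustment columns are dropped.

Genotype-count tables support the Cochran–Armitage trend test with scores
(0, 1, 2) — algebraically the score test of the genotype-scored logistic
model — and the allelic odds ratio from the collapsed 2×2 allele table with
a Woolf (log-scale) confidence interval; a zero cell requires the explicit
continuity-correction flag (0.5 per cell).

## Haplotype inference and haplotype association

Multi-locus haplotype frequencies over k ≤ 12 SNPs are estimated under HWE
by EM over all compatible ordered haplotype pairs per (unique) unphased
genotype row; partially missing sites are marginalized, all-missing samples
are skipped (counted), and haplotypes whose frequency falls below
`prune_threshold = 1e-4` are dropped from the enumeration unless a genotype
row would lose its last compatible pair. The stochastic-EM variant replaces
the E-step by sampling one compatible pair per individual and re-counting;
its point estimate is the mean over post-burn-in iterations (defaults
`n_iter = 500`, `burn_in = 100`, mandatory seed). The reported Monte-Carlo
standard error is the naive iteration sd / √(kept iterations); SEM
iterations are autocorrelated, so tests scale tolerances by the per-iteration
sd rather than this optimistic quantity.

Haplotype effects use expectation-substitution: each individual contributes
the posterior *expected* count E[n_h | genotype] ∈ [0, 2] of every modelled
haplotype, and those expected dosages enter a plain logistic model with the
most frequent haplotype as reference (ties broken lexicographically with a
warning). Haplotypes rarer than `pool_threshold = 0.01` are merged into one
pooled term. The global test is the LRT of all haplotype effects jointly,
with (modelled haplotypes − 1) degrees of freedom. Expectation substitution
slightly attenuates effects relative to a full joint likelihood over phases
when phase uncertainty is substantial; for the nearly phase-resolved systems
modelled here the difference is negligible, and it keeps every fit a plain
logistic regression.

### AIC model search

`aic_scan` fits every SNP subset of size 1–4 in a region (capacity-capped at
`scan_cap = 25` SNPs, ≈ 15 000 models), computes AIC = 2k − 2 logL, rescales
by the minimum over all models, declares models within 2 units equivalent,
and returns the most parsimonious equivalent model (fewest SNPs, then fewest
modelled haplotypes, then leftmost positions). `k` counts **every free
parameter the model estimates**: intercept, covariates, haplotype effects,
and the (active haplotypes − 1) frequency parameters fitted by the EM. The
frequency parameters matter: if only regression coefficients are penalized,
a superset model escapes the 2-unit equivalence band whenever its extra-df
chi-square exceeds 2·df + 2 — roughly a 5% event per 2-SNP superset — and
the parsimony rule loses its selection consistency (measured: the true
singleton wins ~70% of strong-signal replicates instead of ~100%). The
likelihood scored is the disease model; the penalty is the full parameter
count, a deliberately prediction-oriented choice. Models whose fit
degenerates (separation in a rare pooled term, collinearity) are excluded
from the ranking. Covariates are included in every model of a scan, so their
contribution to k cancels in the rescaling.

## Meta-analysis and calibration

Fixed-effect inverse-variance pooling: w_i = 1/se_i², β_c = Σw_iβ_i / Σw_i,
se_c = (Σw_i)^(−1/2), two-sided p from z = β_c/se_c computed in log space so
magnitudes like 1e-13 are exact. Heterogeneity is Cochran's Q with
(studies − 1) df — the standard companion of inverse-variance pooling.
Odds ratios published only as OR [low, high] are pooled by reconstructing
β = ln OR and se = (ln high − ln low)/(2·1.96). Genomic control is
λ = median(χ²₁)/0.454936 (the exact χ²₁ median); QQ payloads pair order
statistics with i/(n+1) expectations and a pointwise Beta(i, n−i+1) band.

The genome-wide threshold 7.4e-9, the suggestive threshold 1e-6, the
imputation-quality filter 0.3 and the conditional-null threshold 0.10 are
single named configuration keys in the pipeline.

## Imputation diagnostics and the tag imputer

Dosage quality is the MACH-style variance ratio r̂² = Var(dose)/(2p̂(1−p̂))
with p̂ = mean(dose)/2 and a population-variance (1/n) denominator, capped
at 1 with the raw value retained. Concordance with truth is the Spearman
correlation (average ranks for ties) plus per-genotype dose quartiles.

`tag_impute` is a deliberately minimal haplotype-conditional imputer: joint
(tag, target) haplotype frequencies are counted from a phased reference
panel, and each study individual receives the HWE posterior expectation of
the target allele count given their unphased tag genotypes. Tag haplotypes
absent from the panel fall back to the panel target frequency with a
pseudo-frequency weight of 0.5/(panel haplotypes), and such fallbacks are
counted. With a small panel the per-haplotype conditional probabilities are
estimated from a handful of chromosomes, which both adds noise to the dose
and *inflates* the variance-ratio quality estimate relative to the true
information content — the same optimism real imputation metrics show for
rare variants.

## The synthetic ghost scenario

`default_ghost_spec()` fixes the study conditions; it is a single object,
not a dial. Core architecture (haplotype classes over 3 tag SNPs and 12
block SNPs, with per-class causal carriage):

| class | tags | block allele | frequency | causal carriage |
|-------|------|--------------|-----------|-----------------|
| GGT   | G,G,T | no  | 0.369 | 0.003 |
| GAT   | G,A,T | no  | 0.282 | 0 |
| GAC   | G,A,C | no  | 0.049 | 0 |
| AGT (risk) | A,G,T | yes | 0.020 | 0.73 |
| AAC   | A,A,C | no  | 0.260 | 0 |
| AAT+block | A,A,T | yes | 0.010 | 0.73 |
| AAT   | A,A,T | no  | 0.010 | 0 |

This gives: causal population allele frequency 0.023; block-SNP frequency
0.030; analytic causal–block r² 0.69; 64% of causal copies on the risk
class; a single common proxy SNP (frequency 0.08, carriage 0.75 given
causal) with analytic r² 0.144 to the causal variant — the "best tag ≈ 0.15"
regime. Causal carriage is *uniform* across the two block-carrying classes
so that conditioning on a block SNP absorbs the haplotype association (the
collapse that unmasks the ghost); the small off-block component on GGT keeps
the causal variant imperfectly tagged. Making the causal variant instead
ride the risk class almost exclusively (carriage 0.9 vs 0.2) concentrates
>80% of causal copies on one haplotype but leaves a residual
haplotype-specific effect after block conditioning, contradicting the
observed collapse; uniform carriage was chosen to reproduce the collapse,
at the price of a 0.64 rather than >0.8 risk-class share.

Geometry follows the motivating locus: causal variant at chr11:46,761,055,
block SNPs spanning 47,373,425–48,064,194 (0.61–1.30 Mb away), scan region
47.30–48.10 Mb. 110 background SNPs (MAF ~ U(0.05, 0.5), fixed catalogue)
carry weak LD from a latent Gaussian AR(1) (adjacent correlation 0.93,
tuned once so the typed-SNP median pairwise r² ≈ 0.10–0.12; the 90th
percentile lands near 0.40).

Disease follows logit P(case) = α + ln(OR)·g_causal with OR = 3.0 and α
solved for a population prevalence of 0.05 (the odds ratio, not the
prevalence, is the recovered invariant; for a rare-ish disease the OR is
insensitive to the prevalence choice). Case/control quotas are filled by
batched rejection sampling with a draw cap. Four pure-noise principal
components exercise the covariate path. One integer seed determines the
full bundle bit-for-bit.

### Observed data

The array carries tags and background only: block SNPs and the causal
variant are withheld. Dosages are generated at a MAF-dependent quality
target q(maf) = 0.97(1 − e^(−maf/0.012)) — rare variants impute worse —
via an allele-copy observation model: each allele is recovered correctly
with probability c = √target, otherwise replaced by a population draw, and
the dose is the posterior mean 2(1−c)p + c(o₁+o₂), whose expected
variance-ratio quality is exactly the target. This model was chosen over
additive Gaussian noise because it reproduces the empirically observed
pairing of variance-ratio quality with rank concordance (quality ≈ 0.27
pairing with Spearman ρ ≈ 0.5) and because it caricatures haplotype-mosaic
imputation. Block SNPs share their allele-recovery events (one uniform draw
per allele across the block, with per-SNP replacement noise): a real engine
reconstructs the shared segment once, so block dose errors are correlated
and conditioning on any one block dose absorbs essentially the whole block
signal. The causal variant's dose comes from `tag_impute` against a
566-haplotype phased panel (a 2010-vintage European reference scale) using
its single weak proxy as tag; measured quality is typically 0.15–0.25
(below the 0.3 filter) with case-only Spearman ρ ≈ 0.40–0.55.

### What the generator does not emulate

No recombination or coalescent history (classes are drawn i.i.d.); no
genotyping error or missingness by default; no population stratification
(the PCs are noise, so covariate adjustment is exercised but never needed);
background LD is first-order stationary rather than block-structured;
imputation is single-target rather than genome-wide HMM. Passing tests
therefore show that the statistical machinery recovers the designed
structure, not that it is robust to every artefact of real array data.

## Pipeline and verdict

`run_ghost_analysis` executes: per-study per-SNP dosage logistic (PCs as
covariates) → fixed-effect meta with the 7.4e-9 threshold and the 0.3
quality filter (both studies must pass) → LD structure of the hit region →
mutual conditional analyses among the hits → exhaustive AIC haplotype scan
of the typed region SNPs → haplotype ORs, crude and block-adjusted →
conditional analysis of the top hit on the candidate culprit (imputed dose;
dose-in-controls/genotype-in-cases merged column; full true genotype) →
culprit quality and concordance. The verdict flag `ghost_signal` is true
when the top hit is not the culprit itself, its combined p is below the
suggestive threshold, the association collapses (p > 0.10) under the
culprit's true genotype, and persists (p < 1e-3) under its imputed dose.
Each stage can be disabled independently; a structured manifest records
stage parameters and runtimes, and a rerun with the same seed and
configuration reproduces every number.

## Numerical and testing choices

- Two-locus EM oracle: a 0.02-step simplex grid (~177k points) of the
  multinomial likelihood; the EM must attain the grid maximum within 1e-6.
- Null calibration of the global haplotype test: 200 replicates at n = 2000;
  the 5% rejection count must fall in the binomial 95% band [4, 16].
- Selection consistency of the scan: 50 replicates, one causal SNP
  (MAF 0.2, OR 2) among 8 background-LD null SNPs at n = 3000.
- Ghost integration: 50 replicates of the two-study design
  (419/1228 + 1500/1200), checking the crude combined p, truth- and
  dose-conditioned p, and culprit quality, each in ≥ 80% of replicates.
  These sizes keep the full suite and the acceptance script at a few
  minutes on one core while leaving comfortable statistical margins.
- Genomic-control λ over the simulated region is intrinsically unstable per
  cohort: the background chain holds only ~8 effectively independent loci,
  so a single-cohort λ swings between ~0.5 and ~2 by chance. The
  calibration test pools background p-values over 30 cohorts; the pipeline
  reports its single-run λ as a descriptive number only.
- Mutual conditionals among block hits are strongly attenuated but not an
  exact null: two noisy doses of the same genotype jointly carry slightly
  more information than either alone (agreement flags correct recovery), a
  second-order effect the tests acknowledge by asserting attenuation by
  many orders of magnitude rather than exact uniformity. Statistically
  duplicate pairs that separate or turn collinear are reported as
  degenerate rather than fitted.

## Known limitations

Haplotype capacity is 2^k enumeration (k ≤ 12; no partition–ligation);
exact logistic regression and Firth correction are out of scope, so
separated fits raise rather than regularize; the SEM Monte-Carlo error
ignores chain autocorrelation; `tag_impute` is a mechanistic stand-in, not
a replacement for HMM imputation engines; and the VCF dialect is limited to
diploid, biallelic GT records.
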