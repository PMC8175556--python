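# Methods

## Statistical model and procedure

The package analyzes a two-group cohort (labels "AAM" vs "EAM" by default;
group 1 is the positive outcome) given a features × samples log-expression
matrix and a per-sample clinical table.

**Baseline comparisons.** Categorical variables are compared with the Pearson
chi-square test of independence without continuity correction
(df = (r−1)(c−1)); sparse 2×2 tables (any expected cell < 5) fall back to the
two-sided Fisher exact test. Continuous variables are summarized as median
(IQR), quartiles by linear interpolation, and compared with the two-sided
Mann-Whitney *U* test: exact enumeration when the combined n ≤ 20 without
ties, otherwise the tie-corrected normal approximation without continuity
correction. Missing values are excluded per variable and the analyzed n is
reported. Percentages round half-even to one decimal.

**Pathway and signature scores.** Genes are z-scored across all samples
(both groups pooled — the only choice that keeps the group contrast
meaningful) with variance denominator n−1; a pathway's activity is the
per-sample mean of z-scores over its genes. Scaling per gene across samples
makes within-set and genome-wide scaling identical. Constant genes scale to
zero with a warning instead of aborting. Signature scores are weighted means
`Σ w x / Σ|w|` with an optional per-gene z-scoring flag; the average genomic
risk is the unweighted mean of per-signature z-scores, since published
prognostic signatures live on incommensurate scales and averaging raw values
would let one signature's units dominate.

**Association scan.** Every feature is fit in the multivariable logistic
model `logit p = β0 + β1·feature + β2·GG + β3·EPE + β4·SVI + β5·LNI` by
Newton/IRLS maximum likelihood (statsmodels, ≤ 100 iterations). GG enters as
a single ordinal covariate (1–5); pT is decomposed into nested binaries
EPE (≥ T3a) and SVI (≥ T3b), with T4 contributing to both; LNI is pN = N1,
and an unassessed pN (NX) counts as node-negative because most of the target
cohort is nodally unstaged. Samples missing any covariate are dropped once
per run so all features see the same n. The per-feature P is the Wald P of
β1 (standard for per-feature scans and matched by the closed-form oracle
tests). Complete separation raised by the optimizer, and converged fits whose
standardized |β| (per predictor SD) exceeds 15, are flagged non-converged;
such features are excluded from the BH family because they contribute no P.
q values are Benjamini–Hochberg step-up over all features with a P, and DE
calls use q < 1e-5 with direction from the sign of β1.

**Drug response.** `DRS_s = Σ Cor·x / Σ Cor` over model genes present in the
matrix, expression unscaled, exactly the signed-sum normalization of the
score's definition. Mixed-sign models can drive the denominator toward zero,
so |Σ Cor| < 1e-9 is an error naming the drug, and an explicit
`abs_normalize=True` mode divides by Σ|Cor| instead. Gene selection for the
models is an input-preparation concern: models arrive with genes and
correlations already chosen, and a fixture generator produces plausible
models (|Cor| ∈ [0.3, 0.9], ~85% sharing one sign).

**Consensus clustering.** For each k, samples are subsampled at 80% for 500
resamples (defaults; configurable), k-means with k-means++ and 10 restarts
runs on z-scored panel genes, and the consensus entry for a pair is its
co-clustering count over its co-subsampling count. Final labels cut an
average-linkage tree of (1 − consensus) at k. k is chosen by minimizing the
proportion of ambiguous clustering (off-diagonal consensus entries strictly
inside (0.1, 0.9)), ties to the smallest k. The immune panel is a required
input; a synthetic 124-gene panel generator matches the size of the panel
the procedure targets.

**qPCR.** ΔCt references the arithmetic mean of the housekeeping Ct values
(equivalent to a geometric mean of linear quantities); relative expression is
2^(−ΔCt); no efficiency correction. Group comparisons use the Mann-Whitney
test plus the fold change of group medians.

## Synthetic cohorts

The generator emulates the cohort the analysis assumes: 596 + 556 samples;
grade group, pT, pN and CAPRA-S drawn per group from the published
baseline-table marginal proportions, with missingness at the table's
per-group rates (pT and CAPRA-S are partially missing; covariates are drawn
independently within group, the simplest structure that still exercises
adjustment); PSA log-normal and age Gaussian with parameters back-solved from
the published medians/IQRs. Expression is per-gene Gaussian on the log scale
(baseline mean 0, default noise SD 1.0 — log-intensity-like behavior with
closed-form effect sizes): planted per-gene effects add δ to group-1 samples,
planted set shifts add a common Δ to a set's genes in group 1, and an
optional confounding map adds level-specific shifts to all genes of samples
carrying a covariate level. A single integer seed drives one PRNG stream;
identical spec + seed reproduces byte-identical files.

What the generator does **not** emulate: probe-level microarray structure,
batch effects, gene–gene correlation beyond planted sets, covariate–covariate
dependence, or heavy-tailed noise. Passing tests therefore demonstrate the
estimators' correctness and calibration under the assumed Gaussian
independence structure, not robustness to real-data artifacts.

## Problem sizes and numerical choices

The test suite and acceptance script run at the study's scale where that is
what is being claimed (n = 596/556 with 2000 genes for calibration and
recovery; 89 drugs × 1152 samples; a 128-sample, 124-gene consensus run with
100 resamples) and at reduced scale for plumbing checks. Tolerances: exact
arithmetic identities at 1e-12; logistic-vs-closed-form at 1e-6; calibration
and recovery at simulation confidence bounds (KS α = 0.01; sensitivity ≥ 90%).
Degenerate inputs are handled explicitly: zero-margin contingency tables,
constant genes/features, models with no overlapping genes, samples missing a
target Ct, and all-identical consensus inputs each either warn-and-continue
or raise a named error as documented on the operation.

The confounded-adjustment scenario uses constructed covariate marginals with
a deliberately large between-group grade imbalance and a monotone
grade-to-expression shift; the published marginals alone induce too small a
confounding signal to make the inflation/correction contrast measurable at
simulation sizes, so this scenario is a designed stress test rather than an
emulation of the study cohort.

## Known limitations

- The logistic scan assumes a linear logit in the feature and ordinal GG;
  no interaction or non-linearity checks.
- BH controls FDR under independence/PRDS; planted-truth simulations here
  have independent genes, the favorable case.
- Consensus clustering reproduces the procedure, not any particular
  published cluster membership; k selection by PAC is one convention among
  several.
- Commercial genomic classifier scores (e.g. metastasis-risk scores) are
  treated as opaque numeric inputs and never recomputed; subtype classifiers
  and enrichment web tools are out of scope.
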