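# Methods

This note documents the models the package implements, the defaults and why,
what the synthetic-data generator does and does not emulate, and the numerical
choices that affect results.

## Morphological concentration-response

Incidence of a dichotomous endpoint across concentrations is modeled as
binomial with the 3-parameter log-logistic mean

    p(d) = g + (1 − g) · expit(a + b·ln d),    p(0) = g,

where `g ∈ [0, 1)` is the background rate, `a` the intercept and `b > 0` the
slope on log-concentration. The control group enters only through `g`; dose 0
is never log-transformed. Parameters maximize the binomial log-likelihood via
L-BFGS-B from 8 deterministic starts on a coarse (g, a, b) grid; the reported
optimum is the best across starts, and the likelihood can only improve over a
flat (intercept-only) model. All-zero or all-one incidence is flagged
non-estimable rather than fitted.

The benchmark concentration at extra risk R solves
`(p(d) − g)/(1 − g) = R`, giving the closed form
`BMC_R = exp((logit(R) − a)/b)`; the default R = 0.20 (BMC₂₀). Extra risk
cancels the background, so the BMC does not depend on `g`. The slope is
constrained positive but not bounded below by 1; a stricter `b ≥ 1`
restriction can be imposed by narrowing the optimizer bounds if a user wants
BMDS-style behavior. BMCs above the top tested concentration are computed but
flagged out-of-range, and summary tables suppress them by default.

Wells from replicate plates are pooled per concentration before fitting.

The time-course analysis tests each (endpoint, concentration, timepoint) cell
against its matched control with the conditional two-sided Fisher exact test
(sum of hypergeometric probabilities ≤ the observed table's, the dominant
convention), then applies Holm's step-down across the whole family of tests in
one analysis. Zero-total cells yield p = 1 with a warning.

## Expression preprocessing

Genes are kept when they have ≥5 reads in ≥2 samples, applied within the
timepoint being analyzed. TMM normalization follows the standard trimmed mean
of M-values: reference = sample whose 75th-percentile count fraction is
closest to the mean of those; M-values trimmed 30% per tail and A-values 5%;
factor = 2^(precision-weighted mean M), rescaled to geometric mean 1. The
implementation reproduces edgeR's `calcNormFactors(method="TMM")` to ~1e-9 on
fixed test matrices. log₂CPM uses a prior count of 0.5 on the TMM-effective
library size. PCA QC is a centered SVD of log₂CPM with variance-explained
ratios.

The differential-expression screen is a negative-binomial Wald test, not a
DESeq2 clone. Per (chemical, timepoint) block: gene-wise method-of-moments
dispersions from full-model (group-mean) residuals with a df correction; a
mean-dispersion trend `a0 + a1/mean` fit by least squares; shrinkage of
log-dispersion toward the trend with a prior weight of 6 pseudo-replicates
against the residual df. Group coefficients are fit by Fisher scoring with
the log effective library size as offset. The Wald statistic is referred to a
t distribution with the block's residual degrees of freedom rather than the
normal — with 4 replicates per group the normal reference is measurably
anti-conservative (empirical type-I ≈ 0.079 vs 0.055–0.065 with the t),
mirroring the small-sample practice of quasi-likelihood NB pipelines. BH
adjustment is applied within each contrast; genes with zero counts in both
groups of a contrast are excluded from it and from the BH denominator.
Validation is by calibration (type-I error) and power on synthetic data;
gene-list parity with DESeq2 is not claimed.

## Gene-level dose-response and BMC

Genes DE at ≥1 concentration enter modeling. Each gene's log₂CPM values are
fit under a homoscedastic Normal likelihood (per-gene variance) to six mean
families following EPA BMDS continuous conventions: Linear, Poly2,
Power (exponent ≥ 1), Exp2, Exp3 (exponent ≥ 1), Exp4; the sign of the
exponential families follows the observed dose trend. Fits profile the
nonlinear parameter: conditional on it the remaining parameters are linear
and solved exactly, so each family reduces to a deterministic grid scan
(24 log-spaced points) plus bounded scalar refinement; Exp3 adds a
coarse-then-refined exponent search. No randomness enters the fits.

AIC = 2(k+1) − 2·lnL with lnL at the MLE variance (RSS/n) and k mean
parameters; the residual SD used for the benchmark response is the
df-corrected `s = sqrt(RSS/(n−k))`. The best model minimizes AIC among
converged fits, ties broken by fewer parameters then a fixed family order.

The BMC is the smallest d > 0 with `|μ(d) − μ(0)| = 1.35·s` — the
1.35-residual-SD convention for the benchmark response; a config switch
substitutes the control-group SD instead. The root is bracketed on a
512-point geometric dose grid and polished with Brent's method; Linear, Power
and Exp2 admit closed forms used as cross-checks (agreement to 1e-9).
Exactly flat fits (s ≤ 1e-9) return no BMC. Multiplying all doses by a
constant multiplies every BMC and CI bound by the same constant.

The 95% CI is a percentile bootstrap (B = 250, fixed seed): residuals are
resampled with replacement within each dose group around the group mean and
rescaled by sqrt(n/(n−1)). The rescaling matters: plain case-resampling
within groups of 4 underestimates the variance by (n−1)/n and gave 79%
empirical coverage at nominal 95%; the rescaled variant gives ~89%, inside
the accepted [88%, 99%] band for Linear-family genes. Only the selected
family is refit per replicate, so the interval reflects parameter uncertainty
but not model-selection uncertainty — see Limitations. If fewer than half the
replicates yield a finite BMC the CI is undefined and the gene fails the
precision filter.

A gene "has a concentration response" when all three published rules hold:
BMC within the tested range, BMCu/BMCl ≤ 40, and best model not Poly2
(non-monotonic). Poly2 fits are computed and flagged rather than dropped
early, and excluded only at this final stage.

## Anchoring, uniqueness, overlaps

Phenotype-associated genes: has-CR genes with BMC ≤ the anchoring
concentration (default 1.33 µM), boundary inclusive. Phenotype-unique genes
additionally exclude any gene with a concentration response (has-CR flag,
regardless of its BMC) in any comparator chemical at the same timepoint.
Multi-way overlaps report all 2^k Venn region counts and per-gene membership
vectors; external DEG tables are joined on lowercase gene symbols with no
ortholog or alias resolution (mismatches are reported, not resolved).

## Enrichment and kappa networks

Term enrichment is the right-tailed hypergeometric test of each GMT term
(intersected with the universe) in the query set, BH-adjusted at 0.05. The
universe is the set of genes passing the low-count filter for that timepoint
— the expressed universe — rather than the whole annotation, the standard
guard against expression-bias inflation. Term similarity is Cohen's kappa on
the two binary membership vectors over the universe; enriched terms are nodes
and edges join pairs with κ ≥ 0.35. Initial functional groups are the
connected components; groups merge (term pairs in lexicographic order, so the
result is deterministic) while two groups share at least 50% of the smaller
group's gene union; each group is labeled by its lowest-p member term.
Raising the kappa threshold can only remove edges; raising the merge
threshold can only increase the number of groups.

## Synthetic-data generator

The generator emulates the study design so that every estimator can be scored
against known truth:

- **Morphology**: per-well Bernoulli draws from the inverted log-logistic
  with the intercept derived from (true BMC₂₀, slope) via the extra-risk
  identity; 12 log-spaced concentrations (0.1–13.3 µM) with 14 wells each and
  24 controls; default endpoints place x-fin at BMC₂₀ = 0.28 µM. Wells are
  independent; plate effects are not modeled.
- **Counts**: negative-binomial (gamma-Poisson) with log-normal baseline
  means (ln-mean 4, ln-SD 2, giving ~7M expected reads per sample),
  dispersion trend α(m) = 0.02 + 1.5/m, library-size factors uniform on
  [0.6, 1.5] (<3-fold), an inter-pool biological SD of 0.05 log₂ units
  (exposed as a parameter since pool-to-pool variance is design-specific),
  and controls shared across chemicals within a timepoint.
- **Responsive genes** (5% for the target chemical, 1% for comparators):
  the mean log₂CPM curve is an exact member of the assigned fitted family,
  with parameters set so the departure from control at the true BMC equals
  1.35 per-sample SDs — the per-sample SD being Monte-Carlo-calibrated by
  pushing NB draws through the same count→log₂CPM transform the analysis
  fits, so the recorded truth lives on exactly the estimated scale. True
  BMCs are log-uniform on (0.1, 10) µM. Exponential families require a
  positive log₂CPM baseline; rising curves that would exceed 10 log₂ units
  at the top dose use the falling branch instead, polynomial-family curves
  are clipped at ±10 log₂ units (binding only above the BMC), and the Exp4
  saturation asymptote is drawn as 2–8× the benchmark response. The manifest
  records the realized family, direction and amplitude per gene.
- **GMT**: null terms drawn uniformly; planted terms draw 80% of members
  from the responsive pool, so enrichment has a known positive control.

Each output file uses its own RNG stream keyed by (seed, file tag), so adding
an output never perturbs the others, and a fixed config is byte-reproducible.

What the generator does not emulate: read-level sequencing artifacts,
mapping, batch effects, plate effects, gene-gene correlation, and annotation
structure beyond flat gene sets. Passing recovery tests on this generator
demonstrates the estimators are correct and calibrated under the stated
noise model, not that real data meet that model.

## Known limitations

- With 4 dose groups and 4 replicates, the BMC of saturating or
  sharply-curved responses (Exp3/Exp4-type) is weakly identified: even an
  oracle fit that knows the true family and starts at the true parameters
  shows ~33–35% median relative error over true BMCs spanning (0.1, 10) µM,
  versus ~16–21% for Linear/Power/Exp2 shapes. End-to-end median recovery
  error across a balanced family mix is therefore ~35–40% at this design,
  improving with replicates or dose resolution, and the BMCu/BMCl ≤ 40 filter
  (not accuracy per se) is what keeps unreliable fits out of downstream sets.
- The bootstrap CI conditions on the selected family; model-selection
  uncertainty is not propagated, so intervals for genes whose AIC choice is
  unstable are optimistic.
- The DE screen is validated by calibration and power, not by parity with
  any particular reference implementation.
- External-list comparison uses exact symbol matching only.
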