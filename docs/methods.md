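# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, what the synthetic
data do and do not emulate, and the numerical details that matter for
reproducing results.

## Data model

A dataset is a samples × metabolites concentration matrix with a
parallel per-cell code layer: `observed`, `fully_missing`, `below_lod`,
`below_lloq`, `above_uloq`, `below_unknown_lod`. Observed cells hold
finite positive concentrations (unitless; consistent within a
metabolite); all other codes hold no number. The distinction drives two
stages: cleaning counts only fully-missing cells as missing, because an
out-of-range cell still says "the value was below/above this limit",
and imputation substitutes each code differently. Batch labels are
namespaced as `study::batch` internally so identical raw labels in two
studies can never merge; batch is thereby nested in study by
construction. Limits live in two tables: batch-specific LODs
(`(batch, metabolite) → value`) and kit-level LLOQ/ULOQ per metabolite.

## Step 1 — cleaning

Order is fixed and replayable from the report: metabolite missingness
filter → sample missingness filter → small-batch exclusion → per-batch
outlier removal. A metabolite is dropped when its fully-missing fraction
strictly exceeds the threshold (default 0.20) in at least one study;
samples symmetrically over the retained metabolites; batches of fewer
than `min_batch_size` (default 10) samples are removed whole, because
batch-wise imputation and normalization need a minimum of information
per batch.

Outlier detection runs per batch on the first two principal components
of the batch's centered, unit-variance matrix. Cells that are not
observed are provisionally filled with the batch median *for scoring
only*; metabolites with no observed value or zero variance in the batch
are ignored there. Sample i is flagged when its Hotelling statistic
T²ᵢ = Σₖ scoreᵢₖ²/λₖ exceeds (1 + expansion)² × T²crit with
T²crit = 2(n−1)/(n−2) · F₁₋α/N_b(2, n−2), i.e. the conventional
two-component T² ellipse at a level Bonferroni-adjusted over the total
number of batches, with both semi-axes inflated by 20% by default.
Batches with fewer than 3 samples are skipped (ellipse undefined) and
recorded. Open choices settled here: the number of ellipse components
(2 — the ellipse is a 2-D construct), the handling of missing cells
inside the scoring PCA (median fill, discarded afterwards), and the
multiplicative reading of the proportional expansion.

## Step 2 — imputation

Per batch: below-LOD → LOD/2; below-LLOQ → LLOQ/2; above-ULOQ → ULOQ;
below an unknown batch LOD → half the study median of that metabolite's
known LODs. Fully missing cells take the batch median of observed values
when the batch's fully-missing fraction for that metabolite is < 50%,
else the study median of the batch medians. "Missing" in the 50% rule
counts fully-missing cells only (a config switch flips this to include
out-of-range cells); the fallback exists so a batch median dominated by
imputed substitutes never propagates. Even-sized medians average the two
central values. The log transform is the natural log; the base only
rescales every downstream linear model uniformly. Observed values pass
through bit-identical, every substitution is recorded, and the whole
step is deterministic and order-invariant.

## Step 3 — PC-PR2

Metabolites are centered and scaled to unit variance before the PCA
(flag `scale=`), because metabolite classes differ by orders of
magnitude and the decomposition should operate on correlation-scale
variation. K is the smallest number of components whose cumulative
explained variance exceeds the threshold (default 0.80). Each
component's scores are regressed on all candidate variables; partial R²
is the relative SSE drop when the variable joins the model holding all
others. For a nested pair (study outer, batch inner), study's partial R²
conditions on everything except study and batch, and batch's conditions
on study plus everything else — the inner variable never claims
variation attributable to the outer. SSEs are distances to column spans
(least squares), so collinear designs remain well-defined; a covariate
whose columns add no rank is reported with R² = 0 and a warning.
Categorical variables use treatment contrasts (cosmetic: partial R² is
coding-invariant). Samples with missing covariate values are dropped
from the regressions only, with a logged count; the PCA uses all
samples. Note the per-covariate shares are *partial* R² values: each is
a fraction of the variance left by the other covariates, so their sum
("total") can exceed 100% when one variable dominates.

## Step 4 — mixed-model normalization

Per metabolite, y = α + Xβ + Zθ + ε on the log scale. X holds study and
batch-within-study as independent random intercepts (both terms, with a
flag to drop the explicit study term; diagonal random-effect
covariance), plus optional fixed unwanted effects; Z holds the
biological variables to preserve as fixed effects. Continuous Z
covariates are mean-centered so adding Zc back does not shift the
location of u. Estimation is REML. The residual structure is either a
single σ² or per-study σ_s² (block-diagonal Σ).

The normalized measurement is u = e + Zc where e is the *conditional*
residual: y minus fixed part minus the predicted (shrunken) random
effects — subtracting the BLUPs is what actually removes realized
study/batch shifts. Under the per-study structure, e is replaced by the
grouped Pearson residuals e/σ̂_s rescaled by the single scalar
SD(e)/SD(e/σ̂_s), which restores the overall residual variance exactly.
The group SD (not the full conditional variance) standardizes the
Pearson residuals. Samples with missing X/Z covariates fail the fit by
default; per-metabolite failures are flagged and the metabolite passes
through unnormalized rather than aborting the run.

### REML engine

No installed Python library fits a variance-components model with
per-group residual variances, so the engine is implemented here
(`metapool.reml`). The restricted likelihood is maximized over variance
*ratios* with the global scale profiled out analytically. All
per-iteration algebra runs on per-residual-group cross-product blocks
(Z'Z, Z'W, W'W, …), so a likelihood evaluation costs O(q³ + p³) in the
number of random levels and fixed coefficients — independent of sample
count — which is what makes per-metabolite fitting across hundreds of
metabolites, and bootstrap refits, cheap. V₀ = D + ZΛZ' is inverted via
the symmetric Woodbury form with S = diag(√λ), which stays well-defined
at the λ = 0 boundary. Fixed-effect columns are rescaled to unit RMS
internally (pure reparameterization; coefficients and the reported
likelihood are returned in the original basis). Optimization is
L-BFGS-B on log-ratios (bounds: log λ ∈ [−25, 18], log residual-variance
ratios ∈ [−8, 8]) from moment-based starts, with a Nelder–Mead polish
whenever the quasi-Newton path fails, stalls within 3 iterations, or
encounters a failed factorization; Cholesky factorizations retry with
escalating jitter (from 1e−12 of the mean diagonal). Convergence is to
relative likelihood tolerance 1e−8. A variance ratio ending below 1e−8
is flagged as a boundary estimate with a warning. The homoscedastic
path is verified against statsmodels MixedLM and the heteroscedastic
path against a dense-matrix REML criterion in the test suite.

### Comparison normalizers

The empirical-Bayes batch adjustment fits, per metabolite, a
fixed-effects model with batch indicators plus the preserve-covariates;
standardizes by the pooled residual SD; estimates per-batch locations
and scales; shrinks them toward a normal prior (moment-matched mean and
variance across metabolites) and an inverse-gamma prior (moment-matched
shape/scale), iterating the standard fixed point to 1e−6; adjusts and
restores covariate effects. With one batch it returns the input. It is
verified against Bioconductor `sva::ComBat` in the test suite. The
PCA-residual method regresses each metabolite on the first K = 2 score
vectors of the standardized matrix (intercept included) and keeps the
residual; K = 0 degenerates to centering.

### Phenotype correlations

Pearson correlations between a numeric phenotype and each metabolite,
on an optional subset (typically controls, to avoid collider bias), with
one aliquot per subject kept at random under an explicit seed.

## ICC from duplicate aliquots

Per metabolite, the one-way model m_ik = γ_i + ξ_ik with
γ_i ~ N(μ, σ_γ²), ξ_ik ~ N(0, σ_ξ²), fitted by REML;
ICC = σ_γ²/(σ_γ² + σ_ξ²). The fit uses per-subject sufficient statistics
(replicate count, mean, within-subject SS) and profiles the residual
scale, reducing each fit to a 1-D bounded optimization with
O(#subjects) cost per evaluation. Confidence intervals are
percentile-bootstrap over parametric resamples from the fitted model
(the CI construction is a choice; percentile is the plain default), with
a mandatory seed. By default only replicated subjects' samples enter;
a flag includes singleton subjects, which still inform σ_γ². A
between-subject variance at the zero boundary yields ICC = 0 with a
flag. ICC is invariant to affine transformations of the measurements.

## Synthetic data

The generator mirrors a pooled multi-cohort kit dataset at desk scale.
Defaults (the `epic_like_preset`): 8 studies × 4 batches × 40 samples,
30 metabolites, τ²_study = 1.0, τ²_batch = 0.25, σ² = 0.5 on the log
scale — chosen so study dominates the pre-normalization variance
decomposition the way it does in real pooled data; two studies are
single-gender (men-only / women-only) and BMI means vary by study, so
biological covariates are genuinely study-confounded; 20% of metabolites
are "quantified" (censored at kit-level LLOQ/ULOQ) and the rest
"semi-quantified" (censored at batch LODs realized as the 5% empirical
batch quantile and written into the LOD table); 1% of cells go fully
missing at random; one batch's LOD is withheld to exercise the
unknown-LOD rule; 24 + 24 subjects are duplicated across two batches /
two studies. Duplicate aliquots share their subject's covariates and a
subject component τ²_subject = 0.35 carved out of the residual variance,
so per-sample marginal variance stays exactly σ_s² while duplicates are
correlated; the design's true ICC is
τ²_subject / (τ²_subject + within), with "within" aggregating batch
(+ study for cross-study pairs) and the remaining residual variance —
0.28 for the preset. Effect sizes default to a 0.4 log-unit gender
shift, 0.05 per BMI unit and 0.005 per g/day alcohol on the first 15
metabolites, with small per-(center, metabolite) effects (SD 0.1).

What it does not emulate: real metabolite–metabolite correlation
structure (no shared latent factors), instrument drift within batches,
skewness beyond lognormality, or informative (non-MCAR) missingness.
Passing tests therefore demonstrate correctness of the algorithms under
the generating model, not performance guarantees on any particular
cohort.

## Problem sizes and numerical notes

The test suite and the acceptance script run the preset (1,280 samples)
for pipeline-wide properties, 200 replicate metabolites for
variance-component recovery, 100 effect-carrying metabolites for the
preservation check, and 200 simulation repeats with 200 bootstrap
resamples for ICC coverage — sizes at which every Monte-Carlo band holds
with margin while a full run stays in the tens of seconds. Mean REML
residual-variance estimates on the preset run a few percent above the
generating σ² because they are computed after LOD/2 and median
imputation, which distorts the lower tail; that is a property of the
pipeline path, reported as such.

One known gap: with all true σ_s equal, the per-study-variance fit does
not reproduce the homoscedastic output to numerical precision at any
realistic sample size, because the estimated σ̂_s differ by sampling
noise of relative order √(2/n_s) (~11% at 160 samples/study) and the
rescaled Pearson residuals inherit it, giving per-metabolite output
differences up to a few tenths of an SD on the preset. The construction
is exactly homoscedastic-equivalent only in the degenerate limit —
verified in the tests: a single-group per-group fit matches the
homoscedastic output to 1e−8, and the Pearson rescaling preserves the
residual variance to 1e−10.
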