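# metapool

Normalization and pooling of targeted metabolomics data acquired in
several studies, for epidemiologists and metabolomics analysts who want
to combine concentration matrices from different cohorts, laboratories
or kit runs without quality-control or reference samples.

Pooling raises a concrete problem: study and batch introduce location
shifts (and possibly different residual variances) that dwarf the
biology, while biological variables of interest — gender, BMI, alcohol,
study center — are often unequally distributed across studies, so naively
regressing out study/batch also removes part of the biology. `metapool`
implements a four-step pipeline that addresses exactly this:

1. **Cleaning** — drop metabolites/samples with > 20% fully-missing
   values in any study (out-of-range cells do not count), samples in
   batches of fewer than 10, and per-batch multivariate outliers outside
   a 20%-expanded Hotelling T² ellipse on the first two principal
   components at level 1 − α/N_b.
2. **Imputation** — deterministic, limit-based: below-LOD → LOD/2
   (batch-specific), below-LLOQ → LLOQ/2, above-ULOQ → ULOQ, below an
   unknown LOD → (study median of known LODs)/2, fully missing → batch
   median with a study-level fallback; then natural log.
3. **PC-PR2 variance decomposition** — PCA retaining K components
   (> 80% of variance), each component's scores regressed on the
   candidate variables; the partial R² of covariate W given the others is

       R²ₖ(W) = [SSE(Cₖ | others) − SSE(Cₖ | W, others)] / SSE(Cₖ | others)

   with the nested convention for batch-within-study, and the overall
   share per covariate is the eigenvalue-weighted mean over components.
4. **Mixed-model normalization** — per metabolite,

       y = α + Xβ + Zθ + ε,      u = e + Zc

   with study and batch-within-study as random intercepts in X (REML,
   diagonal random-effect covariance), biological variables as fixed
   effects in Z, and optionally per-study residual variances
   Σ = blockdiag(σ_s² I). The normalized value u keeps the conditional
   residual (fixed part and predicted random effects subtracted) plus
   the estimated Z contribution; under heteroscedastic fits, e is
   replaced by grouped Pearson residuals rescaled to the variance of e.

Around the pipeline: ICC-based technical reproducibility from duplicate
aliquots (one-way random-intercept REML with parametric-bootstrap CIs),
two comparison normalizers (a parametric empirical-Bayes location/scale
batch adjustment in the ComBat family, and PCA-residual removal with
K = 2), phenotype–metabolite correlation utilities, and a synthetic
multi-study generator with a ground-truth ledger so every property of
the pipeline is testable without access-restricted cohort data.

## Worked example

```python
from metapool import (NormalizationSpec, clean, epic_like_preset, estimate_icc,
                      generate, impute, normalize_dataset, run_pcpr2)

data, truth = generate(epic_like_preset(seed=7))   # 8 studies x 4 batches x 40
cleaned, report = clean(data)
imputed, _ = impute(cleaned)                       # limit-based rules + log

res = run_pcpr2(imputed, ["center", "gender", "bmi", "alcohol",
                          "study", "batch@study"])
normalized, models = normalize_dataset(imputed, NormalizationSpec(
    variance_structure="per_group"))               # per-study sigma_s
res_after = run_pcpr2(normalized, ["center", "gender", "bmi", "alcohol",
                                   "study", "batch@study"])
```

Running `examples/04_normalize_preserving_biology.py` (the script behind
the snippet) prints:

```
fitted 30/30 metabolite models
variance components (first metabolite): {'study': 1.186, 'batch': 0.158}
study+batch share before: 95.38%
study+batch share after:  0.12%
gender effect: injected 0.40, recovered 0.42 (mean over effect metabolites)
```

Before normalization, study and batch dominate the variance
decomposition; afterwards they explain ~0.1%, while the study-confounded
gender effect injected by the generator is still recovered from the
normalized values. `examples/05_reproducibility_icc.py` shows the
reproducibility payoff on the duplicate aliquots:

```
median ICC: 0.474 -> 0.693
metabolites below 0.50: 18 -> 1
```

The other example scripts cover simulation (`01`), cleaning/imputation
(`02`), the variance decomposition (`03`) and the comparison
normalizers (`06`). A thin CLI mirrors the stages
(`metapool simulate | clean | impute | pcpr2 | normalize | icc | run`);
`metapool run --config config.yaml` executes the whole pipeline and
writes per-stage reports, plots and a replayable effective config.

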