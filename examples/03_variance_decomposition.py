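"""Step 3: PC-PR2 — which variables drive the variation?

A PCA retains enough components to explain 80% of total variance; each
component's scores are regressed on the candidate variables and the
eigenvalue-weighted partial R2 attributes the variation.  Batch is
declared nested in study ("batch@study"), so batch is never credited
with variation already explained by study.
"""

from metapool import clean, epic_like_preset, generate, impute, run_pcpr2

data, _ = generate(epic_like_preset(seed=7))
cleaned, _ = clean(data)
imputed, _ = impute(cleaned)

covariates = ["center", "gender", "age", "bmi", "alcohol", "smoking",
              "fasting", "blood_draw_time", "case_control", "study", "batch@study"]
res = run_pcpr2(imputed, covariates)

print(f"retained K = {res.n_components} components")
for name, share in res.overall_partial_r2.items():
    print(f"  {name:16s} {100 * share:6.2f}%")
print(f"  {'total':16s} {100 * res.total_explained:6.2f}%")
# Large study/batch shares flag unwanted technical variation that the
# normalization step should remove; the biological variables' shares are
# what normalization must preserve.
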