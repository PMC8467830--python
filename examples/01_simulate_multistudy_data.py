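"""Generate a synthetic multi-study targeted-metabolomics dataset.

The generator draws log concentrations from a variance-components model
(study and batch random shifts, biological covariate effects, subject
effects shared by duplicate aliquots), exponentiates, censors below
batch-specific detection limits and knocks out cells at random — the
structure a pooled multi-cohort kit dataset actually has.
"""

from metapool import epic_like_preset, generate

data, truth = generate(epic_like_preset(seed=7))

print(f"samples x metabolites: {data.n_samples} x {data.n_metabolites}")
print(f"studies: {data.metadata['study'].nunique()}, "
      f"batches: {data.metadata['batch'].nunique()}")
counts = data.codes.stack().value_counts()
print("cell codes:")
print(counts.to_string())
print(f"duplicate subjects (two aliquots each): {len(truth.duplicate_subjects)}")
print(f"true ICC of the duplicate design: {truth.true_icc.iloc[0]:.3f}")
# The below-LOD / below-LLOQ counts are the cells the imputation step will
# substitute from the limit tables; the true ICC is the recovery target for
# the reproducibility analysis.
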