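"""Step 1 — data cleaning.

Removes the least informative metabolites and samples before imputation:

1. metabolites whose fully-missing fraction exceeds a threshold in at
   least one study (out-of-range codes do not count as missing);
2. samples whose fully-missing fraction exceeds the threshold;
3. samples assayed in batches smaller than a minimum size (small batches
   cannot support batch-wise imputation or normalization);
4. per-batch multivariate outliers: samples outside an expanded Hotelling
   T-squared ellipse on the first two principal components, at a level
   Bonferroni-adjusted over the number of batches.

Cleaning never alters a value: the cleaned dataset is a strict row/column
subset of the input, and the :class:`CleaningReport` is sufficient to
replay every exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Code, MetabolomicsDataset, ValidationError

__all__ = [
    "CleaningReport",
    "filter_metabolites_by_missingness",
    "filter_samples_by_missingness",
    "exclude_small_batches",
    "detect_pca_outliers",
    "clean",
    "apply_report",
]


@dataclass
class CleaningReport:
    """Machine-readable record of every exclusion.

    ``excluded_metabolites`` entries: (metabolite, reason, study, fraction).
    ``excluded_samples`` entries: (sample_id, reason, detail) with reason in
    {"missingness", "small_batch", "pca_outlier"}.
    """

    excluded_metabolites: list[dict] = field(default_factory=list)
    excluded_samples: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    t2_statistics: dict[str, float] = field(default_factory=dict)
    skipped_batches: list[str] = field(default_factory=list)

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        return CleaningReport(
            self.excluded_metabolites + other.excluded_metabolites,
            self.excluded_samples + other.excluded_samples,
            {**self.thresholds, **other.thresholds},
            {**self.t2_statistics, **other.t2_statistics},
            self.skipped_batches + other.skipped_batches,
        )

    def to_dict(self) -> dict:
        return {
            "excluded_metabolites": self.excluded_metabolites,
            "excluded_samples": self.excluded_samples,
            "thresholds": self.thresholds,
            "t2_statistics": self.t2_statistics,
            "skipped_batches": self.skipped_batches,
        }


def _check_studies_nonempty(data: MetabolomicsDataset) -> None:
    sizes = data.metadata.groupby("study", observed=True).size()
    empty = sizes.index[sizes == 0].tolist()
    if empty:
        raise ValidationError(f"study with zero samples: {empty}")


def filter_metabolites_by_missingness(
    data: MetabolomicsDataset, threshold: float = 0.20
) -> tuple[MetabolomicsDataset, CleaningReport]:
    """Drop metabolites fully missing in more than ``threshold`` of the
    samples of at least one study.

    Only FULLY_MISSING counts: below-LOD/LLOQ and above-ULOQ codes carry
    partial information and never trigger exclusion here.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    _check_studies_nonempty(data)
    missing = data.code_mask(Code.FULLY_MISSING)
    frac = missing.groupby(data.metadata["study"], observed=True).mean()  # study x metabolite
    report = CleaningReport(thresholds={"metabolite_missingness": threshold})
    drop = []
    for met in data.metabolites:
        over = frac[met][frac[met] > threshold]
        if len(over):
            worst = over.idxmax()
            drop.append(met)
            report.excluded_metabolites.append(
                {"metabolite": met, "reason": "missingness", "study": worst,
                 "missing_fraction": float(over.max())}
            )
    keep = [m for m in data.metabolites if m not in set(drop)]
    return data.subset(metabolites=keep), report


def filter_samples_by_missingness(
    data: MetabolomicsDataset, threshold: float = 0.20
) -> tuple[MetabolomicsDataset, CleaningReport]:
    """Drop samples with more than ``threshold`` fully-missing metabolites."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = data.code_mask(Code.FULLY_MISSING).mean(axis=1)
    report = CleaningReport(thresholds={"sample_missingness": threshold})
    bad = frac.index[frac > threshold]
    for sid in bad:
        report.excluded_samples.append(
            {"sample_id": sid, "reason": "missingness", "detail": {"missing_fraction": float(frac[sid])}}
        )
    keep = frac.index[frac <= threshold]
    return data.subset(samples=keep), report


def exclude_small_batches(
    data: MetabolomicsDataset, min_batch_size: int = 10
) -> tuple[MetabolomicsDataset, CleaningReport]:
    """Drop every sample in a batch with fewer than ``min_batch_size``
    samples (strict: a batch of exactly ``min_batch_size`` is retained)."""
    if min_batch_size < 1:
        raise ValueError("min_batch_size must be >= 1")
    sizes = data.metadata.groupby("batch", observed=True).size()
    small = set(sizes.index[sizes < min_batch_size])
    report = CleaningReport(thresholds={"min_batch_size": min_batch_size})
    in_small = data.metadata["batch"].isin(small)
    for sid in data.sample_ids[in_small]:
        b = data.metadata.loc[sid, "batch"]
        report.excluded_samples.append(
            {"sample_id": sid, "reason": "small_batch",
             "detail": {"batch": b, "batch_size": int(sizes[b])}}
        )
    return data.subset(samples=data.sample_ids[~in_small]), report


def _batch_scores(values: pd.DataFrame, codes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray] | None:
    """First-two-PC scores and eigenvalues for one batch.

    Non-OBSERVED cells are provisionally filled with the batch median of
    observed values (scoring only; the fill is discarded).  Metabolites
    with no observed value, or zero variance, in the batch are dropped.
    """
    observed = codes.to_numpy(dtype=object) == Code.OBSERVED.value
    x = values.to_numpy(dtype=float).copy()
    x[~observed] = np.nan
    med = np.nanmedian(np.where(observed, x, np.nan), axis=0)
    usable = np.isfinite(med)
    x = x[:, usable]
    med = med[usable]
    inds = np.where(np.isnan(x))
    x[inds] = np.take(med, inds[1])
    sd = x.std(axis=0, ddof=1)
    ok = sd > 0
    if ok.sum() == 0:
        return None
    x = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
    # PCA via SVD of the centered, scaled batch matrix
    u, s, _ = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    n = x.shape[0]
    eig = s**2 / (n - 1)
    scores = u * s
    k = min(2, scores.shape[1])
    return scores[:, :k], eig[:k]


def detect_pca_outliers(
    data: MetabolomicsDataset, expansion: float = 0.20, alpha: float = 0.05
) -> tuple[MetabolomicsDataset, CleaningReport]:
    """Flag per-batch outliers with an expanded Hotelling T-squared ellipse.

    Within each batch the samples are scored on the first two principal
    components of the batch's standardized matrix; sample i is an outlier
    iff T2_i > (1 + expansion)^2 * T2_crit, where T2_crit is the ellipse
    radius at confidence 1 - alpha/N_b (N_b = total number of batches;
    a Bonferroni-style adjustment so the family-wise level is ~alpha) and
    T2_crit = k(n-1)/(n-k) * F_{1-alpha/N_b}(k, n-k) with k = 2 components.

    Batches with fewer than 3 samples are skipped (the ellipse is
    undefined) and recorded in the report.
    """
    report = CleaningReport(thresholds={"ellipse_expansion": expansion, "ellipse_alpha": alpha})
    batches = data.metadata["batch"].unique()
    n_b = len(batches)
    if n_b < 1:
        raise ValidationError("dataset has no batches")
    level = 1 - alpha / n_b
    drop: list[str] = []
    for batch in batches:
        sids = data.sample_ids[data.metadata["batch"] == batch]
        n = len(sids)
        if n < 3:
            warnings.warn(f"batch {batch!r} has {n} samples; T2 ellipse undefined, skipped")
            report.skipped_batches.append(batch)
            continue
        res = _batch_scores(data.values.loc[sids], data.codes.loc[sids])
        if res is None:
            report.skipped_batches.append(batch)
            continue
        scores, eig = res
        k = scores.shape[1]
        if n - k <= 0:
            report.skipped_batches.append(batch)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(eig > 0, scores**2 / eig, 0.0).sum(axis=1)
        crit = k * (n - 1) / (n - k) * stats.f.ppf(level, k, n - k)
        cutoff = (1 + expansion) ** 2 * crit
        for sid, stat_val in zip(sids, t2):
            report.t2_statistics[sid] = float(stat_val)
            if stat_val > cutoff:
                drop.append(sid)
                report.excluded_samples.append(
                    {"sample_id": sid, "reason": "pca_outlier",
                     "detail": {"batch": batch, "t2": float(stat_val), "cutoff": float(cutoff)}}
                )
    keep = data.sample_ids[~data.sample_ids.isin(drop)]
    return data.subset(samples=keep), report


def clean(
    data: MetabolomicsDataset,
    miss_threshold: float = 0.20,
    min_batch_size: int = 10,
    ellipse_expansion: float = 0.20,
    ellipse_alpha: float = 0.05,
) -> tuple[MetabolomicsDataset, CleaningReport]:
    """Run the full cleaning step in its fixed order: metabolite filter,
    sample filter, small-batch exclusion, per-batch outlier removal."""
    data, r1 = filter_metabolites_by_missingness(data, miss_threshold)
    data, r2 = filter_samples_by_missingness(data, miss_threshold)
    data, r3 = exclude_small_batches(data, min_batch_size)
    data, r4 = detect_pca_outliers(data, ellipse_expansion, ellipse_alpha)
    return data, r1.merge(r2).merge(r3).merge(r4)


def apply_report(data: MetabolomicsDataset, report: CleaningReport) -> MetabolomicsDataset:
    """Replay a cleaning report: drop exactly the recorded rows/columns."""
    drop_m = {e["metabolite"] for e in report.excluded_metabolites}
    drop_s = {e["sample_id"] for e in report.excluded_samples}
    return data.subset(
        samples=data.sample_ids[~data.sample_ids.isin(drop_s)],
        metabolites=[m for m in data.metabolites if m not in drop_m],
    )
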