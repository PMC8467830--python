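"""Technical reproducibility from duplicate samples.

Duplicate aliquots of the same subject, assayed in two batches or two
studies, measure how much of a metabolite's variance is subject signal
rather than technical noise.  Per metabolite the one-way random-intercept
model

    m_ik = gamma_i + xi_ik,   gamma_i ~ N(mu, sigma_g^2),  xi_ik ~ N(0, sigma_x^2)

is fitted by REML and the intraclass correlation coefficient is

    ICC = sigma_g^2 / (sigma_g^2 + sigma_x^2).

Confidence intervals come from a parametric bootstrap: simulate from the
fitted model, refit, take percentile bounds of the ICC replicates.

The REML fit uses per-subject sufficient statistics (replicate count,
mean, within-subject sum of squares) and profiles the residual scale, so
one fit is a one-dimensional optimization with O(#subjects) cost per
likelihood evaluation — cheap enough to bootstrap thousands of times.
Subjects with a single sample still inform the between-subject variance
and are supported; by default only replicated subjects' samples are used,
matching how duplicate designs are usually analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset import MetabolomicsDataset, ValidationError

__all__ = ["OneWayREML", "ICCResult", "fit_one_way", "estimate_icc", "icc_comparison_report"]

_LOG_LAMBDA_BOUNDS = (-30.0, 30.0)


@dataclass
class OneWayREML:
    """REML fit of the one-way random-intercept model."""

    mu: float
    sigma2_between: float
    sigma2_within: float
    loglike: float
    n_obs: int
    n_subjects: int
    boundary: bool  # between-subject variance at the zero boundary

    @property
    def icc(self) -> float:
        tot = self.sigma2_between + self.sigma2_within
        return 0.0 if tot == 0 else self.sigma2_between / tot


def _suff_stats(y: np.ndarray, subject_idx: np.ndarray, n_subjects: int):
    counts = np.bincount(subject_idx, minlength=n_subjects).astype(float)
    sums = np.bincount(subject_idx, weights=y, minlength=n_subjects)
    means = sums / counts
    ssw = float(np.bincount(subject_idx, weights=(y - means[subject_idx]) ** 2, minlength=n_subjects).sum())
    return counts, means, ssw


def _profiled_m2ll(log_lam: float, counts: np.ndarray, means: np.ndarray, ssw: float, n: int):
    lam = np.exp(log_lam)
    denom = 1.0 + lam * counts
    w = counts / denom
    sw = w.sum()
    mu = (w * means).sum() / sw
    quad = ssw + (w * (means - mu) ** 2).sum()
    sigma2 = quad / (n - 1)
    m2ll = (n - 1) * (np.log(2 * np.pi * sigma2) + 1) + np.log(denom).sum() + np.log(sw)
    return m2ll, mu, sigma2, lam


def fit_one_way(y: np.ndarray, subject_idx: np.ndarray, n_subjects: int | None = None) -> OneWayREML:
    """REML fit from a response vector and an integer subject index."""
    y = np.asarray(y, dtype=float)
    subject_idx = np.asarray(subject_idx)
    if n_subjects is None:
        n_subjects = int(subject_idx.max()) + 1
    n = len(y)
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    counts, means, ssw = _suff_stats(y, subject_idx, n_subjects)
    if (counts >= 2).sum() < 1:
        raise ValidationError("no subject has replicated samples; ICC is unidentifiable")

    if ssw == 0.0:
        # replicates are exactly equal: all residual variance vanishes
        between = float(np.var(means, ddof=1))
        ll, *_ = _profiled_m2ll(_LOG_LAMBDA_BOUNDS[1], counts, means, ssw, n)
        return OneWayREML(float(means.mean()), between, 0.0, -0.5 * ll, n, n_subjects, boundary=False)

    res = optimize.minimize_scalar(
        lambda t: _profiled_m2ll(t, counts, means, ssw, n)[0],
        bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
        options={"xatol": 1e-10},
    )
    m2ll, mu, sigma2, lam = _profiled_m2ll(res.x, counts, means, ssw, n)
    boundary = res.x <= _LOG_LAMBDA_BOUNDS[0] + 1e-6
    if boundary:
        lam = 0.0
    return OneWayREML(mu, lam * sigma2, sigma2, -0.5 * m2ll, n, n_subjects, boundary)


def _bootstrap_ci(fit: OneWayREML, counts: np.ndarray, n_boot: int, level: float,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Parametric bootstrap percentile CI for the ICC."""
    m = len(counts)
    subject_idx = np.repeat(np.arange(m), counts.astype(int))
    n = len(subject_idx)
    sd_g, sd_x = np.sqrt(fit.sigma2_between), np.sqrt(fit.sigma2_within)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        gamma = rng.normal(fit.mu, sd_g, size=m)
        y = gamma[subject_idx] + rng.normal(0.0, sd_x, size=n)
        reps[b] = fit_one_way(y, subject_idx, m).icc
    lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


@dataclass
class ICCResult:
    """Per-metabolite ICC table with bootstrap CIs.

    ``table`` columns: sigma2_between, sigma2_within, icc, ci_lower,
    ci_upper, boundary; plus n_subjects / n_replicated_subjects attributes.
    """

    table: pd.DataFrame
    n_subjects: int
    n_replicated_subjects: int
    level: float
    n_boot: int

    @property
    def icc(self) -> pd.Series:
        return self.table["icc"]


def estimate_icc(
    data: MetabolomicsDataset,
    subject_col: str = "subject_id",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    replicated_only: bool = True,
) -> ICCResult:
    """Estimate every metabolite's ICC from duplicate samples.

    ``replicated_only`` restricts to subjects with >= 2 aliquots (the
    default duplicate-design analysis); set False to let singleton
    subjects contribute to the between-subject variance as well.
    """
    if subject_col not in data.metadata.columns:
        raise ValidationError(f"no {subject_col!r} column in metadata")
    subjects = data.metadata[subject_col].astype(str)
    counts_per_subject = subjects.value_counts()
    replicated = set(counts_per_subject.index[counts_per_subject >= 2])
    if not replicated:
        raise ValidationError("no subject has replicated samples")
    if replicated_only:
        mask = subjects.isin(replicated).to_numpy()
    else:
        mask = np.ones(len(subjects), dtype=bool)
    ids = data.sample_ids[mask]
    subj = subjects[mask]
    subject_idx, subject_levels = pd.factorize(subj)
    m = len(subject_levels)
    rng = np.random.default_rng(seed)

    rows = []
    for met in data.metabolites:
        y = data.values.loc[ids, met].to_numpy(dtype=float)
        fit = fit_one_way(y, subject_idx, m)
        if fit.boundary:
            warnings.warn(f"{met}: between-subject variance at zero boundary; ICC = 0")
        counts = np.bincount(subject_idx, minlength=m).astype(float)
        if n_boot > 0:
            lo, hi = _bootstrap_ci(fit, counts, n_boot, level, rng)
        else:
            lo = hi = np.nan
        rows.append({
            "metabolite": met, "sigma2_between": fit.sigma2_between,
            "sigma2_within": fit.sigma2_within, "icc": fit.icc,
            "ci_lower": lo, "ci_upper": hi, "boundary": fit.boundary,
        })
    table = pd.DataFrame(rows).set_index("metabolite")
    return ICCResult(table, m, len(replicated), level, n_boot)


def icc_comparison_report(
    before: ICCResult,
    after: ICCResult,
    classes: pd.Series | None = None,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Summarize per-metabolite ICC change across a normalization.

    Returns a table of before/after pairs and deltas; aggregates per
    metabolite class when ``classes`` maps metabolite -> class; counts of
    metabolites below the conventional 0.50 and 0.75 reproducibility
    thresholds are attached as ``DataFrame.attrs["summary"]``.  When
    ``plot_path`` is given, an arrow plot (before -> after per metabolite)
    is written there.
    """
    if not before.table.index.equals(after.table.index):
        raise ValidationError("before/after ICC results cover different metabolites")
    tab = pd.DataFrame({
        "icc_before": before.icc, "icc_after": after.icc,
        "delta": after.icc - before.icc,
    })
    if classes is not None:
        tab["class"] = classes.reindex(tab.index)
    summary = {
        "median_before": float(tab["icc_before"].median()),
        "median_after": float(tab["icc_after"].median()),
        "n_below_050_before": int((tab["icc_before"] < 0.50).sum()),
        "n_below_050_after": int((tab["icc_after"] < 0.50).sum()),
        "n_below_075_before": int((tab["icc_before"] < 0.75).sum()),
        "n_below_075_after": int((tab["icc_after"] < 0.75).sum()),
    }
    if classes is not None:
        summary["class_means"] = (
            tab.groupby("class")[["icc_before", "icc_after"]].mean().to_dict(orient="index")
        )
    tab.attrs["summary"] = summary
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = tab["icc_before"].sort_values().index
        fig, ax = plt.subplots(figsize=(6, max(3, 0.18 * len(tab))))
        for i, met in enumerate(order):
            b, a = tab.at[met, "icc_before"], tab.at[met, "icc_after"]
            ax.annotate("", xy=(a, i), xytext=(b, i),
                        arrowprops=dict(arrowstyle="->", color="#b04848" if a < b else "#4878a8", lw=1))
        ax.set_yticks(range(len(order)))
        ax.set_yticklabels(order, fontsize=6)
        ax.set_xlabel("ICC (arrow: before -> after normalization)")
        ax.set_xlim(0, 1)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return tab
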