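"""Step 4 — removal of unwanted variation with linear mixed models.

Each metabolite's log concentration is modeled as

    y = alpha + X beta + Z theta + eps,

where X holds the unwanted sources of variation (study and batch-within-
study as random intercepts, optionally extra fixed terms) and Z holds the
biological variables whose variation must survive normalization (e.g.
center, gender, BMI, alcohol).  After a REML fit, the normalized
measurement is

    u = e + Z c,

the conditional residual (observed minus fixed part minus predicted
random effects) with the estimated Z contribution added back.  Variables
only in X are thereby eliminated; variables in Z keep their estimated
effect even when they are confounded with study or batch.

Residuals may be heteroscedastic across studies (block-diagonal
covariance sigma_s^2 I per study).  In that case e in u = e + Zc is
replaced by the grouped Pearson residuals e_i / sigma_{s(i)}, rescaled by
one global constant so their overall variance equals that of e.

Two comparison normalizers are provided: a parametric empirical-Bayes
location/scale batch adjustment (ComBat-style) and removal of the first
K principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MetabolomicsDataset, ValidationError
from .reml import RandomTerm, REMLFit, fit_variance_components

__all__ = [
    "NormalizationSpec",
    "FittedMetaboliteModel",
    "fit_metabolite_model",
    "normalize_dataset",
    "combat_normalize",
    "pca_residual_normalize",
    "correlate_with_phenotype",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationSpec:
    """Variable assignment and variance structure for the mixed model.

    ``x_random`` lists grouping variables entering X as random intercepts
    (``"batch@study"`` marks nesting; batch labels are unique within study
    so nesting is enforced by the labels).  ``x_fixed`` lists unwanted
    fixed-effect variables; ``z_fixed`` the biological variables to
    preserve.  ``variance_structure`` is ``"homoscedastic"`` or
    ``"per_group"`` with ``variance_group`` naming the grouping column
    (default study).
    """

    x_random: tuple[str, ...] = ("study", "batch@study")
    x_fixed: tuple[str, ...] = ()
    z_fixed: tuple[str, ...] = ("center", "gender", "bmi", "alcohol")
    variance_structure: str = "homoscedastic"
    variance_group: str = "study"

    def __post_init__(self):
        x_names = {v.split("@")[0] for v in self.x_random} | set(self.x_fixed)
        overlap = x_names & set(self.z_fixed)
        if overlap:
            raise ValidationError(f"variables cannot be in both X and Z: {sorted(overlap)}")
        if self.variance_structure not in ("homoscedastic", "per_group"):
            raise ValidationError(f"unknown variance structure {self.variance_structure!r}")


@dataclass
class FittedMetaboliteModel:
    """One metabolite's fitted mixed model and its normalization pieces."""

    metabolite: str
    fit: REMLFit
    z_columns: np.ndarray          # design columns for Z (same coding as fit)
    z_coef: np.ndarray             # estimated theta (c)
    normalized: np.ndarray         # u = e (possibly rescaled Pearson) + Z c
    failed: bool = False
    error: str = ""

    @property
    def intercept(self) -> float:
        return float(self.fit.beta.iloc[0])

    @property
    def variance_components(self) -> dict[str, float]:
        return self.fit.variance_components


def _categorical_dummies(series: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    codes, levels = pd.factorize(series.astype(str))
    cols = np.zeros((len(series), max(len(levels) - 1, 0)))
    names = []
    for j in range(1, len(levels)):
        cols[codes == j, j - 1] = 1.0
        names.append(f"{prefix}[{levels[j]}]")
    return cols, names


def _fixed_block(meta: pd.DataFrame, variables: tuple[str, ...], center_continuous: bool):
    """Design columns for a list of fixed-effect variables.

    Continuous variables are mean-centered when requested (used for Z so
    that adding Zc back does not shift the location of u arbitrarily).
    """
    cols, names = [], []
    for v in variables:
        if v not in meta.columns:
            raise ValidationError(f"variable {v!r} not in metadata")
        s = meta[v]
        if s.isna().any():
            bad = s.index[s.isna()].tolist()[:5]
            raise ValidationError(f"variable {v!r} has missing values (e.g. {bad}); complete or impute covariates first")
        if pd.api.types.is_numeric_dtype(s):
            col = s.to_numpy(dtype=float)
            if center_continuous:
                col = col - col.mean()
            cols.append(col[:, None])
            names.append(v)
        else:
            c, nm = _categorical_dummies(s, v)
            if c.shape[1] == 0:
                raise ValidationError(f"variable {v!r} is constant")
            cols.append(c)
            names.extend(nm)
    block = np.hstack(cols) if cols else np.zeros((len(meta), 0))
    return block, names


def _build_design(meta: pd.DataFrame, spec: NormalizationSpec):
    random_terms = []
    for v in spec.x_random:
        name = v.split("@")[0]
        if name not in meta.columns:
            raise ValidationError(f"random term {name!r} not in metadata")
        random_terms.append(RandomTerm.from_labels(name, meta[name]))
    xf, xf_names = _fixed_block(meta, spec.x_fixed, center_continuous=False)
    zf, zf_names = _fixed_block(meta, spec.z_fixed, center_continuous=True)
    n = len(meta)
    w = np.hstack([np.ones((n, 1)), xf, zf])
    names = ["Intercept"] + xf_names + zf_names
    z_slice = slice(1 + xf.shape[1], w.shape[1])
    if spec.variance_structure == "per_group":
        codes, levels = pd.factorize(meta[spec.variance_group].astype(str))
        groups, labels = codes, list(levels)
    else:
        groups, labels = None, None
    return w, names, z_slice, random_terms, groups, labels


def fit_metabolite_model(
    y: np.ndarray | pd.Series,
    metadata: pd.DataFrame,
    spec: NormalizationSpec,
    metabolite: str = "",
) -> FittedMetaboliteModel:
    """Fit the mixed model for one metabolite and compute u = e + Zc."""
    y = np.asarray(y, dtype=float)
    w, names, z_slice, terms, groups, labels = _build_design(metadata, spec)
    fit = fit_variance_components(
        y, w, terms, fixed_names=names,
        residual_groups=groups, residual_group_labels=labels,
    )
    zc = w[:, z_slice]
    c = fit.beta.to_numpy()[z_slice]
    e = fit.residuals
    if spec.variance_structure == "per_group":
        sd = np.sqrt(fit.residual_variances.to_numpy())[groups]
        pearson = e / sd
        sd_e, sd_p = e.std(ddof=1), pearson.std(ddof=1)
        scale = sd_e / sd_p if sd_p > 0 else 1.0
        e_used = pearson * scale
    else:
        e_used = e
    u = e_used + zc @ c
    return FittedMetaboliteModel(metabolite, fit, zc, c, u)


def normalize_dataset(
    data: MetabolomicsDataset,
    spec: NormalizationSpec = NormalizationSpec(),
) -> tuple[MetabolomicsDataset, dict[str, FittedMetaboliteModel]]:
    """Normalize every metabolite with the mixed model defined by ``spec``.

    Metabolites whose fit fails are emitted unnormalized with
    ``model.failed`` set; failures never abort the run.
    """
    if data.scale != "log":
        raise ValidationError("normalization expects log-scale data")
    out = data.values.copy()
    models: dict[str, FittedMetaboliteModel] = {}
    for met in data.metabolites:
        y = data.values[met].to_numpy(dtype=float)
        try:
            model = fit_metabolite_model(y, data.metadata, spec, metabolite=met)
            out[met] = model.normalized
        except Exception as exc:  # per-metabolite failure policy
            logger.warning("normalization failed for %s: %s", met, exc)
            model = FittedMetaboliteModel(met, None, None, None, y, failed=True, error=str(exc))
        models[met] = model
    n_failed = sum(m.failed for m in models.values())
    if n_failed:
        logger.warning("%d/%d metabolite models failed; left unnormalized", n_failed, len(models))
    return data.with_values(out), models


# ---------------------------------------------------------------------------
# Comparison method 1: empirical-Bayes location/scale batch adjustment
# ---------------------------------------------------------------------------

def combat_normalize(
    data: MetabolomicsDataset,
    batch_var: str = "batch",
    preserve: tuple[str, ...] = (),
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MetabolomicsDataset:
    """Parametric empirical-Bayes batch adjustment (ComBat-style).

    Per metabolite a fixed-effects model with batch indicators plus the
    ``preserve`` covariates is fitted; per-batch locations gamma and
    scales delta^2 are shrunk toward a normal and a moment-matched
    inverse-gamma prior (standard EB fixed point, iterated to ``tol``),
    the data are adjusted, and covariate effects are restored.  With
    batch nested in study, correcting for batch also removes study shifts.
    """
    if data.scale != "log":
        raise ValidationError("batch adjustment expects log-scale data")
    meta = data.metadata
    codes, batches = pd.factorize(meta[batch_var].astype(str))
    n_batch = len(batches)
    if n_batch == 1:
        return data.with_values(data.values.copy())
    counts = np.bincount(codes, minlength=n_batch)
    if (counts < 2).any():
        small = [batches[i] for i in np.where(counts < 2)[0]]
        raise ValidationError(f"every batch needs >= 2 samples; too small: {small}")

    y = data.values.to_numpy(dtype=float)  # n x p
    n, p = y.shape
    batch_design = np.zeros((n, n_batch))
    batch_design[np.arange(n), codes] = 1.0
    cov_block, _ = _fixed_block(meta, tuple(preserve), center_continuous=False)
    design = np.hstack([batch_design, cov_block])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("singular design: preserved covariates confounded with batch")

    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    gamma_hat_ols = beta[:n_batch]                      # per-batch means, p per batch
    cov_coef = beta[n_batch:]
    frac = counts / n
    grand = frac @ gamma_hat_ols                        # weighted grand mean per metabolite
    covar_part = cov_block @ cov_coef if cov_block.shape[1] else 0.0
    resid = y - batch_design @ gamma_hat_ols - covar_part
    pooled_var = (resid**2).mean(axis=0)                # sigma_g^2, 1/n convention
    pooled_sd = np.sqrt(pooled_var)
    z = (y - grand - covar_part) / pooled_sd            # standardized data

    adjusted = np.empty_like(z)
    for b in range(n_batch):
        rows = codes == b
        nb = counts[b]
        g_hat = z[rows].mean(axis=0)                    # per-metabolite batch location
        d_hat = z[rows].var(axis=0, ddof=1)             # per-metabolite batch scale
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m_d, s2_d = d_hat.mean(), d_hat.var(ddof=1)
        if s2_d <= 0 or t2 <= 0:                        # degenerate prior: no shrinkage
            g_star, d_star = g_hat, d_hat
        else:
            a_prior = (2 * s2_d + m_d**2) / s2_d
            b_prior = (m_d * s2_d + m_d**3) / s2_d
            g_star, d_star = g_hat.copy(), d_hat.copy()
            sum_sq = ((z[rows] - g_star) ** 2).sum(axis=0)
            for _ in range(max_iter):
                g_new = (nb * t2 * g_hat + d_star * g_bar) / (nb * t2 + d_star)
                sum_sq = ((z[rows] - g_new) ** 2).sum(axis=0)
                d_new = (b_prior + 0.5 * sum_sq) / (nb / 2 + a_prior - 1)
                change = max(
                    np.abs((g_new - g_star) / np.where(g_star == 0, 1, g_star)).max(),
                    np.abs((d_new - d_star) / d_star).max(),
                )
                g_star, d_star = g_new, d_new
                if change < tol:
                    break
        adjusted[rows] = (z[rows] - g_star) / np.sqrt(d_star)
    out = adjusted * pooled_sd + grand + covar_part
    return data.with_values(pd.DataFrame(out, index=data.sample_ids, columns=data.metabolites))


# ---------------------------------------------------------------------------
# Comparison method 2: residuals on the first K principal components
# ---------------------------------------------------------------------------

def pca_residual_normalize(data: MetabolomicsDataset, k: int = 2) -> MetabolomicsDataset:
    """Replace each metabolite by its residual on the first K PC scores.

    The PCA runs on the standardized matrix; each (log) metabolite is then
    regressed on the K score vectors with intercept, and the residual is
    the normalized value.  K = 0 degenerates to centering.
    """
    if data.scale != "log":
        raise ValidationError("PCA-residual normalization expects log-scale data")
    x = data.values.to_numpy(dtype=float)
    n, p = x.shape
    if k < 0:
        raise ValidationError("k must be >= 0")
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError("zero-variance metabolite")
    u_svd, s, _ = np.linalg.svd(xc / sd, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum())
    if k >= rank and k > 0:
        raise ValidationError(f"k = {k} >= rank {rank} of the data")
    scores = u_svd[:, :k] * s[:k]
    design = np.column_stack([np.ones(n), scores])
    beta, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    return data.with_values(pd.DataFrame(resid, index=data.sample_ids, columns=data.metabolites))


# ---------------------------------------------------------------------------
# Phenotype association
# ---------------------------------------------------------------------------

def correlate_with_phenotype(
    data: MetabolomicsDataset,
    phenotype: str,
    subset: pd.Series | None = None,
    subject_col: str = "subject_id",
    seed: int | None = None,
) -> pd.Series:
    """Per-metabolite Pearson correlation with a numeric phenotype.

    ``subset`` is an optional boolean mask over samples (e.g. controls
    only).  When a subject contributes several aliquots, one is kept at
    random (``seed`` makes the draw reproducible).
    """
    meta = data.metadata
    if phenotype not in meta.columns or not pd.api.types.is_numeric_dtype(meta[phenotype]):
        raise ValidationError(f"phenotype {phenotype!r} must be a numeric metadata column")
    ids = data.sample_ids if subset is None else data.sample_ids[subset.reindex(data.sample_ids).fillna(False).astype(bool)]
    if subject_col in meta.columns:
        rng = np.random.default_rng(seed)
        sub = meta.loc[ids, subject_col]
        keep = []
        for _, grp in sub.groupby(sub, sort=True):
            keep.append(grp.index[rng.integers(len(grp))])
        ids = pd.Index(keep)
    ph = meta.loc[ids, phenotype].to_numpy(dtype=float)
    if np.ptp(ph) == 0:
        raise ValidationError(f"phenotype {phenotype!r} is constant on the selected subset")
    vals = data.values.loc[ids].to_numpy(dtype=float)
    ph_c = ph - ph.mean()
    v_c = vals - vals.mean(axis=0)
    denom = np.sqrt((ph_c**2).sum() * (v_c**2).sum(axis=0))
    r = (v_c.T @ ph_c) / np.where(denom == 0, np.nan, denom)
    return pd.Series(r, index=data.metabolites, name=f"r({phenotype})")
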