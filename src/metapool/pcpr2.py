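"""Step 3 — principal-component partial-R2 (PC-PR2) variance decomposition.

PC-PR2 attributes the total variation of a metabolomics matrix to a list
of candidate explanatory variables.  A PCA is run on the standardized
matrix and the smallest number K of components explaining more than a
threshold (default 80%) of total variance is retained.  Each component's
scores are regressed on all covariates, and each covariate's partial R2
is the relative drop in residual sum of squares when it is added to the
model already holding every other covariate:

    R2_partial,k(W) = [SSE(C_k | others) - SSE(C_k | W, others)] / SSE(C_k | others)

For a nested pair — study S outer, batch B inner — S's partial R2
conditions on all covariates except S and B, and B's conditions on S plus
all the others, so the inner variable is never credited with variation
already attributable to the outer one.  The overall share per covariate
is the eigenvalue-weighted mean over the K retained components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MetabolomicsDataset, ValidationError

__all__ = ["Covariate", "PCPR2Result", "run_pcpr2", "plot_pcpr2", "parse_covariates"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Covariate:
    """One explanatory variable; ``parent`` declares nesting (inner@outer)."""

    name: str
    parent: str | None = None

    @property
    def label(self) -> str:
        return self.name if self.parent is None else f"{self.name}@{self.parent}"


def parse_covariates(spec: list[str] | list[Covariate]) -> list[Covariate]:
    """Parse ``["study", "batch@study", "age"]``-style covariate lists."""
    out: list[Covariate] = []
    for item in spec:
        if isinstance(item, Covariate):
            out.append(item)
        elif "@" in item:
            inner, outer = item.split("@", 1)
            out.append(Covariate(inner, outer))
        else:
            out.append(Covariate(item))
    names = [c.name for c in out]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate covariates: {names}")
    for c in out:
        if c.parent is not None and c.parent not in names:
            raise ValidationError(f"nested covariate {c.name!r} declares parent {c.parent!r} not in the list")
    return out


@dataclass
class PCPR2Result:
    n_components: int
    eigenvalues: np.ndarray                 # K retained eigenvalues
    explained_variance_ratio: np.ndarray    # K, of total variance
    covariates: list[str]                   # display labels, nesting annotated
    component_partial_r2: pd.DataFrame      # K x Q
    overall_partial_r2: pd.Series           # Q, eigenvalue-weighted means
    n_samples_used: int
    n_samples_dropped: int

    @property
    def total_explained(self) -> float:
        """Sum over covariates of their overall partial R2."""
        return float(self.overall_partial_r2.sum())

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "overall_partial_r2": self.overall_partial_r2.to_dict(),
            "component_partial_r2": self.component_partial_r2.to_dict(orient="list"),
            "total_explained": self.total_explained,
            "n_samples_used": self.n_samples_used,
            "n_samples_dropped": self.n_samples_dropped,
        }


def design_columns(series: pd.Series) -> np.ndarray:
    """Expand one covariate into design columns.

    Categorical (non-numeric) covariates use treatment contrasts with the
    first observed level as reference; numeric covariates contribute a
    single column.  Partial R2 is contrast-coding invariant, so the
    reference choice is cosmetic.
    """
    if pd.api.types.is_numeric_dtype(series):
        col = series.to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ValidationError(f"covariate {series.name!r} is constant")
        return col[:, None]
    codes, levels = pd.factorize(series.astype(str))
    if len(levels) < 2:
        raise ValidationError(f"covariate {series.name!r} is constant")
    out = np.zeros((len(series), len(levels) - 1))
    for j in range(1, len(levels)):
        out[codes == j, j - 1] = 1.0
    return out


def _sse(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    """Residual sum of squares of y on [intercept | blocks].

    Uses a least-squares solve, so rank-deficient (collinear) designs are
    handled: the SSE is the squared distance to the column span.
    """
    x = np.column_stack([np.ones(len(y))] + blocks) if blocks else np.ones((len(y), 1))
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def run_pcpr2(
    data: MetabolomicsDataset,
    covariates: list[str] | list[Covariate],
    variance_threshold: float = 0.80,
    scale: bool = True,
) -> PCPR2Result:
    """Run PC-PR2 on a log-scale dataset.

    Metabolites are centered and (by default) scaled to unit variance
    before the PCA, so the decomposition operates on correlation-scale
    variation and is invariant to per-metabolite affine rescaling.
    Samples with missing values in any listed covariate are dropped from
    the component regressions only (the PCA uses all samples); the count
    is logged on the result.
    """
    covs = parse_covariates(covariates)
    meta = data.metadata
    for c in covs:
        if c.name not in meta.columns:
            raise ValidationError(f"covariate {c.name!r} not in metadata")

    x = data.values.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            zero = data.metabolites[sd == 0].tolist()
            raise ValidationError(f"zero-variance metabolites cannot be standardized: {zero}")
        x = x / sd
    n = x.shape[0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    total_var = eig.sum()
    cum = np.cumsum(eig) / total_var
    k = int(np.searchsorted(cum, variance_threshold, side="right")) + 1
    k = min(k, len(eig))
    scores = u[:, :k] * s[:k]

    # listwise-complete subset for the regressions
    sub = meta[[c.name for c in covs]]
    complete = ~sub.isna().any(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("PC-PR2: dropping %d samples with missing covariate values", n_drop)
    scores_c = scores[complete.to_numpy()]
    meta_c = meta.loc[complete]
    n_used = len(meta_c)

    blocks = {c.name: design_columns(meta_c[c.name]) for c in covs}
    p_cols = 1 + sum(b.shape[1] for b in blocks.values())
    if p_cols >= n_used:
        raise ValidationError(
            f"design has {p_cols} columns for {n_used} samples; merge categorical levels"
        )

    children = {c.parent: c.name for c in covs if c.parent is not None}
    r2 = np.zeros((k, len(covs)))
    warned: set[str] = set()
    for qi, c in enumerate(covs):
        if c.parent is not None:
            # inner of a nested pair: condition on everything else incl. parent
            reduced_names = [o.name for o in covs if o.name != c.name]
        elif c.name in children:
            # outer of a nested pair: the child is excluded from both models
            reduced_names = [o.name for o in covs if o.name not in (c.name, children[c.name])]
        else:
            reduced_names = [o.name for o in covs if o.name != c.name]
        reduced = [blocks[nm] for nm in reduced_names]
        full = reduced + [blocks[c.name]]
        rank_red = np.linalg.matrix_rank(np.column_stack([np.ones(n_used)] + reduced) if reduced else np.ones((n_used, 1)))
        rank_full = np.linalg.matrix_rank(np.column_stack([np.ones(n_used)] + full))
        if rank_full == rank_red and c.name not in warned:
            warnings.warn(f"covariate {c.name!r} is fully confounded with earlier covariates; partial R2 set to 0")
            warned.add(c.name)
        for ki in range(k):
            y = scores_c[:, ki]
            sse_red = _sse(y, reduced)
            sse_full = _sse(y, full)
            r2[ki, qi] = 0.0 if sse_red <= 0 else max(0.0, (sse_red - sse_full) / sse_red)

    labels = [c.label for c in covs]
    weights = eig[:k] / eig[:k].sum()
    overall = pd.Series(weights @ r2, index=labels)
    return PCPR2Result(
        n_components=k,
        eigenvalues=eig[:k],
        explained_variance_ratio=eig[:k] / total_var,
        covariates=labels,
        component_partial_r2=pd.DataFrame(r2, index=[f"PC{i+1}" for i in range(k)], columns=labels),
        overall_partial_r2=overall,
        n_samples_used=n_used,
        n_samples_dropped=n_drop,
    )


def plot_pcpr2(result: PCPR2Result, out_path: str, title: str | None = None) -> str:
    """Bar chart of each covariate's overall partial R2 (in %) plus the total."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(result.overall_partial_r2.index) + ["Total"]
    heights = [100 * v for v in result.overall_partial_r2] + [100 * result.total_explained]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(labels)), 4))
    ax.bar(labels, heights, color=["#4878a8"] * (len(labels) - 1) + ["#b04848"])
    ax.set_ylabel("% of total variation explained")
    if title:
        ax.set_title(title)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
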