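"""Restricted-maximum-likelihood engine for variance-components models.

Fits, for a single response vector,

    y = W beta + sum_r Z_r b_r + eps,
    b_r ~ N(0, tau_r^2 I),   eps_i ~ N(0, sigma^2_{g(i)}),

where each Z_r is the indicator matrix of one grouping factor (e.g. study,
or batch nested within study) and the residual variance may differ across
a grouping of the samples (e.g. per study).  Random effects are mutually
independent with diagonal covariance.

The restricted likelihood is maximized over variance ratios with the
global scale profiled out analytically.  All per-iteration algebra runs
on per-residual-group sufficient statistics (Z'Z, Z'W, W'W, ... blocks),
so one likelihood evaluation costs O(q^3 + p^3) in the number of random
levels q and fixed coefficients p, independent of the sample count — that
is what makes fitting hundreds of metabolites, and parametric bootstraps,
cheap.

The marginal covariance V0 = D + Z Lambda Z' is inverted with the
Woodbury identity in the symmetric form

    V0^{-1} = D^{-1} - D^{-1} Z S (I + S Z' D^{-1} Z S)^{-1} S Z' D^{-1},

with S = diag(sqrt(lambda)), which stays well-defined when a variance
ratio hits the zero boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["RandomTerm", "REMLFit", "REMLConvergenceError", "fit_variance_components"]

_LOG_LAMBDA_MIN = -25.0  # e^-25 ~ 1e-11: effectively the zero boundary
_LOG_LAMBDA_MAX = 18.0   # variance ratios beyond e^18 are boundary-equivalent
_LOG_WEIGHT_MAX = 8.0    # residual-variance ratios across groups
_BOUNDARY_TOL = 1e-8


def _chol(a: np.ndarray) -> np.ndarray:
    """Cholesky with escalating jitter; raises only if hopeless."""
    if a.shape[0] == 0:
        return a.copy()
    jitter = 0.0
    scale = np.mean(np.diag(a)) or 1.0
    for _ in range(4):
        try:
            return np.linalg.cholesky(a + jitter * np.eye(a.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 100, 1e-12 * scale)
    raise np.linalg.LinAlgError("matrix not positive definite")


class REMLConvergenceError(RuntimeError):
    """Raised when the optimizer fails; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[np.ndarray, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class RandomTerm:
    """One random-intercept term: a name and a per-sample level index."""

    name: str
    levels: tuple
    index: np.ndarray  # (n,) integer level index per sample

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomTerm":
        codes, levels = pd.factorize(pd.Series(labels).astype(str))
        return cls(name, tuple(levels), codes)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class REMLFit:
    """Result of one restricted-maximum-likelihood fit."""

    beta: pd.Series                       # fixed effects, named
    variance_components: dict[str, float]  # per random term: tau_r^2
    residual_variances: pd.Series          # per residual group: sigma_g^2
    random_effects: dict[str, pd.Series]   # per term: conditional modes by level
    residuals: np.ndarray                  # conditional residuals e
    fitted: np.ndarray                     # y - e
    loglike: float                         # restricted log-likelihood
    converged: bool
    n_iter: int
    boundary_terms: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def residual_variance(self) -> float:
        """Single residual variance (homoscedastic fits)."""
        return float(self.residual_variances.iloc[0])


def _design_stats(w: np.ndarray, z: np.ndarray, y: np.ndarray, group_index: np.ndarray, n_groups: int):
    """Per-residual-group cross-product blocks."""
    stats = []
    for g in range(n_groups):
        rows = group_index == g
        wg, zg, yg = w[rows], z[rows], y[rows]
        stats.append({
            "ZtZ": zg.T @ zg, "ZtW": zg.T @ wg, "WtW": wg.T @ wg,
            "Zty": zg.T @ yg, "Wty": wg.T @ yg, "yty": float(yg @ yg),
            "n": int(rows.sum()),
        })
    return stats


def fit_variance_components(
    y: np.ndarray,
    w: np.ndarray,
    random_terms: list[RandomTerm],
    *,
    fixed_names: list[str] | None = None,
    residual_groups: np.ndarray | None = None,
    residual_group_labels: list | None = None,
    rtol: float = 1e-8,
    max_iter: int = 500,
) -> REMLFit:
    """Fit the variance-components model by REML.

    Parameters
    ----------
    y : (n,) response
    w : (n, p) fixed-effects design (must include the intercept column)
    random_terms : random-intercept grouping factors (may be empty)
    residual_groups : optional (n,) integer group index for per-group
        residual variances; omit for a homoscedastic fit.
    rtol : relative tolerance on the restricted likelihood.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = w.shape
    if np.linalg.matrix_rank(w) < p:
        raise ValueError("fixed-effects design is rank deficient")
    # internal column scaling (pure reparameterization; beta is unscaled at the end)
    col_scale = np.linalg.norm(w, axis=0) / np.sqrt(n)
    col_scale[col_scale == 0] = 1.0
    w = w / col_scale
    if residual_groups is None:
        residual_groups = np.zeros(n, dtype=int)
        residual_group_labels = ["residual"]
    n_groups = int(residual_groups.max()) + 1
    if residual_group_labels is None:
        residual_group_labels = [str(g) for g in range(n_groups)]

    # dense random-effects design (indicator columns); q is small
    col_slices: list[slice] = []
    q = 0
    for t in random_terms:
        col_slices.append(slice(q, q + t.n_levels))
        q += t.n_levels
    z = np.zeros((n, q))
    for t, sl in zip(random_terms, col_slices):
        z[np.arange(n), sl.start + t.index] = 1.0

    gstats = _design_stats(w, z, y, residual_groups, n_groups)
    n_terms = len(random_terms)
    n_par = n_terms + (n_groups - 1)

    def unpack(theta):
        lam = np.exp(theta[:n_terms])
        wts = np.ones(n_groups)
        if n_groups > 1:
            wts[1:] = np.exp(theta[n_terms:])
        lam_cols = np.concatenate([np.full(t.n_levels, l) for t, l in zip(random_terms, lam)]) if n_terms else np.zeros(0)
        return lam, wts, lam_cols

    def core(theta):
        """Profiled REML pieces for one parameter value."""
        _, wts, lam_cols = unpack(theta)
        inv_w = 1.0 / wts
        ztz = sum(iw * g["ZtZ"] for iw, g in zip(inv_w, gstats)) if q else np.zeros((0, 0))
        ztw = sum(iw * g["ZtW"] for iw, g in zip(inv_w, gstats)) if q else np.zeros((0, p))
        wtw = sum(iw * g["WtW"] for iw, g in zip(inv_w, gstats))
        zty = sum(iw * g["Zty"] for iw, g in zip(inv_w, gstats)) if q else np.zeros(0)
        wty = sum(iw * g["Wty"] for iw, g in zip(inv_w, gstats))
        yty = sum(iw * g["yty"] for iw, g in zip(inv_w, gstats))

        s = np.sqrt(lam_cols)
        m = np.eye(q) + (s[:, None] * ztz * s[None, :])
        lm = _chol(m)
        # helper: a' V0^{-1} b given Z'D^{-1}a and Z'D^{-1}b blocks
        sa_w = s[:, None] * ztw          # S Z'D^-1 W
        sa_y = s * zty
        t_w = np.linalg.solve(lm, sa_w)  # q x p
        t_y = np.linalg.solve(lm, sa_y)
        wvw = wtw - t_w.T @ t_w          # W' V0^-1 W
        wvy = wty - t_w.T @ t_y
        yvy = yty - t_y @ t_y
        lw = _chol(wvw)
        beta = np.linalg.solve(lw.T, np.linalg.solve(lw, wvy))
        quad = yvy - beta @ wvy
        quad = max(quad, 1e-300)
        logdet_v0 = 2 * np.log(np.diag(lm)).sum() + sum(g["n"] * np.log(wt) for g, wt in zip(gstats, wts))
        logdet_wvw = 2 * np.log(np.diag(lw)).sum()
        phi = quad / (n - p)
        m2ll = ((n - p) * (np.log(2 * np.pi * phi) + 1) + logdet_v0 + logdet_wvw)
        return m2ll, phi, beta, (lm, s, ztz, ztw, zty)

    trace: list[tuple[np.ndarray, float]] = []

    def objective(theta):
        try:
            m2ll = core(theta)[0]
        except np.linalg.LinAlgError:
            m2ll = 1e12
        trace.append((theta.copy(), m2ll))
        return m2ll

    if n_par == 0:
        theta_hat = np.zeros(0)
        converged, n_iter, message = True, 0, "closed form (no variance ratios)"
    else:
        theta0 = _starting_values(y, w, z, col_slices, residual_groups, n_groups, n_terms)
        bounds = ([(_LOG_LAMBDA_MIN, _LOG_LAMBDA_MAX)] * n_terms
                  + [(-_LOG_WEIGHT_MAX, _LOG_WEIGHT_MAX)] * (n_groups - 1))
        res = optimize.minimize(
            objective, theta0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": rtol * 1e-2, "gtol": 1e-7, "maxiter": max_iter},
        )
        cliff = any(v >= 1e11 for _, v in trace)
        if not res.success or cliff or res.nit <= 3:
            # the quasi-Newton path is unreliable near boundaries or after a
            # failed factorization; polish derivative-free from the best point
            best = min(trace, key=lambda t: t[1])[0]
            res2 = optimize.minimize(
                objective, best, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": rtol, "maxiter": 400 * (n_par + 1)},
            )
            res2.x = np.clip(res2.x, [b[0] for b in bounds], [b[1] for b in bounds])
            if res2.fun <= res.fun:
                res = res2
            if not (res.success or res2.success):
                raise REMLConvergenceError(f"REML optimizer failed: {res.message}", trace)
        theta_hat = res.x
        converged, n_iter, message = True, int(res.nit), str(res.message)

    m2ll, phi, beta, (lm, s, ztz, ztw, zty) = core(theta_hat)
    lam, wts, lam_cols = unpack(theta_hat)

    # BLUPs: b = Lambda Z' V0^{-1} (y - W beta) (the scale phi cancels)
    if q:
        zt_r = zty - ztw @ beta  # Z' D^-1 (y - W beta)
        rhs = np.linalg.solve(lm, s * zt_r)
        rhs = np.linalg.solve(lm.T, rhs)
        zv_r = zt_r - ztz @ (s * rhs)  # Z' V0^-1 r
        b_hat = lam_cols * zv_r
    else:
        b_hat = np.zeros(0)

    fitted = w @ beta + (z @ b_hat if q else 0.0)
    e = y - fitted

    boundary = [t.name for t, l in zip(random_terms, lam) if l * phi < _BOUNDARY_TOL * max(phi, 1e-300)]
    for name in boundary:
        warnings.warn(f"random-effect variance for {name!r} estimated at the zero boundary")

    beta = beta / col_scale
    names = fixed_names if fixed_names is not None else [f"x{j}" for j in range(p)]
    ranef = {
        t.name: pd.Series(b_hat[sl], index=list(t.levels))
        for t, sl in zip(random_terms, col_slices)
    }
    return REMLFit(
        beta=pd.Series(beta, index=names),
        variance_components={t.name: float(l * phi) for t, l in zip(random_terms, lam)},
        residual_variances=pd.Series(wts * phi, index=residual_group_labels),
        random_effects=ranef,
        residuals=e,
        fitted=fitted,
        # report the likelihood in the unscaled-design basis (the REML
        # criterion's log|W'V^-1 W| term depends on the basis of W)
        loglike=-0.5 * (m2ll + 2 * np.log(col_scale).sum()),
        converged=converged,
        n_iter=n_iter,
        boundary_terms=boundary,
        message=message,
    )

def _starting_values(y, w, z, col_slices, groups, n_groups, n_terms):
    """Moment-based initial variance ratios from OLS residuals."""
    beta0, _, _, _ = np.linalg.lstsq(w, y, rcond=None)
    r = y - w @ beta0
    var_r = max(r.var(ddof=1), 1e-300)
    lam0 = np.empty(n_terms)
    for t, sl in enumerate(col_slices):
        zt = z[:, sl]
        counts = zt.sum(axis=0)
        counts[counts == 0] = 1
        means = (zt.T @ r) / counts
        between = means.var(ddof=1) - var_r * np.mean(1.0 / counts) if len(counts) > 1 else 0.0
        lam0[t] = np.clip(between / var_r, 1e-2, 1e3)
    theta0 = np.log(lam0)
    if n_groups > 1:
        v0 = np.array([max(r[groups == g].var(ddof=1), 1e-300) for g in range(n_groups)])
        theta0 = np.concatenate([theta0, np.clip(np.log(v0[1:] / v0[0]), -5, 5)])
    return theta0
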