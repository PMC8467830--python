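"""PC-PR2 against an explicit SSE-regression oracle.

The oracle below builds every reduced/full regression separately with
statsmodels OLS and applies the partial-R2 formulas directly (including
the nested study/batch convention); the implementation under test uses a
different path (projection SSEs via least-squares on column spans).
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from metapool.dataset import ValidationError
from metapool.pcpr2 import Covariate, parse_covariates, run_pcpr2, plot_pcpr2
from conftest import build_dataset


def oracle_pcpr2(values, meta, covariates, threshold=0.80):
    """Brute-force PC-PR2: explicit OLS fit for every SSE in the formulas."""
    covs = parse_covariates(covariates)
    x = values - values.mean(axis=0)
    x = x / x.std(axis=0, ddof=1)
    n = x.shape[0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    cum = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(cum, threshold, side="right")) + 1
    scores = u[:, :k] * s[:k]

    def block(name):
        col = meta[name]
        if pd.api.types.is_numeric_dtype(col):
            return col.to_numpy(dtype=float)[:, None]
        return pd.get_dummies(col.astype(str), drop_first=True).to_numpy(dtype=float)

    def sse(y, names):
        design = np.ones((n, 1))
        if names:
            design = np.column_stack([design] + [block(nm) for nm in names])
        return float(sm.OLS(y, design).fit().ssr)

    children = {c.parent: c.name for c in covs if c.parent is not None}
    r2 = np.zeros((k, len(covs)))
    for qi, c in enumerate(covs):
        if c.parent is not None:
            reduced = [o.name for o in covs if o.name != c.name]
        elif c.name in children:
            reduced = [o.name for o in covs if o.name not in (c.name, children[c.name])]
        else:
            reduced = [o.name for o in covs if o.name != c.name]
        full = reduced + [c.name]
        for ki in range(k):
            s_red = sse(scores[:, ki], reduced)
            s_full = sse(scores[:, ki], full)
            r2[ki, qi] = (s_red - s_full) / s_red
    weights = eig[:k] / eig[:k].sum()
    return r2, weights @ r2, eig[:k]


@pytest.fixture(scope="module")
def two_study_dataset():
    """200 x 10 with a 2-sigma study shift, nested batches and 2 covariates."""
    rng = np.random.default_rng(21)
    n, p = 200, 10
    studies = np.repeat(["A", "B"], n // 2)
    batches = [f"{s}::b{k}" for s, k in zip(studies, rng.integers(1, 3, n))]
    gender = rng.choice(["M", "F"], n)
    bmi = rng.normal(26, 4, n)
    shift = np.where(studies == "A", 0.0, 2.0)
    x = rng.normal(0, 1, (n, p)) + shift[:, None]
    x += 0.05 * (bmi - 26)[:, None]
    return build_dataset(np.exp(x), studies, batches, gender=gender, bmi=bmi)


class TestOracleEquivalence:
    def test_matches_brute_force_to_1e10(self, two_study_dataset):
        ds = two_study_dataset
        covs = ["gender", "bmi", "study", "batch@study"]
        res = run_pcpr2(ds.with_values(np.log(ds.values), scale="log"), covs)
        r2_ref, overall_ref, eig_ref = oracle_pcpr2(
            np.log(ds.values.to_numpy()), ds.metadata, covs)
        assert res.component_partial_r2.shape == r2_ref.shape
        np.testing.assert_allclose(res.component_partial_r2.to_numpy(), r2_ref, atol=1e-10)
        np.testing.assert_allclose(res.overall_partial_r2.to_numpy(), overall_ref, atol=1e-10)
        np.testing.assert_allclose(res.eigenvalues, eig_ref, rtol=1e-12)

    def test_nested_batch_never_credited_with_study_variation(self, two_study_dataset):
        """Pure study shift, no real batch effect: batch's conditional share
        stays near zero even though batch labels also separate the studies."""
        ds = two_study_dataset
        res = run_pcpr2(ds.with_values(np.log(ds.values), scale="log"),
                        ["bmi", "study", "batch@study"])
        assert res.overall_partial_r2["study"] > 0.2
        assert res.overall_partial_r2["batch@study"] < 0.05


class TestElementaryCases:
    def _simple(self, n=60, p=4, seed=3):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (n, p))
        return x, rng

    def test_covariate_equal_to_pc1_scores_has_r2_one(self):
        x, rng = self._simple()
        n = x.shape[0]
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        u, s, _ = np.linalg.svd(xs, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        ds = build_dataset(np.exp(x), ["A"] * n, ["A::b"] * n, pc1=pc1)
        res = run_pcpr2(ds.with_values(np.log(ds.values), scale="log"), ["pc1"],
                        variance_threshold=0.01)
        assert res.n_components == 1
        assert res.component_partial_r2.iloc[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_covariate_has_zero_r2(self):
        x, rng = self._simple()
        n = x.shape[0]
        w = rng.normal(0, 1, n)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        u, s, _ = np.linalg.svd(xs, full_matrices=False)
        scores = u * s
        # project out every component -> exactly orthogonal covariate
        w = w - scores @ np.linalg.lstsq(scores, w, rcond=None)[0]
        ds = build_dataset(np.exp(x), ["A"] * n, ["A::b"] * n, w=w)
        res = run_pcpr2(ds.with_values(np.log(ds.values), scale="log"), ["w"],
                        variance_threshold=0.9999)
        assert res.overall_partial_r2["w"] == pytest.approx(0.0, abs=1e-10)

    def test_balanced_one_way_matches_direct_variance_share(self):
        """With all components retained and one categorical covariate, the
        eigenvalue-weighted overall R2 equals the multivariate
        between-group share of the standardized matrix."""
        rng = np.random.default_rng(9)
        n, p = 90, 5
        groups = np.repeat(["g1", "g2", "g3"], n // 3)
        x = rng.normal(0, 1, (n, p)) + (groups == "g2")[:, None] * 1.5
        ds = build_dataset(np.exp(x), ["A"] * n, ["A::b"] * n, grp=groups)
        res = run_pcpr2(ds.with_values(np.log(ds.values), scale="log"), ["grp"],
                        variance_threshold=1.0)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        fitted = np.vstack([xs[groups == g].mean(0) for g in ["g1", "g2", "g3"]])
        between = sum(((fitted[i] ** 2) * (groups == g).sum()).sum()
                      for i, g in enumerate(["g1", "g2", "g3"]))
        direct = between / (xs**2).sum()
        assert res.total_explained == pytest.approx(direct, abs=1e-10)


class TestInvariances:
    def test_column_order_and_rescaling_invariance(self, two_study_dataset):
        ds = two_study_dataset
        logds = ds.with_values(np.log(ds.values), scale="log")
        covs = ["gender", "bmi", "study", "batch@study"]
        base = run_pcpr2(logds, covs)
        perm = list(logds.metabolites[::-1])
        v2 = logds.values[perm].copy()
        v2[perm[0]] = v2[perm[0]] * 3.0 + 1.0  # affine change of one metabolite
        res2 = run_pcpr2(logds.with_values(v2, codes=logds.codes[perm]), covs)
        np.testing.assert_allclose(res2.overall_partial_r2, base.overall_partial_r2, atol=1e-8)

    def test_constant_covariate_rejected(self, two_study_dataset):
        ds = two_study_dataset
        logds = ds.with_values(np.log(ds.values), scale="log")
        logds.metadata["const"] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            run_pcpr2(logds, ["const", "study"])

    def test_confounded_covariate_warned_and_zero(self, two_study_dataset):
        ds = two_study_dataset
        logds = ds.with_values(np.log(ds.values), scale="log")
        logds.metadata["study_copy"] = logds.metadata["study"].values
        with pytest.warns(UserWarning, match="confounded"):
            res = run_pcpr2(logds, ["study", "study_copy"])
        assert res.overall_partial_r2["study_copy"] == pytest.approx(0.0, abs=1e-10)

    def test_every_r2_in_unit_interval(self, imputed):
        res = run_pcpr2(imputed, ["center", "gender", "bmi", "study", "batch@study"])
        r2 = res.component_partial_r2.to_numpy()
        assert ((r2 >= 0) & (r2 <= 1)).all()
        assert ((res.overall_partial_r2 >= 0) & (res.overall_partial_r2 <= 1)).all()


def test_plot_writes_file(two_study_dataset, tmp_path):
    ds = two_study_dataset
    res = run_pcpr2(ds.with_values(np.log(ds.values), scale="log"), ["study", "bmi"])
    out = plot_pcpr2(res, str(tmp_path / "pcpr2.png"))
    import os
    assert os.path.getsize(out) > 0
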