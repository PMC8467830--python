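import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest

from metapool.dataset import Code, MetabolomicsDataset, ValidationError
from metapool.normalization import (
    NormalizationSpec,
    combat_normalize,
    correlate_with_phenotype,
    fit_metabolite_model,
    normalize_dataset,
    pca_residual_normalize,
)
from metapool.simulate import generate, make_config
from conftest import build_dataset


def _log_dataset(x, studies, batches, **meta):
    ds = build_dataset(np.exp(x), studies, batches, **meta)
    return ds.with_values(pd.DataFrame(np.asarray(x, dtype=float),
                                       index=ds.sample_ids, columns=ds.metabolites),
                          scale="log")


class TestSpecValidation:
    def test_x_z_overlap_rejected(self):
        with pytest.raises(ValidationError, match="both X and Z"):
            NormalizationSpec(x_random=("study",), z_fixed=("study",))

    def test_unknown_variance_structure_rejected(self):
        with pytest.raises(ValidationError):
            NormalizationSpec(variance_structure="banana")


class TestMixedModelNormalization:
    def test_empty_x_is_centering(self):
        """With nothing to remove and nothing to preserve, u = y - a."""
        rng = np.random.default_rng(0)
        y = rng.normal(3, 1, (40, 2))
        ds = _log_dataset(y, ["A"] * 40, ["A::b"] * 40)
        out, models = normalize_dataset(ds, NormalizationSpec(x_random=(), z_fixed=()))
        for met in ds.metabolites:
            np.testing.assert_allclose(
                out.values[met], ds.values[met] - models[met].intercept, rtol=1e-10)

    def test_batch_shifts_removed(self):
        """Injected batch shifts, empty Z: per-batch means of u are ~0."""
        rng = np.random.default_rng(1)
        n_b, nb = 8, 30
        batch = np.repeat([f"A::b{i}" for i in range(n_b)], nb)
        shift = rng.normal(0, 1.5, n_b)
        y = 2 + np.repeat(shift, nb)[:, None] + rng.normal(0, 0.5, (n_b * nb, 1))
        ds = _log_dataset(y, ["A"] * (n_b * nb), batch)
        out, _ = normalize_dataset(ds, NormalizationSpec(x_random=("batch",), z_fixed=()))
        means = out.values.groupby(ds.metadata["batch"]).mean()["m0"]
        se = 0.5 / np.sqrt(nb)
        assert (means.abs() < 3 * se).all()

    def test_blup_shrinkage_closed_form(self):
        """One balanced random term, no Z: the predicted batch effects equal
        the shrinkage factor tau2/(tau2 + sigma2/n_b) times the GLS batch-mean
        deviations (closed-form BLUP identity at the fitted variances)."""
        rng = np.random.default_rng(5)
        n_b, nb = 12, 25
        batch = np.repeat(np.arange(n_b), nb)
        y = 1 + rng.normal(0, 0.8, n_b)[batch] + rng.normal(0, 0.6, n_b * nb)
        ds = _log_dataset(y[:, None], ["A"] * (n_b * nb),
                          [f"A::b{i}" for i in batch])
        model = fit_metabolite_model(y, ds.metadata, NormalizationSpec(
            x_random=("batch",), z_fixed=()))
        fit = model.fit
        tau2 = fit.variance_components["batch"]
        sig2 = fit.residual_variance
        shrink = tau2 / (tau2 + sig2 / nb)
        mu = fit.beta.iloc[0]
        batch_means = pd.Series(y).groupby(batch).mean()
        expected = shrink * (batch_means - mu)
        got = fit.random_effects["batch"].to_numpy()
        np.testing.assert_allclose(got, expected.to_numpy(), rtol=1e-6)

    def test_confounded_gender_effect_preserved(self):
        """Gender effect confounded with study survives normalization while
        study-level shifts are removed."""
        cfg = make_config(seed=13, n_metabolites=20, n_effect_metabolites=20,
                          lod_quantile=0.0, lloq_quantile=0.0, missing_rate=0.0,
                          gender_effect=1.0)
        data, truth = generate(cfg)
        from metapool.imputation import impute
        imp, _ = impute(data)
        out, _ = normalize_dataset(imp, NormalizationSpec())
        fem = (out.metadata["gender"] == "F").to_numpy(dtype=float)
        bmi = out.metadata["bmi"].to_numpy()
        est = []
        for met in out.metabolites:
            x = np.column_stack([np.ones(len(fem)), fem, bmi])
            est.append(np.linalg.lstsq(x, out.values[met], rcond=None)[0][1])
        assert np.mean(est) == pytest.approx(1.0, rel=0.10)
        # and per-study means within one gender are equalized
        women = out.metadata["gender"] == "F"
        study_means = out.values.loc[women, out.metabolites[0]].groupby(
            out.metadata.loc[women, "study"]).mean()
        assert study_means.std() < 0.25


class TestHeteroscedastic:
    def test_rescaled_pearson_variance_matches_standard_residuals(self, imputed):
        spec = NormalizationSpec(variance_structure="per_group")
        met = imputed.metabolites[0]
        model = fit_metabolite_model(imputed.values[met].to_numpy(),
                                     imputed.metadata, spec, met)
        e = model.fit.residuals
        g = pd.factorize(imputed.metadata["study"])[0]
        sd = np.sqrt(model.fit.residual_variances.to_numpy())[g]
        pearson = e / sd
        scale = e.std(ddof=1) / pearson.std(ddof=1)
        assert abs(np.var(pearson * scale, ddof=1) - np.var(e, ddof=1)) < 1e-10
        # the normalized output embeds exactly these rescaled residuals
        zc = model.z_columns @ model.z_coef
        np.testing.assert_allclose(model.normalized, pearson * scale + zc, rtol=1e-10)

    def test_single_variance_group_equals_homoscedastic(self):
        """Degenerate per-group structure (one group) is exactly the
        homoscedastic model."""
        rng = np.random.default_rng(2)
        n = 200
        batch = np.repeat([f"A::b{i}" for i in range(5)], 40)
        y = rng.normal(0, 1, 5)[np.repeat(np.arange(5), 40)] + rng.normal(0, 0.7, n)
        ds = _log_dataset(y[:, None], ["A"] * n, batch, allgrp="g1")
        spec_h = NormalizationSpec(x_random=("batch",), z_fixed=(),
                                   variance_structure="per_group", variance_group="allgrp")
        spec_o = NormalizationSpec(x_random=("batch",), z_fixed=())
        out_h, _ = normalize_dataset(ds, spec_h)
        out_o, _ = normalize_dataset(ds, spec_o)
        np.testing.assert_allclose(out_h.values.to_numpy(), out_o.values.to_numpy(), atol=1e-8)

    def test_equal_true_variances_give_consistent_estimates_and_outputs(self, imputed):
        """All studies share sigma^2 = 0.5: per-study estimates agree within
        sampling error (~sqrt(2/n_s)) and the two outputs are nearly the
        same signal (their agreement is limited only by that noise)."""
        out_o, _ = normalize_dataset(imputed, NormalizationSpec())
        out_h, mh = normalize_dataset(imputed, NormalizationSpec(variance_structure="per_group"))
        n_s = imputed.metadata.groupby("study").size().min()
        band = 4 * np.sqrt(2.0 / n_s)  # ~4 relative SDs of a variance estimate
        for met in imputed.metabolites[:10]:
            v = mh[met].fit.residual_variances
            assert v.max() / v.min() < 1 + 3 * band
            r = np.corrcoef(out_o.values[met], out_h.values[met])[0, 1]
            assert r > 0.99


class TestComBat:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, (30, 5))
        ds = _log_dataset(y, ["A"] * 30, ["A::b"] * 30)
        out = combat_normalize(ds)
        np.testing.assert_allclose(out.values.to_numpy(), y, atol=1e-12)

    def test_shrinkage_orders_batch_adjustments(self):
        """Batch locations are shrunk toward the cross-metabolite mean shift:
        each per-metabolite location estimate lies between its raw value and
        the pooled prior mean."""
        rng = np.random.default_rng(8)
        n, p = 60, 40
        batch = np.array(["A::b1"] * 30 + ["A::b2"] * 30)
        true_shift = 1.0 + rng.normal(0, 0.3, p)  # similar but not equal shifts
        y = rng.normal(0, 1, (n, p))
        y[30:] += true_shift
        ds = _log_dataset(y, ["A"] * n, batch)
        out = combat_normalize(ds)
        # batch means equalized
        d = out.values.iloc[30:].mean() - out.values.iloc[:30].mean()
        assert d.abs().max() < 0.5
        raw_shift = pd.DataFrame(y[30:]).mean() - pd.DataFrame(y[:30]).mean()
        resid_raw = (out.values.iloc[30:].mean().to_numpy()
                     - out.values.iloc[:30].mean().to_numpy())
        # shrinkage toward the pooled shift: the residual per-metabolite shift
        # keeps the sign of (raw - pooled) but is strictly smaller, i.e. the
        # adjustment lies between the raw shift and the pooled shift
        dev = raw_shift.to_numpy() - raw_shift.mean()
        mask = np.abs(dev) > 0.2
        assert (np.sign(resid_raw[mask]) == np.sign(dev[mask])).all()
        assert (np.abs(resid_raw[mask]) < np.abs(dev[mask])).all()

    def test_matches_bioconductor_sva(self, tmp_path):
        """Independent oracle: sva::ComBat on the same matrix."""
        rng = np.random.default_rng(42)
        n_per, B, p = 25, 3, 12
        batch = np.repeat([f"A::b{i}" for i in range(B)], n_per)
        n = B * n_per
        bi = pd.factorize(batch)[0]
        shift = rng.normal(0, 1, (B, p))
        scale = np.exp(rng.normal(0, 0.3, B))
        age = rng.normal(50, 8, n)
        y = 5 + rng.normal(0, 1, (n, p)) * scale[bi][:, None] + shift[bi] + 0.03 * (age - 50)[:, None]
        ds = _log_dataset(y, ["A"] * n, batch, age=age)

        pd.DataFrame(y.T, columns=[f"s{i}" for i in range(n)]).to_csv(tmp_path / "y.csv", index=False)
        pd.DataFrame({"batch": batch, "age": age}).to_csv(tmp_path / "meta.csv", index=False)
        script = f"""
suppressMessages(library(sva))
y <- as.matrix(read.csv("{tmp_path}/y.csv"))
meta <- read.csv("{tmp_path}/meta.csv")
mod <- model.matrix(~ age, data=meta)
out <- ComBat(dat=y, batch=meta$batch, mod=mod, par.prior=TRUE)
write.csv(out, "{tmp_path}/out.csv", row.names=FALSE)
"""
        (tmp_path / "run.R").write_text(script)
        res = subprocess.run(["Rscript", str(tmp_path / "run.R")],
                             capture_output=True, text=True, timeout=600)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "out.csv").to_numpy().T
        mine = combat_normalize(ds, preserve=("age",)).values.to_numpy()
        np.testing.assert_allclose(mine, ref, atol=1e-4)


class TestPCAResidual:
    def test_k_zero_is_centering(self):
        rng = np.random.default_rng(3)
        y = rng.normal(2, 1, (30, 4))
        ds = _log_dataset(y, ["A"] * 30, ["A::b"] * 30)
        out = pca_residual_normalize(ds, k=0)
        np.testing.assert_allclose(out.values.to_numpy(), y - y.mean(0), atol=1e-12)

    def test_rank_two_structure_removed(self):
        """Data = rank-2 common signal + private noise on one metabolite:
        the residual of that metabolite is (almost exactly) its noise."""
        rng = np.random.default_rng(6)
        n, p = 300, 8
        f = rng.normal(0, 1, (n, 2))
        load = rng.normal(0, 1, (2, p))
        noise = rng.normal(0, 0.05, n)
        y = f @ load
        y[:, 0] += noise
        ds = _log_dataset(y, ["A"] * n, ["A::b"] * n)
        out = pca_residual_normalize(ds, k=2)
        r = np.corrcoef(out.values["m0"], noise - noise.mean())[0, 1]
        assert r > 0.95

    def test_residuals_orthogonal_to_scores(self, imputed):
        out = pca_residual_normalize(imputed, k=2)
        x = imputed.values.to_numpy()
        xc = (x - x.mean(0)) / x.std(0, ddof=1)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        scores = u[:, :2] * s[:2]
        proj = scores.T @ out.values.to_numpy()
        assert np.abs(proj).max() < 1e-8 * np.abs(x).max() * len(x)

    def test_k_at_least_rank_rejected(self):
        y = np.random.default_rng(1).normal(0, 1, (10, 3))
        ds = _log_dataset(y, ["A"] * 10, ["A::b"] * 10)
        with pytest.raises(ValidationError, match="rank"):
            pca_residual_normalize(ds, k=3)


class TestPhenotypeCorrelation:
    def test_metabolite_equal_to_phenotype(self):
        rng = np.random.default_rng(7)
        ph = rng.normal(25, 4, 50)
        ds = _log_dataset(ph[:, None], ["A"] * 50, ["A::b"] * 50, bmi=ph,
                          subject_id=[f"p{i}" for i in range(50)])
        r = correlate_with_phenotype(ds, "bmi")
        assert r.iloc[0] == pytest.approx(1.0)

    def test_independent_metabolite_near_zero(self):
        rng = np.random.default_rng(12)
        n = 1000
        ds = _log_dataset(rng.normal(0, 1, (n, 1)), ["A"] * n, ["A::b"] * n,
                          bmi=rng.normal(25, 4, n),
                          subject_id=[f"p{i}" for i in range(n)])
        r = correlate_with_phenotype(ds, "bmi")
        assert abs(r.iloc[0]) < 0.1

    def test_duplicate_subjects_resolved_deterministically(self):
        rng = np.random.default_rng(9)
        n = 40
        subj = [f"p{i // 2}" for i in range(n)]  # everyone duplicated
        ds = _log_dataset(rng.normal(0, 1, (n, 2)), ["A"] * n, ["A::b"] * n,
                          bmi=rng.normal(25, 4, n), subject_id=subj)
        r1 = correlate_with_phenotype(ds, "bmi", seed=5)
        r2 = correlate_with_phenotype(ds, "bmi", seed=5)
        r3 = correlate_with_phenotype(ds, "bmi", seed=6)
        pd.testing.assert_series_equal(r1, r2)
        assert not r1.equals(r3)

    def test_constant_phenotype_rejected(self):
        ds = _log_dataset(np.zeros((5, 1)), ["A"] * 5, ["A::b"] * 5, bmi=25.0)
        with pytest.raises(ValidationError, match="constant"):
            correlate_with_phenotype(ds, "bmi")


def test_failed_metabolite_flagged_not_fatal(imputed):
    """A constant Z covariate breaks the fit for every metabolite; outputs
    pass through unnormalized with the failure flag set."""
    bad = imputed.subset()
    bad.metadata["broken"] = 1.0
    out, models = normalize_dataset(bad, NormalizationSpec(z_fixed=("broken",)))
    assert all(m.failed for m in models.values())
    pd.testing.assert_frame_equal(out.values, bad.values)
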