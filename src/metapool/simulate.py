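"""Synthetic multi-study targeted-metabolomics data with known truth.

The generator emulates the structure of pooled cohort data assayed with a
targeted kit in several case-control studies: study- and batch-level
location shifts (random intercepts on the log scale), biological
covariates unequally distributed across studies (including single-gender
studies), left-censoring at batch-specific detection limits, sporadic
fully-missing cells, and duplicate aliquots of the same subject assayed
in two batches or two studies.  Latent values are drawn on the log scale

    log y = alpha_m + u_study + b_batch + Z theta + gamma_subject + eps

and exponentiated, so positivity is guaranteed and the pipeline's log
transform exactly inverts the scale.  Every realized effect is recorded
in a :class:`GroundTruth` ledger so parameter-recovery and
removal/preservation properties can be checked against the truth.

Metabolites come in two classes mirroring targeted kits: "semi_quantified"
(one-point calibration; censored at batch-specific LODs) and "quantified"
(fully calibrated; censored at kit-level LLOQ/ULOQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import Code, LimitTable, MetabolomicsDataset, ValidationError

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "epic_like_preset", "generate_duplicates"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generating model (log-scale unless noted)."""

    n_studies: int = 8
    batches_per_study: int = 4
    samples_per_batch: int = 40
    n_metabolites: int = 30
    seed: int = 0

    # variance components
    tau2_study: float = 1.0
    tau2_batch: float = 0.25
    sigma2_residual: float = 0.5
    residual_sd_by_study: tuple[float, ...] | None = None  # overrides sigma2_residual per study
    tau2_subject: float = 0.35    # shared part of the residual for duplicate aliquots

    # metabolite baselines
    alpha_mean: float = 3.0
    alpha_sd: float = 0.5
    frac_quantified: float = 0.2  # fraction of metabolites in the "quantified" class

    # biological covariates (study-confounded by construction)
    n_effect_metabolites: int = 15   # metabolites carrying gender/BMI/alcohol effects
    gender_effect: float = 0.4       # log-scale shift for female on effect metabolites
    bmi_effect: float = 0.05         # log-scale slope per BMI unit
    alcohol_effect: float = 0.005    # log-scale slope per g/day
    center_effect_sd: float = 0.10   # per-(center, metabolite) effect SD
    fasting_effect: float = 0.02
    female_prevalence: tuple[float, ...] | None = None  # per study; default mixed + 2 single-gender
    bmi_mean_by_study: tuple[float, ...] | None = None
    bmi_sd: float = 3.5

    # missingness
    lod_quantile: float = 0.05       # left-censoring quantile per (batch, metabolite)
    lloq_quantile: float = 0.02      # kit-level, quantified metabolites
    uloq_quantile: float = 0.999
    missing_rate: float = 0.01       # MCAR fully-missing rate
    n_unknown_lod_cells: int = 1     # (batch, metabolite) pairs with withheld LOD

    # duplicate design
    n_dup_cross_batch: int = 24      # subjects assayed in two batches of one study
    n_dup_cross_study: int = 24      # subjects assayed in two studies

    # gross outliers (for exercising the cleaning step)
    n_outliers: int = 0
    outlier_shift: float = 8.0       # log-scale shift applied to outlier samples

    def validate(self) -> None:
        if min(self.n_studies, self.batches_per_study, self.samples_per_batch, self.n_metabolites) < 1:
            raise ValidationError("design dimensions must be positive")
        for name in ("tau2_study", "tau2_batch", "sigma2_residual", "tau2_subject"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.tau2_subject > self.sigma2_residual:
            raise ValidationError("tau2_subject cannot exceed sigma2_residual")
        for name in ("lod_quantile", "lloq_quantile", "uloq_quantile", "missing_rate", "frac_quantified"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        n = self.n_studies * self.batches_per_study * self.samples_per_batch
        if 2 * (self.n_dup_cross_batch + self.n_dup_cross_study) > n:
            raise ValidationError("duplicate design needs more sample slots than available")
        if self.n_dup_cross_batch > 0 and self.batches_per_study < 2:
            raise ValidationError("cross-batch duplicates need >= 2 batches per study")
        if self.n_dup_cross_study > 0 and self.n_studies < 2:
            raise ValidationError("cross-study duplicates need >= 2 studies")
        if self.n_outliers > n:
            raise ValidationError("more outliers than samples")


@dataclass
class GroundTruth:
    """Realized effects behind one generated dataset."""

    config: SyntheticConfig
    alpha: pd.Series                     # per metabolite baseline
    study_effects: pd.DataFrame          # study x metabolite
    batch_effects: pd.DataFrame          # batch x metabolite
    center_effects: pd.DataFrame         # center x metabolite
    gender_effect: pd.Series             # per metabolite (0 off effect set)
    bmi_effect: pd.Series
    alcohol_effect: pd.Series
    residual_sd_by_study: pd.Series
    true_icc: pd.Series                  # per metabolite, for the duplicate design
    duplicate_subjects: list[str] = field(default_factory=list)
    outlier_samples: list[str] = field(default_factory=list)
    metabolite_class: pd.Series | None = None


def _default_prevalence(n_studies: int) -> np.ndarray:
    # first study men-only, second women-only, the rest mixed
    prev = np.full(n_studies, 0.5)
    if n_studies >= 1:
        prev[0] = 0.0
    if n_studies >= 2:
        prev[1] = 1.0
    if n_studies >= 5:
        prev[4] = 0.6
    return prev


def epic_like_preset(seed: int = 0) -> SyntheticConfig:
    """Reduced-size preset mirroring a pooled multi-study kit dataset:
    8 studies x 4 batches x 40 samples, 30 metabolites, two single-gender
    studies, study-varying BMI, and 48 duplicate subjects."""
    return SyntheticConfig(
        n_studies=8, batches_per_study=4, samples_per_batch=40,
        n_metabolites=30, seed=seed,
        bmi_mean_by_study=(25.0, 26.5, 24.5, 27.5, 25.5, 28.0, 24.0, 26.0),
    )


def generate(config: SyntheticConfig) -> tuple[MetabolomicsDataset, GroundTruth]:
    """Generate a raw-scale dataset plus its ground-truth ledger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    S, B, Nb, p = config.n_studies, config.batches_per_study, config.samples_per_batch, config.n_metabolites
    n = S * B * Nb

    studies = [f"ST{s+1}" for s in range(S)]
    batch_labels = [f"{st}::B{b+1}" for st in studies for b in range(B)]
    mets = [f"met_{m+1:03d}" for m in range(p)]
    n_quant = int(round(config.frac_quantified * p))
    met_class = pd.Series(
        ["quantified"] * n_quant + ["semi_quantified"] * (p - n_quant), index=mets, name="class"
    )

    study_idx = np.repeat(np.arange(S), B * Nb)
    batch_idx = np.repeat(np.arange(S * B), Nb)
    sample_ids = [f"{batch_labels[b]}_{i % Nb + 1:03d}" for i, b in enumerate(batch_idx)]
    sample_ids = [sid.replace("::", "_") for sid in sample_ids]

    # --- subjects and duplicates -------------------------------------------
    subject = np.array([f"subj_{i+1:05d}" for i in range(n)], dtype=object)
    dup_subjects: list[str] = []
    pair_kind: list[str] = []
    used = np.zeros(n, dtype=bool)

    def _free_slot(mask: np.ndarray) -> int:
        avail = np.where(mask & ~used)[0]
        if len(avail) == 0:
            raise ValidationError("duplicate design infeasible: no free sample slots left")
        return int(avail[rng.integers(len(avail))])

    prev = np.asarray(config.female_prevalence if config.female_prevalence is not None
                      else _default_prevalence(S), dtype=float)
    mixed_studies = np.where((prev > 0) & (prev < 1))[0]
    for d in range(config.n_dup_cross_batch):
        s = int(rng.integers(S))
        b1, b2 = rng.choice(B, size=2, replace=False)
        i = _free_slot(batch_idx == s * B + b1); used[i] = True
        j = _free_slot(batch_idx == s * B + b2); used[j] = True
        subject[j] = subject[i]
        dup_subjects.append(subject[i]); pair_kind.append("cross_batch")
    for d in range(config.n_dup_cross_study):
        pool = mixed_studies if len(mixed_studies) >= 2 else np.arange(S)
        s1, s2 = rng.choice(pool, size=2, replace=False)
        i = _free_slot(study_idx == s1); used[i] = True
        j = _free_slot(study_idx == s2); used[j] = True
        subject[j] = subject[i]
        dup_subjects.append(subject[i]); pair_kind.append("cross_study")

    # --- subject-level covariates (shared by duplicate aliquots) -----------
    uniq_subj, first_slot = np.unique(subject, return_index=True)
    slot_of_subject = dict(zip(uniq_subj, first_slot))
    bmi_means = np.asarray(config.bmi_mean_by_study if config.bmi_mean_by_study is not None
                           else np.linspace(24.0, 28.0, S), dtype=float)

    n_centers = max(3, min(6, S))
    center_names = [f"C{c+1}" for c in range(n_centers)]

    def draw_covariates(slot: int) -> dict:
        s = study_idx[slot]
        c_pool = [(s + k) % n_centers for k in range(3)]
        return {
            "gender": "F" if rng.random() < prev[s] else "M",
            "bmi": float(np.clip(rng.normal(bmi_means[s], config.bmi_sd), 15.0, 45.0)),
            "alcohol": float(np.clip(rng.lognormal(1.8, 0.9), 0.0, 120.0)),
            "age": float(np.clip(rng.normal(55.0, 8.0), 30.0, 80.0)),
            "center": center_names[c_pool[rng.choice(3, p=[0.5, 0.3, 0.2])]],
            "smoking": rng.choice(["never", "former", "current"], p=[0.5, 0.3, 0.2]),
            "fasting": rng.choice(["no", "yes"], p=[0.6, 0.4]),
            "blood_draw_time": rng.choice(["morning", "afternoon"], p=[0.7, 0.3]),
            "case_control": rng.choice(["control", "case"]),
        }

    subj_cov = {subj: draw_covariates(slot) for subj, slot in slot_of_subject.items()}
    meta = pd.DataFrame([subj_cov[s_] for s_ in subject], index=pd.Index(sample_ids, name="sample_id"))
    meta.insert(0, "subject_id", subject)
    meta.insert(1, "study", [studies[s] for s in study_idx])
    meta.insert(2, "batch", [batch_labels[b] for b in batch_idx])

    # --- realized effects ---------------------------------------------------
    alpha = rng.normal(config.alpha_mean, config.alpha_sd, p)
    u_study = rng.normal(0.0, np.sqrt(config.tau2_study), (S, p))
    b_batch = rng.normal(0.0, np.sqrt(config.tau2_batch), (S * B, p))
    c_center = rng.normal(0.0, config.center_effect_sd, (n_centers, p))
    eff = np.zeros(p, dtype=bool)
    eff[: config.n_effect_metabolites] = True
    g_eff = np.where(eff, config.gender_effect, 0.0)
    bmi_eff = np.where(eff, config.bmi_effect, 0.0)
    alc_eff = np.where(eff, config.alcohol_effect, 0.0)

    if config.residual_sd_by_study is not None:
        sd_study = np.asarray(config.residual_sd_by_study, dtype=float)
        if len(sd_study) != S:
            raise ValidationError("residual_sd_by_study must list one SD per study")
    else:
        sd_study = np.full(S, np.sqrt(config.sigma2_residual))
    sigma2_i = sd_study[study_idx] ** 2
    extra_var = sigma2_i - config.tau2_subject
    if (extra_var < 0).any():
        raise ValidationError("tau2_subject exceeds a study's residual variance")

    # shared subject component only matters for duplicate subjects; giving it
    # to every subject keeps per-sample marginal variance exactly sigma_s^2
    gamma = {subj: rng.normal(0.0, np.sqrt(config.tau2_subject), p) for subj in uniq_subj}
    gamma_arr = np.vstack([gamma[s_] for s_ in subject])
    eps = rng.normal(0.0, 1.0, (n, p)) * np.sqrt(extra_var)[:, None]

    female = (meta["gender"] == "F").to_numpy(dtype=float)
    bmi_c = meta["bmi"].to_numpy() - bmi_means.mean()
    alc_c = meta["alcohol"].to_numpy() - meta["alcohol"].mean()
    fast = (meta["fasting"] == "yes").to_numpy(dtype=float)
    center_idx = np.array([center_names.index(c) for c in meta["center"]])

    log_y = (
        alpha[None, :]
        + u_study[study_idx]
        + b_batch[batch_idx]
        + c_center[center_idx]
        + female[:, None] * g_eff[None, :]
        + bmi_c[:, None] * bmi_eff[None, :]
        + alc_c[:, None] * alc_eff[None, :]
        + fast[:, None] * config.fasting_effect
        + gamma_arr
        + eps
    )

    outliers: list[str] = []
    if config.n_outliers:
        out_rows = rng.choice(n, size=config.n_outliers, replace=False)
        log_y[out_rows] += config.outlier_shift
        outliers = [sample_ids[i] for i in out_rows]

    raw = np.exp(log_y)

    # --- censoring at realized limits --------------------------------------
    values = pd.DataFrame(raw, index=meta.index, columns=mets)
    codes = pd.DataFrame(Code.OBSERVED.value, index=meta.index, columns=mets, dtype=object)
    limits = LimitTable()
    lod_records: dict[tuple[str, str], float] = {}
    semi = met_class == "semi_quantified"
    if config.lod_quantile > 0:
        for b in range(S * B):
            rows = batch_idx == b
            q = np.quantile(raw[rows], config.lod_quantile, axis=0)
            for mj, met in enumerate(mets):
                if not semi.iloc[mj]:
                    continue
                lod_records[(batch_labels[b], met)] = float(q[mj])
                below = rows & (raw[:, mj] < q[mj])
                codes.loc[below, met] = Code.BELOW_LOD.value
                values.loc[below, met] = np.nan
    # withhold a few LODs so the unknown-LOD imputation rule is exercised
    semi_mets = [m for m in mets if semi[m]]
    for k in range(min(config.n_unknown_lod_cells, len(lod_records))):
        if not semi_mets:
            break
        met = semi_mets[k % len(semi_mets)]
        batch = batch_labels[(2 * k + 1) % (S * B)]
        if (batch, met) in lod_records:
            del lod_records[(batch, met)]
            mask = (meta["batch"] == batch).to_numpy() & (codes[met] == Code.BELOW_LOD.value).to_numpy()
            codes.loc[mask, met] = Code.BELOW_UNKNOWN_LOD.value
    if lod_records:
        idx = pd.MultiIndex.from_tuples(lod_records.keys(), names=["batch", "metabolite"])
        limits.lod = pd.Series(list(lod_records.values()), index=idx, name="lod")

    quant_mets = [m for m in mets if not semi[m]]
    lloq, uloq = {}, {}
    for met in quant_mets:
        col = raw[:, mets.index(met)]
        lo = float(np.quantile(col, config.lloq_quantile)) if config.lloq_quantile > 0 else None
        hi = float(np.quantile(col, config.uloq_quantile))
        if lo is not None and lo > 0:
            lloq[met] = lo
            below = col < lo
            codes.loc[below, met] = Code.BELOW_LLOQ.value
            values.loc[below, met] = np.nan
        uloq[met] = hi
        above = (col > hi) & (codes[met] == Code.OBSERVED.value).to_numpy()
        codes.loc[above, met] = Code.ABOVE_ULOQ.value
        values.loc[above, met] = np.nan
    limits.lloq = pd.Series(lloq, dtype=float)
    limits.uloq = pd.Series(uloq, dtype=float)

    if config.missing_rate > 0:
        mcar = (rng.random((n, p)) < config.missing_rate) & (codes.to_numpy(dtype=object) == Code.OBSERVED.value)
        codes_arr = codes.to_numpy(dtype=object)
        codes_arr[mcar] = Code.FULLY_MISSING.value
        codes = pd.DataFrame(codes_arr, index=meta.index, columns=mets)
        vals_arr = values.to_numpy()
        vals_arr[mcar] = np.nan
        values = pd.DataFrame(vals_arr, index=meta.index, columns=mets)

    data = MetabolomicsDataset(values, codes, meta, limits, scale="raw")

    # --- true ICC for the duplicate design ----------------------------------
    n_cb = pair_kind.count("cross_batch")
    n_cs = pair_kind.count("cross_study")
    within_parts = []
    mean_extra = float(np.mean(sd_study**2)) - config.tau2_subject
    if n_cb:
        within_parts += [config.tau2_batch + mean_extra] * n_cb
    if n_cs:
        within_parts += [config.tau2_study + config.tau2_batch + mean_extra] * n_cs
    within = float(np.mean(within_parts)) if within_parts else np.nan
    denom = config.tau2_subject + within
    icc_val = config.tau2_subject / denom if within_parts and denom > 0 else np.nan
    true_icc = pd.Series(icc_val, index=mets, name="true_icc")

    truth = GroundTruth(
        config=config,
        alpha=pd.Series(alpha, index=mets),
        study_effects=pd.DataFrame(u_study, index=studies, columns=mets),
        batch_effects=pd.DataFrame(b_batch, index=batch_labels, columns=mets),
        center_effects=pd.DataFrame(c_center, index=center_names, columns=mets),
        gender_effect=pd.Series(g_eff, index=mets),
        bmi_effect=pd.Series(bmi_eff, index=mets),
        alcohol_effect=pd.Series(alc_eff, index=mets),
        residual_sd_by_study=pd.Series(sd_study, index=studies),
        true_icc=true_icc,
        duplicate_subjects=dup_subjects,
        outlier_samples=outliers,
        metabolite_class=met_class,
    )
    return data, truth


def generate_duplicates(
    n_subjects: int,
    sigma2_between: float,
    sigma2_within: float,
    n_replicates: int = 2,
    mu: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain one-way duplicate design: returns (y, subject_index).

    The generating ICC is sigma2_between / (sigma2_between + sigma2_within).
    """
    rng = np.random.default_rng(seed)
    idx = np.repeat(np.arange(n_subjects), n_replicates)
    gamma = rng.normal(mu, np.sqrt(sigma2_between), n_subjects)
    y = gamma[idx] + rng.normal(0.0, np.sqrt(sigma2_within), len(idx))
    return y, idx


def make_config(**overrides) -> SyntheticConfig:
    """Preset with overrides: ``make_config(n_metabolites=100, seed=3)``."""
    return replace(epic_like_preset(), **overrides)
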