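"""End-to-end orchestration of the normalization pipeline.

Stage order: clean -> impute (+ log) -> variance decomposition (PC-PR2)
-> normalize -> optional post-normalization PC-PR2, ICC before/after,
and phenotype correlations.  Every stage writes its report next to its
outputs and the effective configuration is serialized alongside, so a
run can be audited and replayed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import cleaning, imputation
from .dataset import MetabolomicsDataset, load_dataset, read_dataset, write_dataset
from .icc import estimate_icc, icc_comparison_report
from .normalization import (
    NormalizationSpec,
    combat_normalize,
    correlate_with_phenotype,
    normalize_dataset,
    pca_residual_normalize,
)
from .pcpr2 import plot_pcpr2, run_pcpr2

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = (
    "center", "gender", "age", "bmi", "alcohol", "smoking",
    "fasting", "blood_draw_time", "case_control", "study", "batch@study",
)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; fully JSON-serializable."""

    out_dir: str = "pipeline_out"
    # input files (ignored when a dataset object is passed to run_pipeline)
    values_path: str | None = None
    metadata_path: str | None = None
    codes_path: str | None = None
    lod_path: str | None = None
    quant_limits_path: str | None = None

    # cleaning
    miss_threshold: float = 0.20
    min_batch_size: int = 10
    ellipse_expansion: float = 0.20
    ellipse_alpha: float = 0.05

    # variance decomposition
    run_pcpr2: bool = True
    pcpr2_covariates: tuple[str, ...] = DEFAULT_COVARIATES
    pcpr2_threshold: float = 0.80

    # normalization
    normalize: bool = True
    method: str = "mixed"            # mixed | combat | pca
    x_random: tuple[str, ...] = ("study", "batch@study")
    x_fixed: tuple[str, ...] = ()
    z_fixed: tuple[str, ...] = ("center", "gender", "bmi", "alcohol")
    variance_structure: str = "per_group"
    variance_group: str = "study"
    pca_k: int = 2

    # reproducibility assessment
    run_icc: bool = True
    subject_col: str = "subject_id"
    icc_boot: int = 200
    icc_level: float = 0.95

    # phenotype correlations (controls only, one aliquot per subject)
    phenotype: str | None = "bmi"
    phenotype_subset: str | None = "case_control == 'control'"

    seed: int = 0
    plots: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _dump(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)


def run_pipeline(config: PipelineConfig, data: MetabolomicsDataset | None = None) -> dict:
    """Execute the pipeline; returns a dict of produced artifact paths.

    ``data`` bypasses file input (e.g. a freshly simulated dataset).
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    _dump(asdict(config), os.path.join(out, "config.json"))
    artifacts: dict[str, object] = {}

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            _dump({"failed_stage": name, "error": str(exc),
                   "artifacts": {k: str(v) for k, v in artifacts.items()}},
                  os.path.join(out, "failure.json"))
            raise StageError(name, exc) from exc

    if data is None:
        if config.values_path is None or config.metadata_path is None:
            raise ValueError("provide a dataset or values/metadata paths")
        data = stage("read", lambda: read_dataset(
            config.values_path, config.metadata_path, codes_path=config.codes_path,
            lod_path=config.lod_path, quant_limits_path=config.quant_limits_path))

    cleaned, clean_report = stage("clean", lambda: cleaning.clean(
        data, config.miss_threshold, config.min_batch_size,
        config.ellipse_expansion, config.ellipse_alpha))
    _dump(clean_report.to_dict(), os.path.join(out, "cleaning.json"))
    write_dataset(cleaned, os.path.join(out, "cleaned"))

    imputed, imp_report = stage("impute", lambda: imputation.impute(cleaned))
    _dump({"counts": imp_report.counts, "records": imp_report.records},
          os.path.join(out, "imputation.json"))
    write_dataset(imputed, os.path.join(out, "imputed"))
    artifacts["imputed"] = os.path.join(out, "imputed")

    if config.run_pcpr2:
        res = stage("pcpr2", lambda: run_pcpr2(
            imputed, list(config.pcpr2_covariates), config.pcpr2_threshold))
        _dump(res.to_dict(), os.path.join(out, "pcpr2_before.json"))
        if config.plots:
            plot_pcpr2(res, os.path.join(out, "pcpr2_before.png"), "before normalization")
        artifacts["pcpr2_before"] = res

    normalized = None
    if config.normalize:
        if config.method == "mixed":
            spec = NormalizationSpec(
                x_random=config.x_random, x_fixed=config.x_fixed, z_fixed=config.z_fixed,
                variance_structure=config.variance_structure, variance_group=config.variance_group)
            normalized, models = stage("normalize", lambda: normalize_dataset(imputed, spec))
            _dump({m: {"failed": mod.failed, "error": mod.error,
                       "variance_components": (mod.variance_components if not mod.failed else None),
                       "residual_variances": (mod.fit.residual_variances.to_dict() if not mod.failed else None)}
                   for m, mod in models.items()}, os.path.join(out, "models.json"))
        elif config.method == "combat":
            normalized = stage("normalize", lambda: combat_normalize(
                imputed, preserve=config.z_fixed))
        elif config.method == "pca":
            normalized = stage("normalize", lambda: pca_residual_normalize(imputed, config.pca_k))
        else:
            raise ValueError(f"unknown normalization method {config.method!r}")
        write_dataset(normalized, os.path.join(out, "normalized"))
        artifacts["normalized"] = os.path.join(out, "normalized")

        if config.run_pcpr2:
            res_after = stage("pcpr2_after", lambda: run_pcpr2(
                normalized, list(config.pcpr2_covariates), config.pcpr2_threshold))
            _dump(res_after.to_dict(), os.path.join(out, "pcpr2_after.json"))
            if config.plots:
                plot_pcpr2(res_after, os.path.join(out, "pcpr2_after.png"), "after normalization")
            artifacts["pcpr2_after"] = res_after

    final = normalized if normalized is not None else imputed

    if config.run_icc and config.subject_col in data.metadata.columns:
        rng = np.random.default_rng(config.seed)
        icc_before = stage("icc_before", lambda: estimate_icc(
            imputed, config.subject_col, n_boot=config.icc_boot,
            level=config.icc_level, seed=int(rng.integers(2**31))))
        icc_before.table.to_csv(os.path.join(out, "icc_before.csv"))
        artifacts["icc_before"] = icc_before
        if normalized is not None:
            icc_after = stage("icc_after", lambda: estimate_icc(
                normalized, config.subject_col, n_boot=config.icc_boot,
                level=config.icc_level, seed=int(rng.integers(2**31))))
            icc_after.table.to_csv(os.path.join(out, "icc_after.csv"))
            comp = icc_comparison_report(
                icc_before, icc_after,
                plot_path=os.path.join(out, "icc_arrows.png") if config.plots else None)
            comp.to_csv(os.path.join(out, "icc_comparison.csv"))
            _dump(comp.attrs["summary"], os.path.join(out, "icc_summary.json"))
            artifacts["icc_after"] = icc_after

    if config.phenotype is not None and config.phenotype in data.metadata.columns:
        subset = None
        if config.phenotype_subset:
            subset = final.metadata.eval(config.phenotype_subset)
        corr = stage("phenotype", lambda: correlate_with_phenotype(
            final, config.phenotype, subset=subset,
            subject_col=config.subject_col, seed=config.seed))
        corr.to_csv(os.path.join(out, "phenotype_correlations.csv"))
        artifacts["phenotype_correlations"] = corr

    artifacts["out_dir"] = out
    return artifacts
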