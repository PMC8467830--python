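"""Step 2 — deterministic imputation and log transform.

Out-of-range values are substituted from the limit tables, per batch:

* below batch-specific LOD            -> LOD / 2
* below kit-specific LLOQ             -> LLOQ / 2
* above kit-specific ULOQ             -> ULOQ
* below an unknown batch LOD          -> (study median of known LODs) / 2

Fully missing values are then substituted with the batch median of
observed values, falling back to the study median of batch medians when
at least half of the batch is missing.  Finally concentrations are
natural-log transformed.  Every substitution is recorded in an
:class:`ImputationReport`; observed values pass through bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Code, MetabolomicsDataset, ValidationError

__all__ = [
    "ImputationReport",
    "impute_out_of_range",
    "impute_fully_missing",
    "log_transform",
    "impute",
]


@dataclass
class ImputationReport:
    """Per-cell record of every substitution plus counts per rule."""

    records: list[dict] = field(default_factory=list)

    def add(self, sample: str, metabolite: str, code: Code, value: float, rule: str) -> None:
        self.records.append(
            {"sample_id": sample, "metabolite": metabolite, "code": code.value,
             "value": float(value), "rule": rule}
        )

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r["rule"]] = out.get(r["rule"], 0) + 1
        return out

    def merge(self, other: "ImputationReport") -> "ImputationReport":
        return ImputationReport(self.records + other.records)


def impute_out_of_range(data: MetabolomicsDataset) -> tuple[MetabolomicsDataset, ImputationReport]:
    """Substitute below-LOD/LLOQ and above-ULOQ cells from the limit tables."""
    if data.scale != "raw":
        raise ValidationError("out-of-range imputation operates on the raw scale")
    values = data.values.copy()
    codes = data.codes.copy()
    report = ImputationReport()
    meta = data.metadata
    lod, lloq, uloq = data.limits.lod, data.limits.lloq, data.limits.uloq

    # study medians of known LODs, per metabolite, for the unknown-LOD rule
    study_of_batch = meta.drop_duplicates("batch").set_index("batch")["study"]
    study_median_lod: dict[tuple[str, str], float] = {}
    if len(lod):
        lod_df = lod.rename("lod").reset_index()
        lod_df["study"] = lod_df["batch"].map(study_of_batch)
        lod_df = lod_df.dropna(subset=["study"])
        grouped = lod_df.groupby(["study", "metabolite"])["lod"].median()
        study_median_lod = grouped.to_dict()

    codes_arr = codes.to_numpy(dtype=object)
    for code in (Code.BELOW_LOD, Code.BELOW_LLOQ, Code.ABOVE_ULOQ, Code.BELOW_UNKNOWN_LOD):
        rows, cols = np.where(codes_arr == code.value)
        for i, j in zip(rows, cols):
            sid, met = data.sample_ids[i], data.metabolites[j]
            batch = meta.at[sid, "batch"]
            if code is Code.BELOW_LOD:
                key = (batch, met)
                if key not in lod.index:
                    raise ValidationError(f"BELOW_LOD cell but no LOD on record for batch {batch!r}, metabolite {met!r}")
                sub, rule = lod[key] / 2.0, "LOD/2"
            elif code is Code.BELOW_LLOQ:
                if met not in lloq.index:
                    raise ValidationError(f"BELOW_LLOQ cell but no LLOQ on record for metabolite {met!r}")
                sub, rule = lloq[met] / 2.0, "LLOQ/2"
            elif code is Code.ABOVE_ULOQ:
                if met not in uloq.index:
                    raise ValidationError(f"ABOVE_ULOQ cell but no ULOQ on record for metabolite {met!r}")
                sub, rule = uloq[met], "ULOQ"
            else:  # BELOW_UNKNOWN_LOD
                study = meta.at[sid, "study"]
                key2 = (study, met)
                if key2 not in study_median_lod:
                    raise ValidationError(
                        f"BELOW_UNKNOWN_LOD cell but no known LOD anywhere in study {study!r} for metabolite {met!r}"
                    )
                sub, rule = study_median_lod[key2] / 2.0, "UNKNOWN_LOD/2"
            values.iat[i, j] = sub
            codes.iat[i, j] = Code.OBSERVED.value
            report.add(sid, met, code, sub, rule)
    return data.with_values(values, codes), report


def impute_fully_missing(data: MetabolomicsDataset) -> tuple[MetabolomicsDataset, ImputationReport]:
    """Substitute fully-missing cells with batch medians (study fallback).

    Per (batch, metabolite): if the fully-missing fraction in the batch is
    below 50%, the batch median of observed values is used; otherwise the
    study median of the batch medians.  Out-of-range imputation must run
    first so that "observed" covers the limit-based substitutes.
    """
    values = data.values.copy()
    codes = data.codes.copy()
    report = ImputationReport()
    meta = data.metadata
    codes_arr = codes.to_numpy(dtype=object)
    missing = codes_arr == Code.FULLY_MISSING.value
    if not missing.any():
        return data.with_values(values, codes), report

    observed = codes_arr == Code.OBSERVED.value
    vals = values.to_numpy(dtype=float)
    obs_vals = np.where(observed, vals, np.nan)

    batch_codes, batch_labels = pd.factorize(meta["batch"])
    batch_of_study = {b: meta.loc[meta["batch"] == b, "study"].iloc[0] for b in batch_labels}

    # per (batch, metabolite): median of observed values and missing fraction
    batch_median = np.full((len(batch_labels), values.shape[1]), np.nan)
    miss_frac = np.zeros_like(batch_median)
    for bi in range(len(batch_labels)):
        rows = batch_codes == bi
        with np.errstate(all="ignore"):
            batch_median[bi] = np.nanmedian(obs_vals[rows], axis=0)
        miss_frac[bi] = missing[rows].mean(axis=0)

    # study median of batch medians
    studies = pd.Index([batch_of_study[b] for b in batch_labels])
    study_median = {}
    for s in studies.unique():
        with np.errstate(all="ignore"):
            study_median[s] = np.nanmedian(batch_median[studies == s], axis=0)

    rows, cols = np.where(missing)
    for i, j in zip(rows, cols):
        sid, met = data.sample_ids[i], data.metabolites[j]
        bi = batch_codes[i]
        if miss_frac[bi, j] < 0.5 and np.isfinite(batch_median[bi, j]):
            sub, rule = batch_median[bi, j], "BATCH_MEDIAN"
        else:
            s = batch_of_study[batch_labels[bi]]
            sub, rule = study_median[s][j], "STUDY_MEDIAN_OF_BATCH_MEDIANS"
            if not np.isfinite(sub):
                raise ValidationError(
                    f"no observed values for metabolite {met!r} in batch {batch_labels[bi]!r} "
                    f"and the study-level fallback is also empty"
                )
        values.iat[i, j] = sub
        codes.iat[i, j] = Code.OBSERVED.value
        report.add(sid, met, Code.FULLY_MISSING, sub, rule)
    return data.with_values(values, codes), report


def log_transform(data: MetabolomicsDataset) -> MetabolomicsDataset:
    """Natural-log transform; requires a fully observed, positive matrix."""
    if data.scale == "log":
        raise ValidationError("dataset is already on the log scale")
    codes_arr = data.codes.to_numpy(dtype=object)
    if (codes_arr != Code.OBSERVED.value).any():
        raise ValidationError("log transform requires all cells OBSERVED (run imputation first)")
    vals = data.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise ValidationError(
            f"nonpositive value at sample {data.sample_ids[i]!r}, metabolite {data.metabolites[j]!r}"
        )
    return data.with_values(np.log(data.values), scale="log")


def impute(data: MetabolomicsDataset, log: bool = True) -> tuple[MetabolomicsDataset, ImputationReport]:
    """Full imputation step: out-of-range rules, median fallbacks, log."""
    data, r1 = impute_out_of_range(data)
    data, r2 = impute_fully_missing(data)
    if log:
        data = log_transform(data)
    return data, r1.merge(r2)
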