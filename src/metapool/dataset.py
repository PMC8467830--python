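"""Core data structures for pooled targeted-metabolomics data.

The central object is :class:`MetabolomicsDataset`: a samples x metabolites
concentration matrix together with a per-cell missingness code layer, a
sample-metadata table, and the detection/quantification limit tables needed
for imputation.  Every pipeline stage consumes and returns this object.

Concentrations outside the measurable range of the assay are not numbers:
a cell is either observed (finite, positive concentration) or carries one
of the missingness codes below.  The codes matter because cleaning counts
only fully-missing cells as "missing", while imputation substitutes each
out-of-range code with a different limit-derived value.
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Code",
    "LimitTable",
    "MetabolomicsDataset",
    "read_dataset",
    "write_dataset",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


class Code(str, enum.Enum):
    """Per-cell missingness code.

    ``OBSERVED`` cells carry a finite positive concentration; every other
    code carries no numeric value at all.  ``BELOW_LOD`` refers to the
    batch-specific limit of detection, ``BELOW_LLOQ``/``ABOVE_ULOQ`` to the
    kit-specific quantification limits, and ``BELOW_UNKNOWN_LOD`` to a
    value reported below detection in a batch whose LOD was not recorded.
    """

    OBSERVED = "observed"
    FULLY_MISSING = "fully_missing"
    BELOW_LOD = "below_lod"
    BELOW_LLOQ = "below_lloq"
    ABOVE_ULOQ = "above_uloq"
    BELOW_UNKNOWN_LOD = "below_unknown_lod"


#: sentinel strings accepted in a values file in place of a number
SENTINELS = {
    "<LOD": Code.BELOW_LOD,
    "<LLOQ": Code.BELOW_LLOQ,
    ">ULOQ": Code.ABOVE_ULOQ,
    "<LOD?": Code.BELOW_UNKNOWN_LOD,
}
_SENTINEL_FOR_CODE = {c: s for s, c in SENTINELS.items()}

NAMESPACE_SEP = "::"

#: metadata columns the pipeline knows about (extra columns are permitted)
KNOWN_METADATA_COLUMNS = (
    "subject_id",
    "study",
    "batch",
    "center",
    "gender",
    "age",
    "bmi",
    "alcohol",
    "smoking",
    "fasting",
    "blood_draw_time",
    "case_control",
)


@dataclass
class LimitTable:
    """Detection and quantification limits.

    Parameters
    ----------
    lod
        Batch-specific limits of detection: Series indexed by
        ``(batch, metabolite)`` (batch labels namespaced ``study::batch``).
        A pair may be absent.
    lloq, uloq
        Kit-specific lower/upper limits of quantification: Series indexed
        by metabolite.  A metabolite may be absent.
    """

    lod: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    lloq: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    uloq: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def validate(self) -> None:
        for name, s in (("lod", self.lod), ("lloq", self.lloq), ("uloq", self.uloq)):
            if len(s) and not (s > 0).all():
                bad = s.index[~(s > 0)].tolist()
                raise ValidationError(f"{name} limits must be strictly positive; offending entries: {bad}")
        common = self.lloq.index.intersection(self.uloq.index)
        bad = [m for m in common if not self.lloq[m] < self.uloq[m]]
        if bad:
            raise ValidationError(f"LLOQ must be < ULOQ; violated for metabolites: {bad}")

    def copy(self) -> "LimitTable":
        return LimitTable(self.lod.copy(), self.lloq.copy(), self.uloq.copy())


@dataclass
class MetabolomicsDataset:
    """A concentration matrix with missingness codes, metadata and limits.

    Attributes
    ----------
    values : DataFrame, samples x metabolites
        Concentrations; NaN wherever the code is not OBSERVED.
    codes : DataFrame, same shape/labels as ``values``
        String values of :class:`Code`.
    metadata : DataFrame indexed by sample_id
        Must contain ``study`` and ``batch`` (batch namespaced within study).
    limits : LimitTable
    scale : {"raw", "log"}
        ``log`` is only valid once every cell is OBSERVED.
    """

    values: pd.DataFrame
    codes: pd.DataFrame
    metadata: pd.DataFrame
    limits: LimitTable = field(default_factory=LimitTable)
    scale: str = "raw"

    # -- construction helpers -------------------------------------------------

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v, c, m = self.values, self.codes, self.metadata
        if not v.index.equals(c.index) or not v.columns.equals(c.columns):
            raise ValidationError("values and codes must share row/column labels")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id: {dups}")
        if not v.index.equals(m.index):
            only_values = v.index.difference(m.index).tolist()
            only_meta = m.index.difference(v.index).tolist()
            raise ValidationError(
                "sample IDs in values and metadata must match one-to-one; "
                f"only in values: {only_values}; only in metadata: {only_meta}"
            )
        for col in ("study", "batch"):
            if col not in m.columns:
                raise ValidationError(f"metadata must contain a '{col}' column")
        # batch nested in study: one study per batch label
        per_batch = m.groupby("batch", observed=True)["study"].nunique()
        bad = per_batch.index[per_batch > 1].tolist()
        if bad:
            raise ValidationError(f"batch labels shared across studies (namespace them): {bad}")
        if self.scale not in ("raw", "log"):
            raise ValidationError(f"unknown scale {self.scale!r}")

        codes_arr = c.to_numpy(dtype=object)
        valid = {code.value for code in Code}
        unknown = {x for x in codes_arr.ravel() if x not in valid}
        if unknown:
            raise ValidationError(f"unknown missingness codes: {sorted(unknown)}")
        observed = codes_arr == Code.OBSERVED.value
        vals = v.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad_obs = observed & ~np.isfinite(vals)
            if self.scale == "raw":
                bad_obs |= observed & (vals <= 0)
        if bad_obs.any():
            i, j = np.argwhere(bad_obs)[0]
            raise ValidationError(
                "OBSERVED cells must hold finite "
                + ("positive " if self.scale == "raw" else "")
                + f"values; e.g. sample {v.index[i]!r}, metabolite {v.columns[j]!r}"
            )
        if (~observed & np.isfinite(vals)).any():
            i, j = np.argwhere(~observed & np.isfinite(vals))[0]
            raise ValidationError(
                f"non-OBSERVED cells must carry no value; e.g. sample {v.index[i]!r}, metabolite {v.columns[j]!r}"
            )
        if self.scale == "log" and not observed.all():
            raise ValidationError("scale='log' requires every cell to be OBSERVED (impute first)")
        self.limits.validate()

    # -- convenience accessors ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def code_mask(self, code: Code) -> pd.DataFrame:
        return self.codes == code.value

    def subset(self, samples=None, metabolites=None) -> "MetabolomicsDataset":
        """Row/column subset preserving all layers (values are never altered)."""
        v, c, m = self.values, self.codes, self.metadata
        if samples is not None:
            v, c, m = v.loc[samples], c.loc[samples], m.loc[samples]
        if metabolites is not None:
            v, c = v[metabolites], c[metabolites]
        return MetabolomicsDataset(v.copy(), c.copy(), m.copy(), self.limits.copy(), self.scale)

    def with_values(self, values: pd.DataFrame, codes: pd.DataFrame | None = None,
                    scale: str | None = None) -> "MetabolomicsDataset":
        return MetabolomicsDataset(
            values,
            codes if codes is not None else self.codes.copy(),
            self.metadata.copy(),
            self.limits.copy(),
            scale if scale is not None else self.scale,
        )

    def equals(self, other: "MetabolomicsDataset") -> bool:
        return (
            self.scale == other.scale
            and self.values.equals(other.values)
            and self.codes.equals(other.codes)
            and self.metadata.equals(other.metadata)
            and self.limits.lod.equals(other.limits.lod)
            and self.limits.lloq.equals(other.limits.lloq)
            and self.limits.uloq.equals(other.limits.uloq)
        )


# -- namespacing ---------------------------------------------------------------

def namespace_batches(metadata: pd.DataFrame) -> pd.DataFrame:
    """Prefix batch labels with their study (``study::batch``).

    Batch is nested within study; namespacing guarantees that identical raw
    batch labels in two studies are never merged.  Idempotent.
    """
    m = metadata.copy()
    batch = m["batch"].astype(str)
    study = m["study"].astype(str)
    needs = ~batch.str.contains(NAMESPACE_SEP, regex=False)
    m["batch"] = np.where(needs, study + NAMESPACE_SEP + batch, batch)
    return m


# -- I/O -----------------------------------------------------------------------

def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_dataset(
    values_path: str,
    metadata_path: str,
    codes_path: str | None = None,
    lod_path: str | None = None,
    quant_limits_path: str | None = None,
    scale: str = "raw",
) -> MetabolomicsDataset:
    """Read a dataset from delimited files.

    The values file has samples in rows and metabolites in columns, first
    column ``sample_id``.  If ``codes_path`` is absent, empty cells decode to
    FULLY_MISSING and the sentinel strings ``<LOD``, ``<LLOQ``, ``>ULOQ`` and
    ``<LOD?`` decode into the corresponding codes.  The LOD table is long
    format ``(study, batch, metabolite, lod)``; the quantification-limit
    table is ``(metabolite, lloq, uloq)``.  Delimiter is inferred from the
    extension (``.tsv`` -> tab, otherwise comma).
    """
    raw = pd.read_csv(values_path, sep=_sep_for(values_path), index_col=0, dtype=object,
                      float_precision="round_trip")
    raw.index = raw.index.astype(str)
    metadata = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), index_col=0,
                           float_precision="round_trip")
    metadata.index = metadata.index.astype(str)
    metadata = namespace_batches(metadata)

    if codes_path is not None:
        codes = pd.read_csv(codes_path, sep=_sep_for(codes_path), index_col=0, dtype=object)
        codes.index = codes.index.astype(str)
        values = raw.astype(float)  # numpy strtod is round-trip exact
    else:
        values, codes = _decode_sentinels(raw)

    limits = LimitTable()
    if lod_path is not None:
        lod = pd.read_csv(lod_path, sep=_sep_for(lod_path), float_precision="round_trip")
        lod["batch"] = lod["batch"].astype(str)
        needs = ~lod["batch"].str.contains(NAMESPACE_SEP, regex=False)
        lod.loc[needs, "batch"] = lod.loc[needs, "study"].astype(str) + NAMESPACE_SEP + lod.loc[needs, "batch"]
        limits.lod = lod.set_index(["batch", "metabolite"])["lod"].astype(float)
    if quant_limits_path is not None:
        q = pd.read_csv(quant_limits_path, sep=_sep_for(quant_limits_path),
                        float_precision="round_trip").set_index("metabolite")
        limits.lloq = q["lloq"].dropna().astype(float)
        limits.uloq = q["uloq"].dropna().astype(float)

    missing_lim = [m for m in limits.lod.index.get_level_values("metabolite").unique()
                   if m not in values.columns] if len(limits.lod) else []
    if missing_lim:
        raise ValidationError(f"LOD table names metabolites absent from values: {missing_lim}")

    if scale == "raw":
        with np.errstate(invalid="ignore"):
            if (values.to_numpy() <= 0).any():
                raise ValidationError("negative or zero concentration in values file")
    return MetabolomicsDataset(values, codes, metadata, limits, scale)


def _decode_sentinels(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    codes = pd.DataFrame(Code.FULLY_MISSING.value, index=raw.index, columns=raw.columns, dtype=object)
    for col in raw.columns:
        s = raw[col]
        stripped = s.where(s.isna(), s.astype(str).str.strip())
        for sentinel, code in SENTINELS.items():
            codes.loc[stripped == sentinel, col] = code.value
        is_sentinel = stripped.isin(SENTINELS) | stripped.isna() | (stripped == "")
        numeric = stripped.where(~is_sentinel).astype(float)
        observed = numeric.notna()
        values.loc[observed, col] = numeric[observed].astype(float)
        codes.loc[observed, col] = Code.OBSERVED.value
    return values, codes


def write_dataset(data: MetabolomicsDataset, out_dir: str, sep: str = ",") -> dict[str, str]:
    """Write a dataset to ``out_dir`` as delimited files plus a manifest.

    Emits ``values``, ``codes``, ``metadata``, limit tables and
    ``manifest.json`` (scale flag).  Lossless:
    ``load_dataset(write_dataset(d)) == d``.
    """
    os.makedirs(out_dir, exist_ok=True)
    ext = "tsv" if sep == "\t" else "csv"
    paths = {name: os.path.join(out_dir, f"{name}.{ext}")
             for name in ("values", "codes", "metadata", "lod", "quant_limits")}
    data.values.to_csv(paths["values"], sep=sep, index_label="sample_id")
    data.codes.to_csv(paths["codes"], sep=sep, index_label="sample_id")
    data.metadata.to_csv(paths["metadata"], sep=sep, index_label="sample_id")
    lod = data.limits.lod.rename("lod").reset_index()
    if len(lod):
        lod.insert(0, "study", lod["batch"].str.split(NAMESPACE_SEP, n=1).str[0])
    else:
        lod = pd.DataFrame(columns=["study", "batch", "metabolite", "lod"])
    lod.to_csv(paths["lod"], sep=sep, index=False)
    q = pd.DataFrame({"lloq": data.limits.lloq, "uloq": data.limits.uloq})
    q.index.name = "metabolite"
    q.to_csv(paths["quant_limits"], sep=sep)
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({"scale": data.scale, "sep": sep, "files": {k: os.path.basename(v) for k, v in paths.items()}}, fh, indent=1)
    paths["manifest"] = manifest_path
    return paths


def load_dataset(in_dir: str) -> MetabolomicsDataset:
    """Read back a directory written by :func:`write_dataset`."""
    with open(os.path.join(in_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    f = {k: os.path.join(in_dir, v) for k, v in manifest["files"].items()}
    return read_dataset(
        f["values"], f["metadata"], codes_path=f["codes"],
        lod_path=f["lod"], quant_limits_path=f["quant_limits"],
        scale=manifest["scale"],
    )
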