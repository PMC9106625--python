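"""Feature-table container and delimited-text I/O.

A :class:`FeatureTable` holds an LC-MS feature intensity matrix (features x
samples) together with per-feature metadata (m/z, retention time, ionization
mode) and per-sample metadata (subject, arm, visit, sample type, batch,
injection order).  It is the object every preprocessing stage consumes and
returns.  All I/O is plain delimited text so that every intermediate artifact
of a run can be inspected and hashed.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError

#: canonical sample types
SAMPLE = "sample"
BLANK = "blank"
QC_POOL = "qc_pool"

SAMPLE_COLUMNS = ["subject", "arm", "visit", "sample_type", "batch", "injection_order"]
FEATURE_COLUMNS = ["mz", "rt", "mode"]

#: clinical outcomes carried by a ClinicalTable (baseline and week-8 columns each)
OUTCOMES = ["ldl_c", "hdl_c", "total_c", "tg", "glucose", "insulin"]

# float format used for every table written by the package; fixing the
# precision keeps output hashes stable across platforms
FLOAT_FORMAT = "%.6g"


@dataclass
class FeatureTable:
    """Feature intensities plus feature and sample metadata.

    Parameters
    ----------
    features : DataFrame indexed by feature id with columns ``mz`` (Da/e),
        ``rt`` (minutes) and ``mode`` (``positive``/``negative``).
    intensities : DataFrame indexed by feature id, one column per sample id.
        Non-negative for measured tables; baseline-subtracted change tables
        (``is_change=True``) may be signed.
    samples : DataFrame indexed by sample id with columns ``subject``,
        ``arm``, ``visit`` (``baseline``/``week8``), ``sample_type``
        (``sample``/``blank``/``qc_pool``), ``batch``, ``injection_order``.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame
    is_change: bool = False

    # ---- invariants -----------------------------------------------------
    def validate(self) -> None:
        if not self.features.index.is_unique:
            raise SchemaError("feature ids are not unique")
        if list(self.features.index) != list(self.intensities.index):
            raise SchemaError("feature metadata and intensity rows disagree")
        missing = [s for s in self.intensities.columns if s not in self.samples.index]
        if missing:
            raise SchemaError(f"sample columns without metadata record: {missing}")
        if (self.features["mz"] <= 0).any():
            raise SchemaError("m/z must be positive")
        if (self.features["rt"] < 0).any():
            raise SchemaError("retention time must be non-negative")
        if not self.is_change and (self.intensities.to_numpy() < 0).any():
            raise SchemaError("intensities must be non-negative")

    # ---- convenience accessors -----------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    def sample_ids_of_type(self, sample_type: str) -> list[str]:
        meta = self.samples.loc[list(self.intensities.columns)]
        return list(meta.index[meta["sample_type"] == sample_type])

    @property
    def study_sample_ids(self) -> list[str]:
        return self.sample_ids_of_type(SAMPLE)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.intensities.copy(), self.samples.copy(), self.is_change
        )

    def subset_features(self, keep_ids) -> "FeatureTable":
        keep = self.features.index.isin(set(keep_ids))
        return FeatureTable(
            self.features.loc[keep].copy(),
            self.intensities.loc[keep].copy(),
            self.samples.copy(),
            self.is_change,
        )


@dataclass
class FilterReport:
    """Audit record of one filtering stage."""

    stage: str
    removed_ids: list = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_before - self.n_after != len(self.removed_ids):
            raise ValueError(
                f"{self.stage}: counts inconsistent with removal list "
                f"({self.n_before} - {self.n_after} != {len(self.removed_ids)})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stage,
                "removed_id": self.removed_ids,
                "category": [self.detail.get(i, "") for i in self.removed_ids],
            }
        )


# -------------------------------------------------------------------------
# delimited-text I/O
# -------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str, samples_path: str | None = None) -> None:
    """Write the native dialect: one TSV with columns
    ``feature_id, mz, rt, mode, <sample ids...>``, plus a sample-metadata TSV.
    """
    out = pd.concat([table.features[FEATURE_COLUMNS], table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    if samples_path is not None:
        meta = table.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(samples_path, sep="\t", float_format=FLOAT_FORMAT)


#: MZmine "export to CSV" header mapping for the mzmine-csv dialect
MZMINE_COLUMN_MAP = {
    "row ID": "feature_id",
    "row m/z": "mz",
    "row retention time": "rt",
}


def read_feature_table(
    path: str,
    samples_path: str | None = None,
    dialect: str = "native",
    mode: str | None = None,
    is_change: bool = False,
) -> FeatureTable:
    """Read a feature table written by this package (``native``) or an
    MZmine-style CSV export (``mzmine-csv``; ``mode`` must then be given
    because MZmine exports each ionization mode separately).
    """
    if dialect not in ("native", "mzmine-csv"):
        raise SchemaError(f"unknown dialect {dialect!r}")
    if not os.path.exists(path):
        raise SchemaError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise SchemaError(f"empty feature-table file: {path}")
    sep = "\t" if dialect == "native" else ","
    raw = pd.read_csv(path, sep=sep)
    if dialect == "mzmine-csv":
        missing = [c for c in MZMINE_COLUMN_MAP if c not in raw.columns]
        if missing:
            raise SchemaError(
                f"mzmine-csv file lacks expected headers {missing}; "
                f"expected {sorted(MZMINE_COLUMN_MAP)}"
            )
        raw = raw.rename(columns=MZMINE_COLUMN_MAP)
        raw["feature_id"] = raw["feature_id"].astype(str)
        if mode is None:
            raise SchemaError("mzmine-csv dialect requires an explicit ionization mode")
        raw["mode"] = mode
        # MZmine appends e.g. " Peak area" to sample columns
        raw.columns = [c.replace(" Peak area", "").strip() for c in raw.columns]
    for col in ("feature_id", "mz", "rt"):
        if col not in raw.columns:
            raise SchemaError(
                f"feature table {path} lacks column {col!r}; "
                f"expected feature_id, mz, rt, mode, <sample ids>"
            )
    raw = raw.set_index("feature_id")
    feat = raw[FEATURE_COLUMNS].copy()
    inten = raw.drop(columns=FEATURE_COLUMNS)
    if samples_path is not None:
        meta = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        for col in ("subject", "arm", "visit", "sample_type"):
            if col in meta.columns:
                meta[col] = meta[col].fillna("")
    else:  # minimal metadata: every column is a study sample
        meta = pd.DataFrame(
            {
                "subject": list(inten.columns),
                "arm": "",
                "visit": "",
                "sample_type": SAMPLE,
                "batch": 1,
                "injection_order": range(len(inten.columns)),
            },
            index=pd.Index(inten.columns, name="sample_id"),
        )
    table = FeatureTable(feat, inten, meta, is_change=is_change)
    table.validate()
    return table


# -------------------------------------------------------------------------
# clinical table helpers
# -------------------------------------------------------------------------

def clinical_changes(clinical: pd.DataFrame) -> pd.DataFrame:
    """Week-8 minus baseline change per outcome, indexed by subject.

    The input is wide: ``arm`` plus ``<outcome>_baseline`` and
    ``<outcome>_week8`` columns for each outcome in :data:`OUTCOMES`.
    """
    out = pd.DataFrame(index=clinical.index)
    out["arm"] = clinical["arm"]
    for o in OUTCOMES:
        out[o] = clinical[f"{o}_week8"] - clinical[f"{o}_baseline"]
    return out


def write_clinical_table(clinical: pd.DataFrame, path: str) -> None:
    df = clinical.copy()
    df.index.name = "subject"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_clinical_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path) or os.path.getsize(path) == 0:
        raise SchemaError(f"missing or empty clinical table: {path}")
    df = pd.read_csv(path, sep="\t").set_index("subject")
    missing = [
        c
        for o in OUTCOMES
        for c in (f"{o}_baseline", f"{o}_week8")
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"clinical table lacks columns: {missing}")
    return df


def align_samples(a: FeatureTable, b: FeatureTable) -> None:
    """Raise :class:`AlignmentError` unless both tables cover the same
    study-sample ids (order may differ)."""
    sa, sb = set(a.study_sample_ids), set(b.study_sample_ids)
    if sa != sb:
        only_a = sorted(sa - sb)
        only_b = sorted(sb - sa)
        raise AlignmentError(
            f"study-sample sets differ; only in first: {only_a}; only in second: {only_b}"
        )
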