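"""Feature-table I/O, validation, and quality-control feature filtering.

A :class:`FeatureTable` holds one measurement batch: an intensity matrix
(samples x features) plus per-sample metadata (sample ID, subject ID, a
single batch tag, optional binary class labels).  One delimited text file
holds exactly one batch; multi-batch studies are directories of per-batch
files, keeping batch provenance explicit.

The QC filter mirrors common mass-spectrometry practice: features are
kept by a signal-to-noise threshold combined with a relative-standard-
deviation (RSD) condition whose direction is configurable (``keep_above``
retains features whose replicate RSD exceeds the threshold — the literal
protocol wording this package follows by default — while ``keep_below``
is the more common stability convention; see the methods documentation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureTable", "TableSchema", "QCRule", "SchemaError",
    "read_feature_table", "write_feature_table", "qc_filter_features",
]


class SchemaError(ValueError):
    """A file does not match the declared column schema or batch structure."""


@dataclass(frozen=True)
class TableSchema:
    """Column mapping for delimited feature-table files."""

    sample_col: str = "sample"
    subject_col: str = "subject"
    batch_col: str = "batch"
    label_col: str = "label"

    @classmethod
    def from_yaml(cls, path) -> "TableSchema":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {k: v for k, v in cfg.items()
                 if k in ("sample_col", "subject_col", "batch_col", "label_col")}
        return cls(**known)

    def meta_columns(self) -> list[str]:
        return [self.sample_col, self.subject_col, self.batch_col, self.label_col]


@dataclass
class FeatureTable:
    """One batch of samples: values matrix plus aligned metadata."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    subject_ids: list[str]
    batch_id: str
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x features)")
        n, d = self.values.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length must equal n_features")
        if len(self.sample_ids) != n or len(self.subject_ids) != n:
            raise ValueError("sample_ids/subject_ids length must equal n_samples")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if any(not s for s in self.subject_ids):
            raise ValueError("subject_ids must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal n_samples")
            if not np.all(np.isin(self.labels, (0, 1))):
                raise ValueError("labels must be binary in {0, 1}")
            self.labels = self.labels.astype(int)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def without_labels(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), list(self.feature_ids),
                            list(self.sample_ids), list(self.subject_ids),
                            self.batch_id, labels=None)

    def subset(self, rows) -> "FeatureTable":
        rows = np.asarray(rows)
        return FeatureTable(
            self.values[rows], list(self.feature_ids),
            [self.sample_ids[i] for i in rows],
            [self.subject_ids[i] for i in rows],
            self.batch_id,
            labels=None if self.labels is None else self.labels[rows],
        )


def read_feature_table(path, schema: TableSchema = TableSchema(),
                       delimiter: str | None = None,
                       impute_missing: bool = False) -> FeatureTable:
    """Load one batch from a delimited text file with a header row.

    Columns named by ``schema`` carry metadata (the label column is
    optional); all remaining columns are features, in file order.  Rows
    must share a single batch value.  Missing feature cells are rejected
    unless ``impute_missing`` is set, in which case they are replaced by
    the per-feature mean.
    """
    path = Path(path)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=delimiter)
    for col in (schema.sample_col, schema.subject_col, schema.batch_col):
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} is missing")
    has_labels = schema.label_col in df.columns
    meta_cols = [schema.sample_col, schema.subject_col, schema.batch_col] + \
        ([schema.label_col] if has_labels else [])
    feature_cols = [c for c in df.columns if c not in meta_cols]
    if not feature_cols:
        raise SchemaError(f"{path}: no feature columns found")

    batches = df[schema.batch_col].astype(str).unique()
    if len(batches) != 1:
        raise SchemaError(
            f"{path}: found {len(batches)} batch values {sorted(batches)}; "
            "one file must hold exactly one batch — split the file per batch")

    feats = df[feature_cols]
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feats.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SchemaError(
            f"{path}: non-numeric feature value {feats.iat[r, c]!r} "
            f"at row {r}, column {feature_cols[c]!r}")
    values = numeric.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_missing:
            r, c = np.argwhere(np.isnan(values))[0]
            raise SchemaError(
                f"{path}: missing feature value at row {r}, column "
                f"{feature_cols[c]!r} (pass impute_missing=True to mean-impute)")
        col_means = np.nanmean(values, axis=0)
        idx = np.where(np.isnan(values))
        values[idx] = np.take(col_means, idx[1])

    labels = None
    if has_labels:
        labels = pd.to_numeric(df[schema.label_col], errors="raise").to_numpy()
    return FeatureTable(
        values=values,
        feature_ids=feature_cols,
        sample_ids=df[schema.sample_col].astype(str).tolist(),
        subject_ids=df[schema.subject_col].astype(str).tolist(),
        batch_id=str(batches[0]),
        labels=labels,
    )


def write_feature_table(table: FeatureTable, path,
                        schema: TableSchema = TableSchema(),
                        delimiter: str = ",") -> None:
    """Write a batch to delimited text; round-trips through the reader."""
    data = {
        schema.sample_col: table.sample_ids,
        schema.subject_col: table.subject_ids,
        schema.batch_col: [table.batch_id] * table.n_samples,
    }
    if table.labels is not None:
        data[schema.label_col] = table.labels
    df = pd.DataFrame(data)
    feats = pd.DataFrame(table.values, columns=table.feature_ids, index=df.index)
    df = pd.concat([df, feats], axis=1)
    try:
        df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"could not write feature table to {path}: {exc}") from exc


@dataclass(frozen=True)
class QCRule:
    """Feature QC thresholds: SNR floor plus a directional RSD condition."""

    snr_threshold: float = 3.0
    rsd_threshold: float = 0.05
    rsd_direction: str = "keep_above"

    def __post_init__(self):
        if self.snr_threshold <= 0 or self.rsd_threshold <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.rsd_direction not in ("keep_above", "keep_below"):
            raise ValueError("rsd_direction must be 'keep_above' or 'keep_below'")


def qc_filter_features(per_feature_snr, per_feature_rsd,
                       rule: QCRule = QCRule()) -> np.ndarray:
    """Boolean keep-mask: SNR strictly above threshold AND the RSD condition."""
    snr = np.asarray(per_feature_snr, dtype=float)
    rsd = np.asarray(per_feature_rsd, dtype=float)
    if snr.shape != rsd.shape or snr.ndim != 1:
        raise ValueError("SNR and RSD vectors must be 1-D and aligned")
    if rule.rsd_direction == "keep_above":
        rsd_ok = rsd > rule.rsd_threshold
    else:
        rsd_ok = rsd < rule.rsd_threshold
    return (snr > rule.snr_threshold) & rsd_ok
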