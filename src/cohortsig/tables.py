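"""Feature tables and sample metadata, plus their TSV serialization.

The interchange formats are deliberately plain: tab-separated UTF-8 text,
"." decimal separator, header comment lines starting with "#".  Feature
tables are features-as-rows with a leading ``feature_id`` column; metadata
tables carry one row per sample with ``sample_id``, ``subject_id``,
``study_id`` and ``timepoint_months`` (0 = pre-intervention baseline).
Missing values are not permitted: absence of a taxon is encoded as count 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TableFormatError, ValidationError

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "subject_id", "study_id", "timepoint_months")


@dataclass
class FeatureTable:
    """A feature x sample abundance matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative matrix with feature IDs as the index and sample IDs as
        columns.
    is_count : bool
        True when every value is an integral count (the raw-sequencing case);
        False for continuous abundances (relative abundances, pathway
        copies-per-million, ...).
    """

    values: pd.DataFrame
    is_count: bool = True

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        arr = v.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("feature table values must be numeric")
        if arr.size and (arr < 0).any():
            f, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value for feature {v.index[f]!r} in sample {v.columns[s]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample column totals (sequencing depth for count tables)."""
        return self.values.sum(axis=0)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[:, list(sample_ids)], self.is_count)

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(feature_ids), :], self.is_count)


@dataclass
class SampleMetadata:
    """Per-sample design information: subject, study, and timepoint."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in f.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        f = f.loc[:, list(METADATA_COLUMNS)].reset_index(drop=True)
        f["timepoint_months"] = pd.to_numeric(f["timepoint_months"], errors="raise")
        if f["sample_id"].duplicated().any():
            dups = f.loc[f["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dups}")
        if (f["timepoint_months"] < 0).any():
            bad = f.loc[f["timepoint_months"] < 0, "sample_id"].tolist()
            raise ValidationError(f"negative timepoint for samples: {bad}")
        n_studies = f.groupby("subject_id")["study_id"].nunique()
        multi = n_studies[n_studies > 1].index.tolist()
        if multi:
            raise ValidationError(f"subjects appear in more than one study: {multi}")
        dup = f.duplicated(subset=["subject_id", "timepoint_months"], keep=False)
        if dup.any():
            pairs = f.loc[dup, ["subject_id", "timepoint_months"]].drop_duplicates()
            raise ValidationError(
                "more than one sample per (subject, timepoint): "
                + ", ".join(f"({r.subject_id}, {r.timepoint_months})" for r in pairs.itertuples())
            )
        self.frame = f

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def study_ids(self) -> list[str]:
        return sorted(self.frame["study_id"].unique())

    def post_timepoints(self) -> list[float]:
        t = self.frame["timepoint_months"]
        return sorted(t[t > 0].unique())

    def subset(self, sample_ids) -> "SampleMetadata":
        keep = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMetadata(keep)

    def indexed(self) -> pd.DataFrame:
        return self.frame.set_index("sample_id")


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise TableFormatError(f"{path}: {exc}") from exc


def read_feature_table(path) -> FeatureTable:
    """Read a features-as-rows TSV with a leading ``feature_id`` column."""
    raw = _read_tsv(path)
    if raw.columns[0] != "feature_id":
        raise TableFormatError(
            f"{path}: first column must be 'feature_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("feature_id")
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            values[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()]
            raise TableFormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} for feature "
                f"{bad.index[0]!r} in sample {col!r}"
            ) from exc
    arr = values.to_numpy()
    if (arr < 0).any():
        f, s = np.argwhere(arr < 0)[0]
        raise TableFormatError(
            f"{path}: negative value for feature {values.index[f]!r} "
            f"in sample {values.columns[s]!r}"
        )
    is_count = bool(np.all(np.mod(arr, 1) == 0)) if arr.size else True
    if is_count:
        values = values.astype(np.int64)
    return FeatureTable(values, is_count=is_count)


def write_feature_table(table: FeatureTable, path, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        table.values.rename_axis("feature_id").to_csv(fh, sep="\t")


def read_metadata(path) -> SampleMetadata:
    raw = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: metadata missing columns {missing}")
    try:
        raw["timepoint_months"] = pd.to_numeric(raw["timepoint_months"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: non-numeric timepoint_months") from exc
    return SampleMetadata(raw)


def write_metadata(meta: SampleMetadata, path, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        meta.frame.to_csv(fh, sep="\t", index=False)


def write_result_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a result TSV with '#'-prefixed key=value provenance comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def align(table: FeatureTable, meta: SampleMetadata):
    """Restrict a table and metadata to their shared samples, in table order.

    Samples present in only one of the two inputs are dropped with a logged
    warning; an empty intersection is an error.
    """
    meta_ids = set(meta.sample_ids)
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise ValidationError("no samples shared between table and metadata")
    dropped_table = [s for s in table.sample_ids if s not in meta_ids]
    dropped_meta = [s for s in meta.sample_ids if s not in set(shared)]
    if dropped_table or dropped_meta:
        logger.warning(
            "align: dropped %d table sample(s) %s and %d metadata sample(s) %s",
            len(dropped_table), dropped_table, len(dropped_meta), dropped_meta,
        )
    return table.subset_samples(shared), meta.subset(shared)
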