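"""Depth normalization, prevalence filtering, and the classifier feature transform.

Count tables are corrected for library size with

    value(f, j) = log10( c_{f,j} / N_j * Nbar + 1 )

where ``c`` is the raw count, ``N_j`` the sample's total count and ``Nbar``
the mean depth over the samples of the table (i.e. within one study, since
studies are processed independently before any comparison).  Features present
(value > 0) in strictly fewer than 10% of a study's samples are removed.

For supervised classification, relative abundances are log10-transformed after
adding a pseudocount of 1e-5 and standardized feature-wise as z-scores; the
standardization parameters are *frozen* on the training study and applied
unchanged to external data (``FrozenStandardizer``).
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral, Real

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .tables import FeatureTable

DEFAULT_PREVALENCE = 0.10
DEFAULT_PSEUDOCOUNT = 1e-5


@dataclass
class NormalizedTable:
    """A depth-normalized log10 abundance table.

    Retains the per-sample original depths ``depths`` and the cohort average
    depth ``mean_depth`` used by the normalization.
    """

    values: pd.DataFrame
    depths: pd.Series
    mean_depth: float

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_depth(table: FeatureTable) -> NormalizedTable:
    """Apply the log10 depth normalization to a count table."""
    if not table.is_count:
        raise ValidationError("normalize_depth requires a count table")
    depths = table.depths().astype(float)
    zero = depths[depths <= 0]
    if len(zero):
        raise ValidationError(f"zero-depth sample(s): {list(zero.index)}")
    mean_depth = float(depths.mean())
    values = np.log10(table.values / depths * mean_depth + 1.0)
    return NormalizedTable(values, depths, mean_depth)


def prevalence_filter(table, threshold: float = DEFAULT_PREVALENCE):
    """Drop features present in strictly fewer than ``threshold`` of samples.

    "Present" means value > 0.  A feature present in exactly the threshold
    fraction is retained (strictly-less-than removal).  Works on FeatureTable
    and NormalizedTable alike and returns the same type.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError("threshold must be in [0, 1]")
    values = table.values
    prevalence = (values > 0).mean(axis=1)
    keep = prevalence >= threshold
    if not keep.any():
        raise ValidationError("prevalence filter removed every feature")
    filtered = values.loc[keep]
    if isinstance(table, NormalizedTable):
        return NormalizedTable(filtered, table.depths, table.mean_depth)
    return FeatureTable(filtered, table.is_count)


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert counts (or any non-negative abundances) to per-sample proportions."""
    depths = table.values.sum(axis=0)
    zero = depths[depths <= 0]
    if len(zero):
        raise ValidationError(f"zero-depth sample(s): {list(zero.index)}")
    return FeatureTable(table.values / depths, is_count=False)


def log_pathway(table: FeatureTable) -> NormalizedTable:
    """log10(x + 1) transform for pathway tables already normalized upstream.

    Pathway abundances arrive on a copies-per-million-like continuous scale,
    so the depth correction is skipped and only the log transform is applied.
    """
    values = np.log10(table.values + 1.0)
    depths = table.values.sum(axis=0).astype(float)
    return NormalizedTable(values, depths, float(depths.mean()))


class FrozenStandardizer(BaseEstimator, TransformerMixin):
    """Log-pseudocount z-score transform with parameters frozen at fit time.

    ``fit`` expects a samples x features frame of relative abundances, drops
    zero-variance features, and records per-feature mean ``mean_`` and
    (population) standard deviation ``scale_`` of ``log10(x + pseudocount)``.
    ``transform`` applies those parameters unchanged; features absent from the
    new data are imputed as relative abundance 0 before the log transform.
    """

    def __init__(self, pseudocount: float = DEFAULT_PSEUDOCOUNT):
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y=None) -> "FrozenStandardizer":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        variable = X.columns[X.var(axis=0, ddof=0) > 0]
        if len(variable) == 0:
            raise ValidationError("all features have zero variance")
        logged = np.log10(X.loc[:, variable] + self.pseudocount)
        self.feature_names_ = list(variable)
        self.mean_ = logged.mean(axis=0).to_numpy()
        self.scale_ = logged.std(axis=0, ddof=0).to_numpy()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            raise ValidationError("FrozenStandardizer is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X, columns=self.feature_names_)
        present = [f for f in self.feature_names_ if f in X.columns]
        if not present:
            raise ValidationError("none of the fitted features are present")
        aligned = X.reindex(columns=self.feature_names_, fill_value=0.0)
        logged = np.log10(aligned + self.pseudocount)
        return (logged - self.mean_) / self.scale_


def ml_transform(
    rel: FeatureTable,
    frozen: FrozenStandardizer | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, FrozenStandardizer]:
    """Classifier feature transform over a relative-abundance table.

    Fit mode (``frozen`` is None): drops zero-variance features, fits the
    standardization on this table and returns (z-scores, fitted transform).
    Apply mode: applies the given transform unchanged.
    The returned matrix is samples x features.
    """
    X = rel.values.T  # samples x features
    if frozen is None:
        frozen = FrozenStandardizer(pseudocount=pseudocount).fit(X)
    return frozen.transform(X), frozen
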