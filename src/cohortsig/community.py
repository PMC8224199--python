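"""Community-level structure: Bray-Curtis, PCoA, Shannon diversity, PERMANOVA.

PERMANOVA here supports the two-factor crossed design ``distance ~ study *
timepoint`` with sequential (Type I) sums of squares: terms are added in the
given order and each term's SS is the increment in explained inertia of the
Gower-centered inner-product matrix.  Timepoint is coded pre/post (all
post-baseline months pooled).  P-values come from free (unrestricted)
permutation of sample labels with the add-one rule; an exhaustive mode
enumerates all permutations for small n.  Free permutation ignores the
repeated-measures structure of longitudinal designs; that caveat is recorded
in the result metadata.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .tables import SampleMetadata

DEFAULT_TERMS = ("study", "timepoint", "study:timepoint")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix shape does not match sample IDs")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValidationError("distances must be non-negative")
        self.matrix = m

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples of a feature x sample table.

    d(i,j) = 1 - 2 sum_f min(x_fi, x_fj) / (sum_f x_fi + sum_f x_fj).
    Two all-zero samples get d = 0 by convention; an all-zero sample versus a
    non-zero one gives d = 1.
    """
    values = table.values
    X = values.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 samples")
    if np.any(X < 0):
        raise ValidationError("Bray-Curtis requires non-negative values")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(X, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # nan only for all-zero vs all-zero pairs
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(values.columns), d)


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: pd.DataFrame       # samples x retained positive axes
    eigenvalues: np.ndarray         # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dist: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis by eigendecomposition of the Gower matrix.

    Axes are ordered by descending eigenvalue.  Negative eigenvalues (possible
    for non-Euclidean dissimilarities like Bray-Curtis) are reported but their
    axes are excluded from the coordinates; proportion explained is computed
    over the positive eigenvalues.
    """
    g = _gower_center(dist.matrix)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10 * max(abs(eigvals[0]), 1.0), 0.0)
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"axis{i + 1}" for i in range(coords.shape[1])]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    return Ordination(
        dist.sample_ids,
        pd.DataFrame(coords, index=dist.sample_ids, columns=axes),
        eigvals,
        prop,
    )


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (natural log), zero entries omitted."""
    c = np.asarray(list(counts), dtype=float)
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA partition: one row per term plus the residual."""

    table: pd.DataFrame  # term, df, SS, F, R2, p
    n_permutations: int
    seed: int | None
    permutation_scheme: str = (
        "free permutation of sample labels (repeated measures not restricted)"
    )


def _design_columns(meta: SampleMetadata, term: str) -> np.ndarray:
    frame = meta.frame
    if term == "study":
        labels = frame["study_id"].to_numpy()
        levels = np.unique(labels)
        if len(levels) < 2:
            raise ValidationError("term 'study' is constant across samples")
        return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])
    if term == "timepoint":
        post = (frame["timepoint_months"] > 0).astype(float).to_numpy()
        if post.min() == post.max():
            raise ValidationError("term 'timepoint' is constant across samples")
        return post[:, None]
    if term == "study:timepoint":
        study = _design_columns(meta, "study")
        post = (meta.frame["timepoint_months"] > 0).astype(float).to_numpy()
        return study * post[:, None]
    raise ValidationError(f"unknown term {term!r}")


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, abs(r[0, 0]))))
    q = q[:, :rank]
    return q @ q.T


def permanova(
    dist: DistanceMatrix,
    meta: SampleMetadata,
    terms=DEFAULT_TERMS,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Multi-term PERMANOVA with sequential sums of squares.

    With ``exhaustive=True`` all n! label permutations are enumerated (use for
    small n only) and the p-value is the exact tail fraction including the
    identity; otherwise ``n_perm`` Monte-Carlo permutations with the add-one
    rule, so p is never reported as 0.
    """
    meta = meta.subset(dist.sample_ids)
    n = dist.n_samples
    g = _gower_center(dist.matrix)
    ss_total = float(np.trace(g))
    if ss_total <= 0:
        raise ValidationError("total sum of squares is zero")

    terms = list(terms)
    designs = [_design_columns(meta, t) for t in terms]
    hats = [_hat(np.ones((n, 1)))]
    ranks = [1]
    x = np.ones((n, 1))
    for d in designs:
        x = np.column_stack([x, d])
        h = _hat(x)
        hats.append(h)
        ranks.append(int(round(np.trace(h))))
    dfs = np.diff(ranks)
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")

    def stats_for(gm: np.ndarray):
        tr = np.array([float(np.sum(h * gm)) for h in hats])
        ss_terms = np.diff(tr)
        ss_resid = float(np.trace(gm)) - tr[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_terms / dfs) / (ss_resid / df_resid)
        return ss_terms, ss_resid, f

    ss_terms, ss_resid, f_obs = stats_for(g)
    # permutations equivalent to the observed labeling must count as ties even
    # when floating-point summation order shifts F by an ulp
    f_thresh = np.where(np.isfinite(f_obs), f_obs - 1e-9 * np.abs(f_obs), f_obs)

    if exhaustive:
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            _, _, f_perm = stats_for(g[np.ix_(idx, idx)])
            count += f_perm >= f_thresh
            total += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, _, f_perm = stats_for(g[np.ix_(idx, idx)])
            count += f_perm >= f_thresh
        p = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm

    rows = [
        (t, int(dfs[k]), ss_terms[k], f_obs[k], ss_terms[k] / ss_total, p[k])
        for k, t in enumerate(terms)
    ]
    rows.append(("residual", df_resid, ss_resid, math.nan, ss_resid / ss_total, math.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "F", "R2", "p"])
    return PermanovaResult(table, n_used, seed)
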