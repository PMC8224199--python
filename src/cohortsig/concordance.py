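"""Between- and within-study concordance of signed log10 p-value signatures.

Each (study, post-timepoint) contrast yields one signed log10 p-value per
feature.  Concordance between two contrasts is the Spearman rank correlation
of those signatures over the features shared by both (pairwise-complete; no
imputation).  Comparison pairs are either *between*-study (any cross-study
combination of post-timepoints) or *within*-study (any two post-timepoints of
one study).  Correlation p-values are Benjamini–Hochberg adjusted as a single
family per run, and the between-vs-within contrast of correlation
coefficients uses the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError

MIN_SHARED_FEATURES = 3

CONCORDANCE_COLUMNS = [
    "study_a", "timepoint_a", "study_b", "timepoint_b",
    "kind", "n_shared", "rho", "p", "q",
]


@dataclass(frozen=True)
class ComparisonPair:
    study_a: str
    timepoint_a: float
    study_b: str
    timepoint_b: float
    kind: str  # "between" or "within"


@dataclass
class ConcordanceResult:
    pair: ComparisonPair
    rho: float
    p: float
    n_shared: int
    q: float = math.nan

    @property
    def valid(self) -> bool:
        return self.n_shared >= MIN_SHARED_FEATURES and np.isfinite(self.rho)


def enumerate_pairs(timepoint_map: dict) -> list[ComparisonPair]:
    """All between-study and within-study comparison pairs.

    ``timepoint_map`` maps study ID to its set of post-baseline timepoints.
    Between-pairs are every cross-study combination of timepoints; within-pairs
    every unordered timepoint pair inside one study.  Ordering is
    deterministic: lexicographic by study, then by timepoint.
    """
    if not timepoint_map:
        raise ValidationError("empty timepoint map")
    studies = sorted(timepoint_map)
    clean = {}
    for s in studies:
        tps = sorted(timepoint_map[s])
        if not tps:
            raise ValidationError(f"study {s!r} has no post-baseline timepoints")
        if any(t <= 0 for t in tps):
            raise ValidationError(f"study {s!r}: timepoints must be > 0")
        clean[s] = tps
    pairs: list[ComparisonPair] = []
    for sa, sb in itertools.combinations(studies, 2):
        for ta in clean[sa]:
            for tb in clean[sb]:
                pairs.append(ComparisonPair(sa, ta, sb, tb, "between"))
    for s in studies:
        for ta, tb in itertools.combinations(clean[s], 2):
            pairs.append(ComparisonPair(s, ta, s, tb, "within"))
    return pairs


def _signature_vector(sig: pd.DataFrame, study: str, timepoint: float) -> pd.Series:
    sel = sig[(sig["study_id"] == study) & (sig["timepoint_months"] == timepoint)]
    if sel.empty:
        raise ValidationError(f"no signature rows for study {study!r} at month {timepoint}")
    return sel.set_index("feature_id")["signed_log10p"]


def spearman_t_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the t approximation with n-2 df."""
    if n < 3:
        return math.nan
    if abs(rho) >= 1.0:
        return float(np.nextafter(0, 1))
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(min(max(2.0 * stats.t.sf(abs(t), n - 2), np.nextafter(0, 1)), 1.0))


def correlate_pair(
    sig_a: pd.DataFrame, sig_b: pd.DataFrame, pair: ComparisonPair
) -> ConcordanceResult:
    """Spearman concordance of two contrasts over their shared features.

    Features with a missing signed log10 p-value in either table are dropped
    (pairwise-complete).  Fewer than three shared features flags the result
    with a missing rho rather than raising.
    """
    a = _signature_vector(sig_a, pair.study_a, pair.timepoint_a).dropna()
    b = _signature_vector(sig_b, pair.study_b, pair.timepoint_b).dropna()
    shared = a.index.intersection(b.index)
    n = len(shared)
    if n < MIN_SHARED_FEATURES:
        return ConcordanceResult(pair, math.nan, math.nan, n)
    rho = float(stats.spearmanr(a.loc[shared], b.loc[shared]).statistic)
    return ConcordanceResult(pair, rho, spearman_t_pvalue(rho, n), n)


def bh_adjust(p_values) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample rank-sum test; returns (rank-sum statistic of x, two-sided p).

    Uses the exact null distribution when both samples have <= 20 observations
    and there are no ties; otherwise a normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    no_ties = np.unique(combined).size == combined.size
    if no_ties and n1 <= 20 and n2 <= 20:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        return w, p
    mean_w = n1 * (n2 + n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    return w, float(min(2.0 * stats.norm.sf(z), 1.0))


def concordance_summary(results: list[ConcordanceResult]) -> dict:
    """Mean/SD of rho by pair kind, between-vs-within contrast, and FDR counts.

    The reported spread is the standard deviation (not the standard error) of
    the correlation coefficients, labeled as such.
    """
    import logging

    by_kind: dict[str, list[float]] = {"between": [], "within": []}
    for r in results:
        if r.valid:
            by_kind[r.pair.kind].append(r.rho)
    summary: dict = {"rho_sd_is": "standard deviation"}
    for kind, rhos in by_kind.items():
        summary[kind] = {
            "n_pairs": len(rhos),
            "rho_mean": float(np.mean(rhos)) if rhos else math.nan,
            "rho_sd": float(np.std(rhos, ddof=1)) if len(rhos) > 1 else math.nan,
        }
    if by_kind["between"] and by_kind["within"]:
        _, p = wilcoxon_rank_sum(by_kind["within"], by_kind["between"])
        summary["within_vs_between_p"] = p
    else:
        logging.getLogger(__name__).warning(
            "concordance_summary: one pair kind absent; contrast omitted"
        )
        summary["within_vs_between_p"] = math.nan
    summary["n_significant_q05"] = int(
        sum(1 for r in results if r.valid and np.isfinite(r.q) and r.q < 0.05)
    )
    return summary


def adjust_results(results: list[ConcordanceResult]) -> list[ConcordanceResult]:
    """BH-adjust all valid pair p-values as one family; returns the same list."""
    idx = [i for i, r in enumerate(results) if r.valid and np.isfinite(r.p)]
    if idx:
        qs = bh_adjust([results[i].p for i in idx])
        for i, q in zip(idx, qs):
            results[i].q = q
    return results


def concordance_analysis(signatures: pd.DataFrame):
    """Run the full pairwise concordance over a concatenated signature table.

    Returns (results, tidy DataFrame, summary dict).  The comparison family is
    every between- and within-study pair of contrasts present in the table;
    BH adjustment spans the whole family.
    """
    tp_map = {
        s: set(g.loc[g["timepoint_months"] > 0, "timepoint_months"])
        for s, g in signatures.groupby("study_id")
    }
    pairs = enumerate_pairs(tp_map)
    results = [correlate_pair(signatures, signatures, p) for p in pairs]
    adjust_results(results)
    tidy = pd.DataFrame(
        [
            (r.pair.study_a, r.pair.timepoint_a, r.pair.study_b, r.pair.timepoint_b,
             r.pair.kind, r.n_shared, r.rho, r.p, r.q)
            for r in results
        ],
        columns=CONCORDANCE_COLUMNS,
    )
    return results, tidy, concordance_summary(results)


@dataclass
class ClusterResult:
    """Leaf orders and scipy linkage matrices for rows and columns."""

    row_order: list
    row_linkage: np.ndarray
    col_order: list
    col_linkage: np.ndarray | None = None


def cluster_signature(matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of a feature x (study, timepoint) signature matrix.

    Agglomerative, Euclidean distance, complete linkage, for heatmap-style
    displays of signed log10 p-values.  Missing entries are imputed as 0 (no
    evidence) — only here, never in the correlation analysis.  Ties break
    deterministically by input order (scipy's ordering).
    """
    if matrix.shape[0] < 2:
        raise ValidationError("need >= 2 rows to cluster")
    filled = matrix.fillna(0.0)
    row_link = hierarchy.linkage(pdist(filled.to_numpy()), method="complete")
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    if matrix.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(filled.to_numpy().T), method="complete")
        col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    else:
        col_link, col_order = None, list(matrix.columns)
    return ClusterResult(row_order, row_link, col_order, col_link)
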