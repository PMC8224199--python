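"""Supervised discrimination of pre- vs post-intervention samples.

Mirrors a cross-study transfer workflow: per study, relative abundances are
log-transformed with a pseudocount, z-scored with parameters frozen on the
training data, and used to train either an L1-penalized ("lasso") logistic
regression or a random forest under 8-fold cross-validation repeated 10 times
(80 models).  Within-study performance is the mean over repeats of the AUROC
on pooled held-out predictions.  For external validation every trained model
scores every external sample, per-sample scores are averaged across models,
and AUROC is computed on the averaged scores — both study-to-study transfer
and leave-one-study-out (LOSO) pooling use this rule.

Cross-validation folds are grouped by subject: all samples from one subject
share a fold, so repeated measures never leak between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .preprocess import DEFAULT_PSEUDOCOUNT, FrozenStandardizer, relative_abundance
from .tables import FeatureTable, SampleMetadata

LASSO_C_GRID = np.logspace(-2.0, 3.0, 8)
RF_N_TREES = 500
MAX_FOLD_RETRIES = 100

TRANSFER_COLUMNS = ["train_study", "test_study", "mode", "model_type", "auroc"]


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(random positive outscores random negative), ties 1/2."""
    labels = np.asarray(list(labels))
    scores = np.asarray(list(scores), dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def labels_from_meta(meta: SampleMetadata) -> np.ndarray:
    """Binary surgical-status labels: baseline (month 0) -> 0, post -> 1."""
    return (meta.frame["timepoint_months"].to_numpy() > 0).astype(int)


def _base_model(model_type: str, y_train: np.ndarray, random_state: int):
    if model_type == "lasso":
        minority = int(np.bincount(y_train).min())
        n_inner = min(5, minority)
        if n_inner >= 2:
            return LogisticRegressionCV(
                Cs=LASSO_C_GRID,
                cv=StratifiedKFold(n_inner, shuffle=True, random_state=random_state),
                l1_ratios=(1.0,), solver="liblinear", scoring="roc_auc",
                max_iter=2000, random_state=random_state,
                use_legacy_attributes=False,
            )
        return LogisticRegression(
            penalty="l1", solver="liblinear", C=1.0,
            max_iter=2000, random_state=random_state,
        )
    if model_type == "random_forest":
        return RandomForestClassifier(
            n_estimators=RF_N_TREES, random_state=random_state, n_jobs=1
        )
    raise ValidationError(f"unknown model_type {model_type!r}")


def _grouped_folds(groups: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator):
    """Assign subjects to k folds; retry until every training split has both classes."""
    subjects = np.unique(groups)
    for _ in range(MAX_FOLD_RETRIES):
        perm = rng.permutation(subjects)
        assignment = {s: i % k for i, s in enumerate(perm)}
        fold_of = np.array([assignment[g] for g in groups])
        folds = []
        ok = True
        for f in range(k):
            test = fold_of == f
            if not test.any():
                continue
            if len(np.unique(y[~test])) < 2:
                ok = False
                break
            folds.append((~test, test))
        if ok and folds:
            return folds
    raise ValidationError("could not build subject-grouped folds with both classes in training")


class SurgeryStatusClassifier(BaseEstimator):
    """Ensemble classifier of pre- vs post-intervention status for one training set.

    fit() trains ``k x repeats`` models under subject-grouped cross-validation
    on a relative-abundance table; fitted attributes follow sklearn
    conventions (``models_``, ``frozen_``, ``feature_names_``,
    ``repeat_aurocs_``, ``within_auroc_``).
    """

    def __init__(self, model_type: str = "lasso", k: int = 8, repeats: int = 10,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT, random_state: int = 0):
        self.model_type = model_type
        self.k = k
        self.repeats = repeats
        self.pseudocount = pseudocount
        self.random_state = random_state

    def fit(self, table: FeatureTable, meta: SampleMetadata, labels=None):
        if table.is_count:
            table = relative_abundance(table)
        meta = meta.subset(table.sample_ids)
        y = np.asarray(labels) if labels is not None else labels_from_meta(meta)
        if len(np.unique(y)) < 2:
            raise ValidationError("training data needs both classes")
        groups = meta.frame["subject_id"].to_numpy()

        self.frozen_ = FrozenStandardizer(pseudocount=self.pseudocount).fit(table.values.T)
        X = self.frozen_.transform(table.values.T).to_numpy()
        self.feature_names_ = list(self.frozen_.feature_names_)

        rng = np.random.default_rng(self.random_state)
        self.models_ = []
        self.repeat_aurocs_ = []
        for rep in range(self.repeats):
            folds = _grouped_folds(groups, y, self.k, rng)
            held_scores = np.full(len(y), np.nan)
            for train, test in folds:
                seed = int(rng.integers(0, 2 ** 31 - 1))
                model = _base_model(self.model_type, y[train], seed)
                model.fit(X[train], y[train])
                self.models_.append(model)
                held_scores[test] = model.predict_proba(X[test])[:, 1]
            self.repeat_aurocs_.append(auroc(held_scores, y))
        self.within_auroc_ = float(np.mean(self.repeat_aurocs_))
        self.train_study_ = "+".join(sorted(meta.frame["study_id"].unique()))
        return self

    def predict_scores(self, table: FeatureTable) -> pd.Series:
        """Average per-sample score over all trained models (apply-mode transform)."""
        if not hasattr(self, "models_"):
            raise ValidationError("classifier is not fitted")
        if table.is_count:
            table = relative_abundance(table)
        X = self.frozen_.transform(table.values.T).to_numpy()
        scores = np.mean([m.predict_proba(X)[:, 1] for m in self.models_], axis=0)
        return pd.Series(scores, index=table.sample_ids)


@dataclass
class TransferResult:
    train_study: str
    test_study: str
    auroc: float
    mode: str  # "cv" | "transfer" | "loso"
    model_type: str


def fit_cv_models(
    table: FeatureTable,
    meta: SampleMetadata,
    model_type: str = "lasso",
    k: int = 8,
    repeats: int = 10,
    seed: int = 0,
    labels=None,
) -> SurgeryStatusClassifier:
    """Train the within-study cross-validated model ensemble."""
    clf = SurgeryStatusClassifier(model_type=model_type, k=k, repeats=repeats,
                                  random_state=seed)
    return clf.fit(table, meta, labels=labels)


def transfer_predict(
    ensemble: SurgeryStatusClassifier,
    external_table: FeatureTable,
    external_labels,
    test_study: str = "external",
    mode: str = "transfer",
) -> TransferResult:
    """Score an external study with a trained ensemble and report AUROC."""
    scores = ensemble.predict_scores(external_table)
    return TransferResult(
        ensemble.train_study_, test_study,
        auroc(scores.to_numpy(), np.asarray(external_labels)),
        mode, ensemble.model_type,
    )


def _pool_relative(studies):
    """Per-study relative abundance, then outer-join features (absent -> 0)."""
    rels = [relative_abundance(t) if t.is_count else t for t, _ in studies]
    features = sorted(set().union(*(r.values.index for r in rels)))
    joined = pd.concat(
        [r.values.reindex(features, fill_value=0.0) for r in rels], axis=1
    )
    meta = SampleMetadata(pd.concat([m.frame for _, m in studies], ignore_index=True))
    return FeatureTable(joined, is_count=False), meta


def loso(
    studies: list[tuple[FeatureTable, SampleMetadata]],
    model_type: str = "lasso",
    seed: int = 0,
    k: int = 8,
    repeats: int = 10,
    permute_labels_seed: int | None = None,
) -> list[TransferResult]:
    """Leave-one-study-out validation over a list of (table, metadata) studies.

    ``permute_labels_seed`` randomly permutes the pre/post labels of both the
    training pool and the hold-out study — the null-calibration mode in which
    AUROC should hover around chance.
    """
    if len(studies) < 2:
        raise ValidationError("LOSO needs >= 2 studies")
    perm_rng = (np.random.default_rng(permute_labels_seed)
                if permute_labels_seed is not None else None)
    results = []
    for hold in range(len(studies)):
        train = [studies[i] for i in range(len(studies)) if i != hold]
        pooled_table, pooled_meta = _pool_relative(train)
        train_labels = labels_from_meta(pooled_meta)
        if perm_rng is not None:
            train_labels = perm_rng.permutation(train_labels)
        clf = fit_cv_models(pooled_table, pooled_meta, model_type=model_type,
                            k=k, repeats=repeats, seed=seed + hold,
                            labels=train_labels)
        t_hold, m_hold = studies[hold]
        rel_hold = relative_abundance(t_hold) if t_hold.is_count else t_hold
        m_sub = m_hold.subset(rel_hold.sample_ids)
        hold_labels = labels_from_meta(m_sub)
        if perm_rng is not None:
            hold_labels = perm_rng.permutation(hold_labels)
        res = transfer_predict(
            clf, rel_hold, hold_labels,
            test_study=m_sub.frame["study_id"].iloc[0], mode="loso",
        )
        results.append(res)
    return results


def transfer_matrix(
    studies: list[tuple[FeatureTable, SampleMetadata]],
    model_type: str = "lasso",
    seed: int = 0,
    k: int = 8,
    repeats: int = 10,
) -> list[TransferResult]:
    """Within-study CV AUROCs (diagonal) and all study-to-study transfers."""
    ensembles = []
    results = []
    for i, (t, m) in enumerate(studies):
        clf = fit_cv_models(t, m, model_type=model_type, k=k, repeats=repeats,
                            seed=seed + i)
        ensembles.append(clf)
        results.append(TransferResult(clf.train_study_, "self", clf.within_auroc_,
                                      "cv", model_type))
    for i, clf in enumerate(ensembles):
        for j, (t, m) in enumerate(studies):
            if i == j:
                continue
            rel = relative_abundance(t) if t.is_count else t
            m_sub = m.subset(rel.sample_ids)
            results.append(transfer_predict(
                clf, rel, labels_from_meta(m_sub),
                test_study=m_sub.frame["study_id"].iloc[0],
            ))
    return results
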