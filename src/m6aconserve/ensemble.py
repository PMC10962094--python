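"""Balanced-negative ensemble of RBF-kernel SVMs.

The non-conserved (negative) class heavily outnumbers the conserved
(positive) class, so the negatives are split into k disjoint
sub-datasets (default 10); each sub-dataset is paired 1:1 with the full
positive set and trains one SVM member.  Every member fits its own
[0,1] min-max scaler on its own training pairs, so no statistic from
held-out data can leak into a prediction.  The ensemble score for a
site is the arithmetic mean of the members' conserved-class
probabilities; the class call uses a 0.5 threshold (training is
balanced).

SVM members use the libsvm defaults the framework was built with:
C = 1, RBF kernel with width gamma = 1/n_features, Platt-sigmoid
probability estimates.  Alternative classifier backends (naive Bayes,
logistic regression) are registered for comparison runs but the SVM is
the shipped model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .features import apply_minmax, fit_minmax, genomic_feature_names
from .metrics import EvalReport, evaluate, roc_auc
from .sites import make_balanced_pairs, split_negatives

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_BACKENDS",
    "EnsembleMember",
    "EnsembleModel",
    "fit_member",
    "fit_ensemble",
    "predict",
    "cross_validate",
    "rank_features",
    "feature_selection_curve",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class PlattSVC:
    """RBF-kernel SVM with Platt-sigmoid probability calibration.

    The sigmoid is fit on the member's own training decision values, so
    calibrated probabilities are strictly monotone in the SVM decision
    value (rankings, hence AUROC, are identical to the uncalibrated
    margin).
    """

    def __init__(self, C: float = 1.0, gamma="auto", seed: int = 0):
        self._svc = SVC(C=C, kernel="rbf", gamma=gamma, random_state=seed)
        self._sigmoid = LogisticRegression(max_iter=1000)
        self.classes_ = None

    def fit(self, X, y):
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        dec = self._svc.decision_function(X).reshape(-1, 1)
        self._sigmoid.fit(dec, y)
        return self

    def decision_function(self, X):
        return self._svc.decision_function(X)

    def predict_proba(self, X):
        dec = self._svc.decision_function(X).reshape(-1, 1)
        return self._sigmoid.predict_proba(dec)

    def predict(self, X):
        return self._svc.predict(X)


CLASSIFIER_BACKENDS = {
    "svm": lambda seed: PlattSVC(seed=seed),
    "nb": lambda seed: GaussianNB(),
    "glm": lambda seed: LogisticRegression(max_iter=1000, random_state=seed),
}


@dataclass
class EnsembleMember:
    scaler: object
    classifier: object

    def predict_proba(self, vectors: pd.DataFrame) -> np.ndarray:
        normalized = apply_minmax(self.scaler, vectors)
        proba = self.classifier.predict_proba(normalized.to_numpy())
        pos_col = list(self.classifier.classes_).index(1)
        return proba[:, pos_col]


@dataclass
class EnsembleModel:
    members: list[EnsembleMember]
    feature_schema: list[str]
    seed: int
    backend: str = "svm"
    config_hash: str = ""

    @property
    def k(self) -> int:
        return len(self.members)


def fit_member(
    train_matrix: pd.DataFrame,
    labels,
    backend: str = "svm",
    seed: int = 0,
) -> object:
    """Fit one classifier member on an already-normalized matrix."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("member training data must contain both classes")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 examples per class")
    clf = CLASSIFIER_BACKENDS[backend](seed)
    clf.fit(train_matrix.to_numpy(dtype=float), y)
    return clf


def fit_ensemble(
    conserved_vectors: pd.DataFrame,
    nonconserved_vectors: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    backend: str = "svm",
) -> EnsembleModel:
    """Train the k-member balanced ensemble on unnormalized features.

    Member i is trained on the conserved set paired 1:1 with negative
    sub-dataset i; each member fits its own min-max scaler on its own
    pairs.
    """
    if list(conserved_vectors.columns) != list(nonconserved_vectors.columns):
        raise ValueError("positive and negative feature schemas differ")
    neg_subsets = split_negatives(list(nonconserved_vectors.index), k=k, seed=seed)
    members = []
    for i, neg_ids in enumerate(neg_subsets):
        pos_ids, neg_ids = make_balanced_pairs(
            list(conserved_vectors.index), neg_ids, seed=seed + i
        )
        X = pd.concat(
            [conserved_vectors.loc[pos_ids], nonconserved_vectors.loc[neg_ids]]
        )
        y = np.r_[np.ones(len(pos_ids), dtype=int),
                  np.zeros(len(neg_ids), dtype=int)]
        scaler = fit_minmax(X)
        Xn = apply_minmax(scaler, X)
        clf = fit_member(Xn, y, backend=backend, seed=seed + i)
        members.append(EnsembleMember(scaler=scaler, classifier=clf))
    return EnsembleModel(
        members=members,
        feature_schema=list(conserved_vectors.columns),
        seed=seed,
        backend=backend,
    )


def _check_schema(model: EnsembleModel, vectors: pd.DataFrame) -> None:
    cols = list(vectors.columns)
    if cols != model.feature_schema:
        missing = [c for c in model.feature_schema if c not in cols]
        extra = [c for c in cols if c not in model.feature_schema]
        raise ValueError(
            f"feature schema mismatch: missing={missing[:5]} extra={extra[:5]}"
            + (" (column order matters)" if not missing and not extra else "")
        )


def predict(model: EnsembleModel, vectors: pd.DataFrame) -> np.ndarray:
    """Mean member probability that each site is tissue-conserved."""
    _check_schema(model, vectors)
    if vectors.empty:
        return np.empty(0)
    per_member = np.vstack([m.predict_proba(vectors) for m in model.members])
    return per_member.mean(axis=0)


def cross_validate(
    conserved_vectors: pd.DataFrame,
    nonconserved_vectors: pd.DataFrame,
    folds: int = 5,
    k: int = 10,
    seed: int = 0,
    backend: str = "svm",
) -> tuple[list[EvalReport], EvalReport]:
    """Stratified k-fold CV of the full ensemble protocol.

    Ensembles (and every member's scaler) are fit inside each training
    fold only.  Returns per-fold reports plus a mean report whose
    scalar metrics are fold averages (no pooled ROC points).
    """
    n_pos, n_neg = len(conserved_vectors), len(nonconserved_vectors)
    if folds > min(n_pos, n_neg):
        raise ValueError("more folds than members of the smaller class")
    X = pd.concat([conserved_vectors, nonconserved_vectors])
    y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X.iloc[train_idx], y[train_idx]
        model = fit_ensemble(
            X_tr[y_tr == 1], X_tr[y_tr == 0], k=k, seed=seed + fold,
            backend=backend,
        )
        scores = predict(model, X.iloc[test_idx])
        reports.append(evaluate(scores, y[test_idx]))
    mean = EvalReport(
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        acc=float(np.mean([r.acc for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auroc=float(np.mean([r.auroc for r in reports])),
        roc_points=[],
    )
    return reports, mean


def rank_features(
    model: EnsembleModel,
    holdout_matrix: pd.DataFrame,
    labels,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance on a labeled holdout.

    Importance of a feature = mean drop in ensemble AUROC over
    ``n_repeats`` seeded shuffles of that column.  Returns a DataFrame
    (feature, importance, rank) sorted by descending importance.
    """
    if not model.members:
        raise ValueError("model has no fitted members")
    _check_schema(model, holdout_matrix)
    y = np.asarray(labels, dtype=int)
    baseline, _ = roc_auc(predict(model, holdout_matrix), y)
    rng = np.random.default_rng(seed)
    importances = []
    for col in holdout_matrix.columns:
        drops = []
        for _ in range(n_repeats):
            shuffled = holdout_matrix.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            auc, _ = roc_auc(predict(model, shuffled), y)
            drops.append(baseline - auc)
        importances.append(float(np.mean(drops)))
    report = pd.DataFrame(
        {"feature": list(holdout_matrix.columns), "importance": importances}
    )
    report = report.sort_values(
        ["importance", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report


def feature_selection_curve(
    ranked_genomic_features,
    conserved_vectors: pd.DataFrame,
    nonconserved_vectors: pd.DataFrame,
    ks,
    seed: int = 0,
    k_members: int = 10,
    train_fraction: float = 0.8,
    backend: str = "svm",
) -> list[tuple[int, float]]:
    """AUROC as a function of the number of top-ranked genomic slots.

    For each k the ensemble is retrained using the top-k genomic
    features (any sequence-block columns in the input are always kept)
    and evaluated on a seeded stratified holdout split.  Selected
    columns keep their original schema order, so k = 54 reproduces the
    full model exactly.
    """
    from sklearn.model_selection import train_test_split as _sk_split

    all_genomic = set(genomic_feature_names())
    ranked = [f for f in ranked_genomic_features if f in all_genomic]
    if any(kk > len(all_genomic) for kk in ks):
        raise ValueError("k cannot exceed the 54 genomic slots")
    schema = list(conserved_vectors.columns)
    seq_cols = [c for c in schema if c not in all_genomic]

    pos_tr, pos_te = _sk_split(
        conserved_vectors, train_size=train_fraction, random_state=seed
    )
    neg_tr, neg_te = _sk_split(
        nonconserved_vectors, train_size=train_fraction, random_state=seed
    )
    curve = []
    for kk in ks:
        chosen = set(ranked[:kk])
        cols = [c for c in schema if c in chosen or c in seq_cols]
        if not cols:
            raise ValueError("no columns selected (k=0 with no sequence block)")
        model = fit_ensemble(
            pos_tr[cols], neg_tr[cols], k=k_members, seed=seed, backend=backend
        )
        X_te = pd.concat([pos_te[cols], neg_te[cols]])
        y_te = np.r_[np.ones(len(pos_te), dtype=int),
                     np.zeros(len(neg_te), dtype=int)]
        auc, _ = roc_auc(predict(model, X_te), y_te)
        curve.append((int(kk), float(auc)))
    return curve


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: EnsembleModel, path) -> None:
    """Versioned model archive (members, scalers, schema, config hash)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_schema": model.feature_schema,
        "seed": model.seed,
        "backend": model.backend,
        "config_hash": model.config_hash,
        "members": [(m.scaler, m.classifier) for m in model.members],
    }
    joblib.dump(payload, path)


def load_model(path) -> EnsembleModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {version!r}")
    return EnsembleModel(
        members=[EnsembleMember(scaler=s, classifier=c)
                 for s, c in payload["members"]],
        feature_schema=payload["feature_schema"],
        seed=payload["seed"],
        backend=payload.get("backend", "svm"),
        config_hash=payload.get("config_hash", ""),
    )
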