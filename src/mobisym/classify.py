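"""Model fitting, feature selection and evaluation for symptom prediction.

Three model families are supported — logistic regression (LR, behind a
standard scaler), random forest (RF) and gradient boosted trees (GBT) —
wrapped in the :class:`SymptomClassifier` estimator, which optionally runs
recursive feature elimination (RFE, step 1) and a small cross-validated
hyperparameter grid, both scored on precision. Evaluation reports
precision, recall, F1, AUCROC (from continuous predicted probabilities) and
a row-normalised 2x2 confusion matrix (rows = true class, each summing
to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    make_scorer,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

FAMILIES = ("lr", "rf", "gbt")

#: small documented default grids; the precision-maximising point is chosen
DEFAULT_GRIDS = {
    "lr": {"model__C": [0.1, 1.0, 10.0]},
    "rf": {"n_estimators": [100, 300], "max_depth": [5, None]},
    "gbt": {"n_estimators": [100], "max_depth": [3, 5]},
}

_PRECISION = make_scorer(precision_score, zero_division=0)


def base_estimator(family: str, random_state=None):
    """Untuned default estimator for a family."""
    if family == "lr":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("model", LogisticRegression(max_iter=2000, random_state=random_state)),
            ]
        )
    if family == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=random_state, n_jobs=1)
    if family == "gbt":
        return GradientBoostingClassifier(random_state=random_state)
    raise ValueError(f"unknown model family: {family!r} (expected one of {FAMILIES})")


def _importance_getter(family: str):
    # LR sits behind a scaler, so pull coefficients out of the pipeline
    return "named_steps.model.coef_" if family == "lr" else "auto"


def _validate_xy(X, y=None):
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X)
    if X.dtype == object or not np.issubdtype(X.dtype, np.number):
        raise ValueError("feature matrix must be numeric")
    if y is not None:
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
    return X, y, names


def select_features_rfe(X, y, family: str = "lr", n_features: int = 10, random_state=None):
    """Recursive feature elimination down to ``n_features``.

    Repeatedly fits the family's estimator and drops the lowest-ranked
    feature (absolute coefficient for LR, impurity importance for the tree
    ensembles) one at a time. Returns ``(support, ranking)``; rank 1 marks
    the surviving subset.
    """
    X, y, _ = _validate_xy(X, y)
    rfe = RFE(
        base_estimator(family, random_state=random_state),
        n_features_to_select=n_features,
        step=1,
        importance_getter=_importance_getter(family),
    ).fit(X, y)
    return rfe.support_, rfe.ranking_


class SymptomClassifier(BaseEstimator, ClassifierMixin):
    """Binary symptom-presence classifier over mobility features.

    Parameters
    ----------
    family : {'lr', 'rf', 'gbt'}, default 'rf'
        Model family: scaled logistic regression, random forest, or gradient
        boosted trees.
    n_features : int, 'cv' or None, default None
        None fits on all features. An int runs RFE down to that count.
        'cv' additionally tunes the count over a small ladder by
        cross-validated precision.
    param_grid : dict or None, default None
        None uses the family's documented default grid; an empty dict skips
        hyperparameter search and fits the default configuration.
    cv : int, default 10
        Stratified folds for every internal cross-validation.
    random_state : int or None
        Seeds CV shuffling, the forests and the boosting subsampling.

    Attributes
    ----------
    estimator_ : the fitted (and possibly grid-selected) inner model
    support_ : boolean mask of retained features
    selected_features_ : retained feature names (when X was a DataFrame)
    ranking_ : RFE ranking (1 = kept), or all-ones without selection
    best_params_ : hyperparameters chosen by the grid search
    cv_precision_ : cross-validated precision of the chosen configuration
    """

    def __init__(self, family="rf", n_features=None, param_grid=None, cv=10, random_state=None):
        self.family = family
        self.n_features = n_features
        self.param_grid = param_grid
        self.cv = cv
        self.random_state = random_state

    def _cv(self):
        if self.cv < 2:
            raise ValueError("cv must be >= 2")
        return StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)

    def fit(self, X, y):
        Xa, ya, names = _validate_xy(X, y)
        grid = DEFAULT_GRIDS[self.family] if self.param_grid is None else self.param_grid
        n_total = Xa.shape[1]
        if self.n_features is None:
            support = np.ones(n_total, dtype=bool)
            self.ranking_ = np.ones(n_total, dtype=int)
        elif self.n_features == "cv":
            ladder = sorted({min(n_total, k) for k in (5, 10, 20, 40)})
            best_n, best_p, best = None, -np.inf, None
            for k in ladder:
                sup, rank = select_features_rfe(
                    Xa, ya, self.family, n_features=k, random_state=self.random_state
                )
                est = base_estimator(self.family, random_state=self.random_state)
                p = _cv_precision(est, Xa[:, sup], ya, self._cv())
                if p > best_p:
                    best_n, best_p, best = k, p, (sup, rank)
            support, self.ranking_ = best
            self.n_features_selected_ = best_n
        else:
            support, self.ranking_ = select_features_rfe(
                Xa, ya, self.family, n_features=int(self.n_features),
                random_state=self.random_state,
            )
        self.support_ = support
        self.selected_features_ = (
            [n for n, s in zip(names, support) if s] if names is not None else None
        )
        Xs = Xa[:, support]
        est = base_estimator(self.family, random_state=self.random_state)
        if grid:
            search = GridSearchCV(est, grid, scoring=_PRECISION, cv=self._cv(), n_jobs=1)
            search.fit(Xs, ya)
            self.estimator_ = search.best_estimator_
            self.best_params_ = search.best_params_
            self.cv_precision_ = float(search.best_score_)
        else:
            self.estimator_ = clone(est).fit(Xs, ya)
            self.best_params_ = {}
            self.cv_precision_ = _cv_precision(est, Xs, ya, self._cv())
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_total
        return self

    def _select(self, X):
        Xa, _, _ = _validate_xy(X)
        return Xa[:, self.support_]

    def predict(self, X):
        return self.estimator_.predict(self._select(X))

    def predict_proba(self, X):
        return self.estimator_.predict_proba(self._select(X))

    def decision_scores(self, X):
        """Probability of the symptomatic class."""
        return self.predict_proba(X)[:, 1]


def _cv_precision(est, X, y, cv) -> float:
    y_pred = cross_val_predict(clone(est), X, y, cv=cv, n_jobs=1)
    return float(precision_score(y, y_pred, zero_division=0))


def fit_and_tune(X, y, families=FAMILIES, seed=0, n_features=None, param_grid=None, cv=10):
    """Fit one tuned :class:`SymptomClassifier` per family; the overall best
    family is the one with the highest cross-validated precision.

    Returns ``(models, best_family)``.
    """
    models = {}
    for fam in families:
        models[fam] = SymptomClassifier(
            family=fam, n_features=n_features, param_grid=param_grid, cv=cv, random_state=seed
        ).fit(X, y)
    best = max(models, key=lambda f: models[f].cv_precision_)
    return models, best


def normalize_confusion(tn: int, fp: int, fn: int, tp: int) -> np.ndarray:
    """Row-stochastic 2x2 confusion matrix: row 0 = true No (tn, fp)
    proportions, row 1 = true Yes (fn, tp) proportions."""
    m = np.array([[tn, fp], [fn, tp]], dtype=float)
    sums = m.sum(axis=1, keepdims=True)
    return np.divide(m, sums, out=np.full_like(m, np.nan), where=sums > 0)


@dataclass
class EvaluationReport:
    """Per-configuration classification metrics; AUCROC is None when the
    evaluated set contains a single true class."""

    precision: float
    recall: float
    f1: float
    aucroc: float | None
    confusion: np.ndarray
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "aucroc": self.aucroc,
            "confusion": self.confusion.tolist(),
            "counts": self.counts,
        }


def report_from_predictions(y_true, y_pred, y_score=None) -> EvaluationReport:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    aucroc = None
    if y_score is not None and len(np.unique(y_true)) == 2:
        aucroc = float(roc_auc_score(y_true, y_score))
    return EvaluationReport(
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0)),
        f1=float(f1_score(y_true, y_pred, zero_division=0)),
        aucroc=aucroc,
        confusion=normalize_confusion(tn, fp, fn, tp),
        counts={"tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp)},
    )


def evaluate(model, X, y) -> EvaluationReport:
    """Evaluate a fitted classifier on a labelled set."""
    score = None
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(X)[:, 1]
    return report_from_predictions(y, model.predict(X), score)


def cross_validated_report(
    family_or_model, X, y, cv: int = 10, seed: int = 0, groups=None
) -> EvaluationReport:
    """Out-of-fold metrics on the full set via stratified K-fold
    cross-validated predictions (the pooled-CV reporting mode).

    When ``groups`` (e.g. user ids) is given, folds never split a group:
    windowed samples from the same user overlap in time and share the user's
    geographic fingerprint, so ungrouped folds let a model score above
    chance by recognising the user rather than the mobility-symptom link.
    """
    if isinstance(family_or_model, str):
        est = base_estimator(family_or_model, random_state=seed)
    else:
        est = clone(family_or_model)
    Xa, ya, _ = _validate_xy(X, y)
    if groups is None:
        splits = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    else:
        sgkf = StratifiedGroupKFold(n_splits=cv, shuffle=True, random_state=seed)
        splits = list(sgkf.split(Xa, ya, np.asarray(groups)))
    proba = cross_val_predict(est, Xa, ya, cv=splits, method="predict_proba", n_jobs=1)[:, 1]
    return report_from_predictions(ya, proba >= 0.5, proba)


def run_experiment_grid(
    samples_by_config: dict,
    families=FAMILIES,
    seed: int = 0,
    mode: str = "cv",
    cv: int = 10,
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Evaluate every (t_hist, t_hor, family) cell.

    ``samples_by_config`` maps (t_hist, t_hor) to an already *balanced*
    sample table. mode='cv' reports pooled 10-fold out-of-fold metrics;
    mode='holdout' splits, fits the untuned family estimator on the training
    part and evaluates on the held-out part. Missing cells are simply
    absent from the output.
    """
    from .samples import split_xy, train_test_split

    rows = []
    for (t_hist, t_hor), samples in sorted(samples_by_config.items()):
        for fam in families:
            if mode == "cv":
                X, y = split_xy(samples)
                rep = cross_validated_report(fam, X, y, cv=cv, seed=seed)
            elif mode == "holdout":
                train, test = train_test_split(samples, test_fraction, seed)
                Xtr, ytr = split_xy(train)
                Xte, yte = split_xy(test)
                model = base_estimator(fam, random_state=seed).fit(np.asarray(Xtr), ytr)
                rep = evaluate(model, np.asarray(Xte), yte)
            else:
                raise ValueError(f"unknown mode: {mode!r}")
            rows.append(
                {
                    "t_hist": t_hist,
                    "t_hor": t_hor,
                    "family": fam,
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "f1": rep.f1,
                    "aucroc": rep.aucroc,
                }
            )
    return pd.DataFrame(rows)
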