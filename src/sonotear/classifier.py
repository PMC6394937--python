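"""Logistic tear-probability model with backward elimination and LOOCV.

The tear probability of a case with features ``f_1..f_n`` is

    P(tear) = 1 / (1 + exp(-(f_1 C_1 + ... + f_n C_n - constant)))

i.e. an ordinary binary logistic regression whose intercept is written as
``-constant``.  A case is called a tear when its probability is >= 0.5.

The model is fitted by maximum likelihood with damped Newton iterations
(log-likelihood change < 1e-8 or 100 iterations).  When the classes are
(quasi-)separable the ML optimum diverges; that is detected and the model
is refitted with a tiny ridge penalty (1e-6) and flagged, so downstream
code can see that coefficients are not interpretable.

Feature selection is greedy backward elimination driven by the
leave-one-out cross-validation (LOOCV) error: starting from the full set,
the feature whose removal yields the smallest LOOCV error is dropped as
long as that error does not exceed the current one (ties broken by the
largest Wald p-value in the full-data fit); the loop stops when every
removal strictly increases the error or one feature remains.

Internally features are z-scored for numerical conditioning and the
coefficients are mapped back to the raw feature scale — the unpenalized
ML fit is equivariant under affine feature maps, so this changes nothing
but the arithmetic.  Coefficients are always reported on the raw scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

POSITIVE_LABEL = "tear"
NEGATIVE_LABEL = "tendinopathy"

_SEPARATION_COEF_BOUND = 30.0  # |beta| on the z-scored scale beyond which the fit is degenerate


class CollinearFeaturesError(ValueError):
    """Raised when two selected features are numerically collinear."""


# ---------------------------------------------------------------------------
# Newton core (arrays, intercept in column 0)
# ---------------------------------------------------------------------------

def _penalized_ll(X1, y, beta, pen):
    eta = X1 @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (pen * beta**2).sum())


def _newton(X1, y, ridge=0.0, beta0=None, tol=1e-8, max_iter=100):
    """Damped Newton ascent of the (optionally ridge-penalized) log-likelihood.

    Returns ``(beta, converged, n_iter, hessian, singular)``; the intercept
    (column 0) is never penalized.
    """
    n, p1 = X1.shape
    beta = np.zeros(p1) if beta0 is None else np.array(beta0, dtype=float)
    pen = np.full(p1, float(ridge))
    pen[0] = 0.0
    ll = _penalized_ll(X1, y, beta, pen)
    hessian = None
    for it in range(1, max_iter + 1):
        mu = expit(X1 @ beta)
        grad = X1.T @ (y - mu) - pen * beta
        w = mu * (1.0 - mu)
        hessian = (X1 * w[:, None]).T @ X1 + np.diag(pen)
        try:
            step = np.linalg.solve(hessian, grad)
        except np.linalg.LinAlgError:
            return beta, False, it, hessian, True
        if not np.isfinite(step).all():
            return beta, False, it, hessian, True
        # step halving keeps the ascent monotone
        new_beta = beta + step
        new_ll = _penalized_ll(X1, y, new_beta, pen)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _penalized_ll(X1, y, new_beta, pen)
            halvings += 1
        beta = new_beta
        if abs(new_ll - ll) < tol:
            return beta, True, it, hessian, False
        ll = new_ll
    return beta, False, max_iter, hessian, False


def _fit_with_separation_guard(X1, y, ridge_on_separation, tol, max_iter, beta0=None,
                               force_ridge=False):
    """Unpenalized Newton fit, falling back to a flagged ridge fit on separation."""
    if not force_ridge:
        beta, converged, n_iter, hessian, singular = _newton(
            X1, y, 0.0, beta0=beta0, tol=tol, max_iter=max_iter
        )
        diverged = X1.shape[1] > 1 and np.abs(beta[1:]).max() > _SEPARATION_COEF_BOUND
        # if the fitted direction classifies the training data perfectly, a
        # separating hyperplane exists and the unpenalized ML optimum diverges
        eta = X1 @ beta
        separated = bool(
            np.any(eta != 0.0)
            and np.all(y[eta > 0] == 1.0)
            and np.all(y[eta < 0] == 0.0)
        )
        if converged and not singular and not diverged and not separated:
            return beta, hessian, False, n_iter
    beta, _, n_iter, hessian, _ = _newton(
        X1, y, ridge_on_separation, beta0=beta0, tol=tol, max_iter=max_iter
    )
    return beta, hessian, True, n_iter


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class NewtonLogisticRegression(ClassifierMixin, BaseEstimator):
    """Maximum-likelihood binary logistic regression (Newton iterations).

    Parameters
    ----------
    standardize : bool
        Z-score features internally for conditioning.  Coefficients are
        reported on the raw scale either way (the unpenalized ML optimum is
        identical; only the arithmetic differs).
    ridge_on_separation : float
        Ridge penalty used for the flagged refit when (quasi-)complete
        separation is detected.
    tol, max_iter : float, int
        Newton convergence control: stop when the log-likelihood change
        drops below `tol` or after `max_iter` iterations.

    Attributes
    ----------
    coef_ : ndarray of shape (1, n_features)  — raw-scale coefficients
    intercept_ : ndarray of shape (1,)
    constant_ : float — the model's ``constant`` (= ``-intercept_[0]``)
    separation_ : bool — True when the flagged ridge refit was used
    wald_p_ : ndarray of shape (n_features,) — two-sided Wald p per feature
    classes_, n_iter_, n_features_in_, feature_names_in_ : sklearn standard
    """

    def __init__(self, standardize=True, ridge_on_separation=1e-6, tol=1e-8,
                 max_iter=100, collinearity_tol=1e-7):
        self.standardize = standardize
        self.ridge_on_separation = ridge_on_separation
        self.tol = tol
        self.max_iter = max_iter
        self.collinearity_tol = collinearity_tol

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"expected exactly 2 classes, got {list(self.classes_)}"
            )
        y01 = (y == self.classes_[1]).astype(float)
        counts = np.bincount(y01.astype(int), minlength=2)
        if counts.min() < 2:
            raise ValueError("need at least 2 cases per class")

        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        if (sd == 0).any():
            name = self._feature_name(int(np.flatnonzero(sd == 0)[0]))
            raise CollinearFeaturesError(f"feature {name} is constant")
        if X.shape[1] >= 2:
            corr = np.corrcoef(X, rowvar=False)
            tri = np.triu(np.abs(corr), k=1)
            if tri.max() > 1.0 - self.collinearity_tol:
                a, b = np.unravel_index(np.argmax(tri), tri.shape)
                raise CollinearFeaturesError(
                    f"features {self._feature_name(int(a))} and "
                    f"{self._feature_name(int(b))} are collinear "
                    f"(|r| = {tri.max():.10f})"
                )

        if self.standardize:
            Xw = (X - mean) / sd
        else:
            Xw = X
        X1 = np.hstack([np.ones((X.shape[0], 1)), Xw])
        beta, hessian, separation, n_iter = _fit_with_separation_guard(
            X1, y01, self.ridge_on_separation, self.tol, self.max_iter
        )
        self.separation_ = bool(separation)
        self.n_iter_ = int(n_iter)

        # Wald p-values on the working (z-scored) parameterization; z-scores
        # are invariant under per-feature rescaling.
        try:
            cov = np.linalg.inv(hessian)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(se > 0, beta / se, np.inf)
            self.wald_p_ = 2.0 * norm.sf(np.abs(z[1:]))
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by ridge
            self.wald_p_ = np.full(X.shape[1], np.nan)

        if self.standardize:
            coef = beta[1:] / sd
            intercept = beta[0] - float(coef @ mean)
        else:
            coef = beta[1:]
            intercept = beta[0]
        self.coef_ = coef[None, :]
        self.intercept_ = np.array([intercept])
        self.constant_ = -float(intercept)
        return self

    def _feature_name(self, idx: int) -> str:
        names = getattr(self, "feature_names_in_", None)
        return str(names[idx]) if names is not None else f"x{idx}"

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return X @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]


class BackwardEliminationLogistic(ClassifierMixin, BaseEstimator):
    """Logistic classifier with LOOCV-driven backward feature elimination.

    Fitting runs the greedy elimination loop described in the module
    docstring on the training data, then refits a
    :class:`NewtonLogisticRegression` on the surviving features.

    Attributes
    ----------
    support_ : bool mask of the selected features
    selected_features_ : tuple of selected feature names
    trace_ : :class:`EliminationTrace`
    estimator_ : the final fitted :class:`NewtonLogisticRegression`
    """

    def __init__(self, standardize=True, ridge_on_separation=1e-6, tol=1e-8,
                 max_iter=100):
        self.standardize = standardize
        self.ridge_on_separation = ridge_on_separation
        self.tol = tol
        self.max_iter = max_iter

    def _est_params(self):
        return dict(
            standardize=self.standardize,
            ridge_on_separation=self.ridge_on_separation,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        names = [
            str(n) for n in getattr(
                self, "feature_names_in_",
                np.array([f"x{k}" for k in range(X.shape[1])]),
            )
        ]
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 classes, got {list(classes)}")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(float)
        selected, self.trace_ = _eliminate_arrays(
            X, y01, names, self._est_params()
        )
        self.selected_features_ = tuple(selected)
        idx = [names.index(f) for f in selected]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[idx] = True
        self.estimator_ = NewtonLogisticRegression(**self._est_params()).fit(
            X[:, idx], y
        )
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return self.estimator_.predict_proba(X[:, self.support_])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]


# ---------------------------------------------------------------------------
# Serializable model (Eq.-style parameterization) and functional surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticModel:
    """Fitted tear-probability model: raw-scale coefficients and constant."""

    feature_names: tuple
    coefficients: tuple
    constant: float
    separation: bool = False

    def __post_init__(self):
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if not np.isfinite(list(self.coefficients) + [self.constant]).all():
            raise ValueError("model parameters must be finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "coefficients": list(self.coefficients),
                "constant": self.constant,
                "separation": self.separation,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            coefficients=tuple(d["coefficients"]),
            constant=float(d["constant"]),
            separation=bool(d.get("separation", False)),
        )


def predict_probability(model: LogisticModel, feature_values) -> float:
    """Tear probability of one case:
    ``1 / (1 + exp(-(f1*C1 + ... + fn*Cn - constant)))``."""
    f = np.asarray(feature_values, dtype=float)
    if f.shape != (len(model.coefficients),):
        raise ValueError(
            f"expected {len(model.coefficients)} feature values, got shape {f.shape}"
        )
    eta = float(f @ np.asarray(model.coefficients)) - model.constant
    return float(expit(eta))


def _table_xy(table: pd.DataFrame, features) -> tuple[np.ndarray, np.ndarray]:
    features = list(features)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    X = table[features].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [f for f in features if table[f].isna().any()]
        raise ValueError(f"undefined (nan) values in features: {bad}")
    y = (table["label"] == POSITIVE_LABEL).to_numpy().astype(float)
    return X, y


def fit_logistic(table: pd.DataFrame, features, **params) -> LogisticModel:
    """Fit the tear-probability model on the named features of a feature table."""
    X, y = _table_xy(table, features)
    est = NewtonLogisticRegression(**params).fit(X, y)
    return LogisticModel(
        feature_names=tuple(features),
        coefficients=tuple(float(c) for c in est.coef_[0]),
        constant=est.constant_,
        separation=est.separation_,
    )


# ---------------------------------------------------------------------------
# LOOCV and backward elimination on arrays / tables
# ---------------------------------------------------------------------------

def _loocv_probs_arrays(X, y01, est_params) -> np.ndarray:
    """Held-out tear probability for every case (one fold per case).

    Folds are fitted with the same Newton + separation-guard procedure as
    the full fit, warm-started from the full-data solution.  Features are
    z-scored once on the full data purely for conditioning — the
    unpenalized ML fit is equivariant under affine feature maps, so this
    does not couple the folds.  A fold whose training half contains a
    single class falls back to the training majority rate.
    """
    n, p = X.shape
    standardize = est_params.get("standardize", True)
    tol = est_params.get("tol", 1e-8)
    max_iter = est_params.get("max_iter", 100)
    ridge = est_params.get("ridge_on_separation", 1e-6)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xw = (X - X.mean(axis=0)) / sd
    else:
        Xw = X
    X1 = np.hstack([np.ones((n, 1)), Xw])
    beta_full, _, sep_full, _ = _fit_with_separation_guard(
        X1, y01, ridge, tol, max_iter
    )
    probs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        y_tr = y01[keep]
        if y_tr.min() == y_tr.max():
            probs[i] = y_tr.mean()  # single-class fold: majority fallback
            continue
        beta, _, _, _ = _fit_with_separation_guard(
            X1[keep], y_tr, ridge, tol, max_iter,
            beta0=beta_full, force_ridge=sep_full,
        )
        probs[i] = expit(X1[i] @ beta)
    return probs


def _loocv_error(X, y01, cols, est_params, cache) -> float:
    key = frozenset(cols)
    if key not in cache:
        probs = _loocv_probs_arrays(X[:, list(cols)], y01, est_params)
        cache[key] = float(np.mean((probs >= 0.5) != (y01 == 1.0)))
    return cache[key]


@dataclass(frozen=True)
class EliminationStep:
    removed: str
    error_before: float
    error_after: float
    surviving: tuple


@dataclass
class EliminationTrace:
    start_features: tuple
    steps: list = field(default_factory=list)
    final_features: tuple = ()
    final_error: float = np.nan


def _eliminate_arrays(X, y01, names, est_params):
    current = list(names)
    cache: dict = {}
    col_of = {f: k for k, f in enumerate(names)}
    err = _loocv_error(X, y01, [col_of[f] for f in current], est_params, cache)
    trace = EliminationTrace(start_features=tuple(names))
    while len(current) > 1:
        removals = [
            (
                _loocv_error(
                    X, y01, [col_of[f] for f in current if f != cand],
                    est_params, cache,
                ),
                cand,
            )
            for cand in current
        ]
        best_err = min(e for e, _ in removals)
        if best_err > err:
            break
        tied = [cand for e, cand in removals if e == best_err]
        if len(tied) > 1:
            # break ties by the largest Wald p in the full-data fit of the
            # current set (the least individually significant feature goes)
            est = NewtonLogisticRegression(**est_params).fit(
                X[:, [col_of[f] for f in current]], y01
            )
            wald = dict(zip(current, est.wald_p_))
            removed = max(tied, key=lambda f: (wald.get(f, np.inf), f))
        else:
            removed = tied[0]
        current.remove(removed)
        trace.steps.append(
            EliminationStep(
                removed=removed,
                error_before=err,
                error_after=best_err,
                surviving=tuple(current),
            )
        )
        err = best_err
    trace.final_features = tuple(current)
    trace.final_error = err
    return current, trace


def backward_eliminate(
    table: pd.DataFrame, start_features, **params
) -> tuple[LogisticModel, EliminationTrace]:
    """Greedy LOOCV-error backward elimination on a feature table."""
    start_features = list(start_features)
    if not start_features:
        raise ValueError("start_features must be nonempty")
    X, y01 = _table_xy(table, start_features)
    selected, trace = _eliminate_arrays(X, y01, start_features, params)
    model = fit_logistic(table, selected, **params)
    return model, trace


def loocv(
    table: pd.DataFrame,
    features,
    selection_mode: str = "fixed",
    **params,
) -> pd.DataFrame:
    """Leave-one-out cross-validated predictions for a feature table.

    ``selection_mode``:

    * ``"fixed"`` — fit the given feature set in every fold;
    * ``"paper"`` — run backward elimination once on the full table, then
      LOOCV the fixed surviving set (the protocol a study reporting one
      global selected set most plausibly used; optimistic, since selection
      saw every case);
    * ``"inside"`` — repeat the elimination inside every training fold
      (leakage-free, considerably slower).

    Returns one row per case: case_id, probability, predicted, truth.
    """
    n = len(table)
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 cases, got {n}")
    if selection_mode not in ("fixed", "paper", "inside"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    features = list(features)
    if selection_mode == "paper":
        _, trace = backward_eliminate(table, features, **params)
        features = list(trace.final_features)
    X, y01 = _table_xy(table, features)
    if selection_mode == "inside":
        probs = np.empty(n)
        idx = np.arange(n)
        for i in range(n):
            keep = idx != i
            y_tr = y01[keep]
            if y_tr.min() == y_tr.max():
                probs[i] = y_tr.mean()
                continue
            selected, _ = _eliminate_arrays(X[keep], y_tr, features, params)
            cols = [features.index(f) for f in selected]
            est = NewtonLogisticRegression(**params).fit(X[keep][:, cols], y_tr)
            probs[i] = est.predict_proba(X[i : i + 1, cols])[0, 1]
    else:
        probs = _loocv_probs_arrays(X, y01, params)
    case_ids = (
        table["case_id"].to_numpy()
        if "case_id" in table.columns
        else np.arange(n).astype(str)
    )
    predicted = np.where(probs >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL)
    truth = np.where(y01 == 1.0, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame(
        {
            "case_id": case_ids,
            "probability": probs,
            "predicted": predicted,
            "truth": truth,
        }
    )
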