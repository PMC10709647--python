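"""L2 logistic-regression classification with nested CV and explanations.

Feature tables (subjects x features, p >> n) are classified with an
L2-penalized logistic regression; the regularization strength is selected
by an inner stratified grid search, generalization is estimated on outer
folds, and per-subject predictions come from leave-one-out. Attributions
use conditional SHAP values realized through the Gaussian/linear closed
form: expectations of withheld features are conditioned on observed ones
via a (shrunk) background covariance, so correlated features share credit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.covariance import LedoitWolf
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .recording import GROUP_A

#: Regularization strengths lambda (sklearn C = 1/lambda), 13 points
#: log-spaced over 1e-3 .. 1e3.
DEFAULT_GRID: Tuple[float, ...] = tuple(np.logspace(-3, 3, 13))


class ClassificationError(ValueError):
    pass


def table_to_xy(table: pd.DataFrame, positive_group: str = GROUP_A
                ) -> Tuple[np.ndarray, np.ndarray, List[str], List[str]]:
    """Split a feature table with a ``group`` column into (X, y, names, ids)."""
    if "group" not in table.columns:
        raise ClassificationError("feature table must carry a 'group' column")
    y = (table["group"].to_numpy() == positive_group).astype(int)
    X = table.drop(columns="group").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ClassificationError("labels must contain both classes")
    return X, y, [c for c in table.columns if c != "group"], list(table.index)


@dataclass
class L2LogisticModel:
    """Fitted L2 logistic regression (optionally with internal standardization).

    ``coef``/``intercept`` act on the standardized feature space; the
    public prediction methods accept raw features.
    """

    coef: np.ndarray
    intercept: float
    strength: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Margin (log-odds) per subject."""
        return self.standardize(X) @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class."""
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def fit_l2_logistic(X: np.ndarray, y: np.ndarray, strength: float,
                    standardize: bool = True) -> L2LogisticModel:
    """Fit an L2-penalized logistic regression at one regularization strength.

    Minimizes ``0.5 ||w||^2 + (1/strength) * sum_i log(1 + exp(-y_i m_i))``
    (the sklearn parameterization with C = 1/strength) to tight tolerance,
    so the solution is deterministic. Features are standardized with the
    training statistics unless ``standardize=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ClassificationError("features must be finite")
    if strength <= 0:
        raise ClassificationError("strength must be positive")
    if len(np.unique(y)) < 2:
        raise ClassificationError("both classes must be present")
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-12] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    # L2 penalty (the sklearn default) with C = 1/strength
    clf = LogisticRegression(C=1.0 / strength, solver="lbfgs",
                             max_iter=20000, tol=1e-12)
    clf.fit(Xs, y)
    return L2LogisticModel(
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        strength=float(strength),
        feature_mean=mean,
        feature_scale=scale,
    )


def _grid_search(X: np.ndarray, y: np.ndarray, grid: Sequence[float],
                 inner: int, seed: int) -> float:
    """Inner stratified CV; returns the accuracy-maximizing strength.

    Ties are broken toward stronger regularization (larger lambda).
    """
    if len(grid) == 1:
        return grid[0]
    skf = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in skf.split(X, y)
              if len(np.unique(y[tr])) == 2]
    if not splits:
        raise ClassificationError(
            "no inner split keeps both classes in its training part")
    scores = np.zeros(len(grid))
    for tr, te in splits:
        for g_idx, strength in enumerate(grid):
            model = fit_l2_logistic(X[tr], y[tr], strength)
            scores[g_idx] += (model.predict(X[te]) == y[te]).mean()
    best = scores.max()
    candidates = [grid[i] for i in range(len(grid)) if scores[i] >= best - 1e-12]
    return max(candidates)


def _fold_metrics(y_true: np.ndarray, proba: np.ndarray) -> Dict[str, float]:
    pred = (proba >= 0.5).astype(int)
    pos = y_true == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ClassificationError("fold is missing one class (stratification error)")
    return {
        "accuracy": float((pred == y_true).mean()),
        "sensitivity": float((pred[pos] == 1).mean()),
        "specificity": float((pred[neg] == 0).mean()),
        "auc": float(roc_auc_score(y_true, proba)),
    }


@dataclass
class CVReport:
    """Outer-fold metrics of a nested cross-validation run."""

    folds: pd.DataFrame  # accuracy/sensitivity/specificity/auc/strength per fold
    outer_splits: int
    inner_splits: int
    seed: int

    def summary(self) -> Dict[str, Dict[str, float]]:
        cols = ["accuracy", "sensitivity", "specificity", "auc"]
        return {c: {"mean": float(self.folds[c].mean()),
                    "std": float(self.folds[c].std(ddof=1))} for c in cols}

    def to_dict(self) -> dict:
        return {
            "outer_splits": self.outer_splits,
            "inner_splits": self.inner_splits,
            "seed": self.seed,
            "folds": self.folds.to_dict(orient="records"),
            "summary": self.summary(),
        }


def nested_cv(X: np.ndarray, y: np.ndarray, outer: int = 6, inner: int = 5,
              grid: Sequence[float] = DEFAULT_GRID, seed: int = 0) -> CVReport:
    """Nested stratified cross-validation (default 6 outer x 5 inner splits).

    The inner loop grid-searches the regularization strength by accuracy;
    outer test subjects are never seen by fitting or model selection.
    Feature standardization uses training-fold statistics only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
    rows = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ClassificationError(
                f"outer fold {k} is missing one class (stratification error)")
        strength = _grid_search(X[tr], y[tr], grid, inner, seed=seed + 1000 + k)
        model = fit_l2_logistic(X[tr], y[tr], strength)
        metrics = _fold_metrics(y[te], model.predict_proba(X[te]))
        metrics["strength"] = strength
        metrics["fold"] = k
        rows.append(metrics)
    folds = pd.DataFrame(rows).set_index("fold")
    return CVReport(folds=folds, outer_splits=outer, inner_splits=inner, seed=seed)


# ---------------------------------------------------------------------------
# conditional SHAP (Gaussian/linear closed form)

def _permutation_attribution(sigma: np.ndarray, sigma_w: np.ndarray,
                             order: np.ndarray) -> np.ndarray:
    """Attribution matrix contribution of one feature ordering.

    Maintains the Cholesky factor of sigma[S, S] as S grows along the
    ordering; row j of the result maps (x - mu) to the credit feature j
    earns when inserted after its predecessors.
    """
    p = sigma.shape[0]
    L = np.zeros((p, p))
    contrib = np.zeros((p, p))
    g_prev = np.zeros(p)
    for k, j in enumerate(order):
        prev = order[:k]
        if k:
            a_vec = solve_triangular(L[:k, :k], sigma[prev, j], lower=True)
            L[k, :k] = a_vec
            d_sq = sigma[j, j] - a_vec @ a_vec
        else:
            d_sq = sigma[j, j]
        L[k, k] = math.sqrt(max(d_sq, 1e-12))
        cur = order[:k + 1]
        half = solve_triangular(L[:k + 1, :k + 1], sigma_w[cur], lower=True)
        u = solve_triangular(L[:k + 1, :k + 1].T, half, lower=False)
        g = np.zeros(p)
        g[cur] = u
        contrib[j] = g - g_prev
        g_prev = g
    return contrib


def conditional_shap(model: L2LogisticModel, X_background: np.ndarray,
                     X_explain: np.ndarray, n_permutations: int = 16,
                     seed: int = 0,
                     covariance: Optional[np.ndarray] = None
                     ) -> Tuple[np.ndarray, float]:
    """SHAP values of the linear margin under Gaussian conditional expectations.

    Withheld features are imputed by their conditional mean given the
    features already in the coalition, estimated from the background
    covariance (Ledoit-Wolf shrinkage by default, since n << p makes the
    empirical covariance singular); correlated features therefore share
    credit. Attributions are exact averages over all feature orderings for
    p <= 6 and Monte-Carlo averages over ``n_permutations`` sampled
    orderings otherwise. For any ordering the attributions telescope, so
    local accuracy (base + sum SV = margin) holds exactly.

    Returns ``(sv_matrix, base_value)`` on the margin (log-odds) scale.
    """
    if X_background.shape[0] < 2:
        raise ClassificationError("background needs at least 2 rows")
    bg = model.standardize(X_background)
    xs = np.atleast_2d(model.standardize(X_explain))
    p = bg.shape[1]
    mu = bg.mean(axis=0)
    if covariance is not None:
        sigma = np.asarray(covariance, dtype=float)
        if sigma.shape != (p, p):
            raise ClassificationError(f"covariance must be ({p}, {p})")
    else:
        sigma = LedoitWolf(assume_centered=False).fit(bg).covariance_
        sigma = sigma + 1e-10 * np.eye(p)

    w = model.coef
    sigma_w = sigma @ w
    if p <= 6:
        from itertools import permutations as _perms
        orders = [np.array(o, dtype=np.intp) for o in _perms(range(p))]
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(p) for _ in range(n_permutations)]
    A = np.zeros((p, p))
    for order in orders:
        A += _permutation_attribution(sigma, sigma_w, order)
    A /= len(orders)

    sv = (xs - mu) @ A.T
    base = float(mu @ w + model.intercept)
    if np.ndim(X_explain) == 1:
        return sv[0], base
    return sv, base


@dataclass
class ExplanationReport:
    """Aggregated SHAP feature importance.

    ``fi`` is mean |SV| across all subjects divided by its maximum;
    group-conditional vectors are computed over each true-label subset
    and normalized by their own maxima.
    """

    feature_names: List[str]
    shap_values: np.ndarray  # (subjects, features)
    base_value: float
    fi: np.ndarray
    fi_by_group: Dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {"fi": self.fi}
        for grp, vec in self.fi_by_group.items():
            data[f"fi_{grp}"] = vec
        return pd.DataFrame(data, index=self.feature_names)


def feature_importance(sv_matrix: np.ndarray, labels: Sequence[str],
                       feature_names: Sequence[str],
                       base_value: float = 0.0) -> ExplanationReport:
    """Normalized mean-|SV| feature importance, overall and per group."""
    sv = np.atleast_2d(np.asarray(sv_matrix, dtype=float))
    labels = np.asarray(labels)
    if sv.shape[0] != labels.size:
        raise ClassificationError("one label per explained subject required")
    mean_abs = np.abs(sv).mean(axis=0)
    top = mean_abs.max()
    if top == 0:
        raise ClassificationError("all SHAP values are zero; FI undefined")
    fi_by_group = {}
    for grp in np.unique(labels):
        grp_mean = np.abs(sv[labels == grp]).mean(axis=0)
        grp_top = grp_mean.max()
        fi_by_group[str(grp)] = grp_mean / grp_top if grp_top > 0 else grp_mean
    return ExplanationReport(
        feature_names=list(feature_names),
        shap_values=sv,
        base_value=base_value,
        fi=mean_abs / top,
        fi_by_group=fi_by_group,
    )


@dataclass
class LOOPredictions:
    """Per-subject leave-one-out class probabilities."""

    subject_ids: List[str]
    proba: np.ndarray  # P(positive class)
    predicted: np.ndarray
    true: np.ndarray

    @property
    def misclassified(self) -> List[str]:
        return [sid for sid, p, t in zip(self.subject_ids, self.predicted, self.true)
                if p != t]

    def to_dict(self) -> dict:
        return {
            "subjects": [
                {"subject_id": sid, "proba": float(pr),
                 "predicted": int(pd_), "true": int(t)}
                for sid, pr, pd_, t in zip(self.subject_ids, self.proba,
                                           self.predicted, self.true)],
            "misclassified": self.misclassified,
        }


def loo_predict(X: np.ndarray, y: np.ndarray, subject_ids: Sequence[str],
                grid: Sequence[float] = DEFAULT_GRID, inner: int = 5,
                seed: int = 0) -> LOOPredictions:
    """Leave-one-out predictions with an inner grid search per held-out subject."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ClassificationError("need at least 2 subjects per class")
    proba = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        strength = _grid_search(X[keep], y[keep], grid, inner, seed=seed + i)
        model = fit_l2_logistic(X[keep], y[keep], strength)
        proba[i] = model.predict_proba(X[i:i + 1])[0]
    return LOOPredictions(
        subject_ids=list(subject_ids),
        proba=proba,
        predicted=(proba >= 0.5).astype(int),
        true=y,
    )
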