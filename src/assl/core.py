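"""Weighted L1-penalized binary logistic regression.

The classifier underlying every training variant in this package: a binary
logistic model with a lasso penalty on the gene coefficients (the intercept is
unpenalized), fit by minimizing

    sum_i w_i * logloss(y_i, b0 + x_i . beta)  +  penalty * ||beta||_1

over samples with positive weight.  Genes with a nonzero coefficient are the
"selected" genes; the lasso drives the rest exactly to zero, which is what the
gene-selection metrics count.

Genes are standardized to zero weighted mean / unit weighted variance on the
current training set before solving, and coefficients are mapped back to the
original scale, so the penalty acts uniformly regardless of expression units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ExpressionMatrix",
    "ModelState",
    "DegenerateFitError",
    "fit_l1_logistic",
    "predict_prob",
    "tune_penalty",
    "lambda_grid",
    "penalized_objective",
]

# Coefficients below this magnitude (on the standardized scale) are numerical
# dust from the solver and are snapped to exactly zero so that support counts
# are well defined.
COEF_ZERO_TOL = 1e-8

# liblinear penalizes the intercept through the intercept-scaling trick; with
# this scaling the effective penalty on the intercept is ~1e-3 of the gene
# penalty, i.e. negligible for every use in this package.
_INTERCEPT_SCALING = 1000.0

_PROB_EPS = 1e-12


class DegenerateFitError(ValueError):
    """Raised when a logistic fit is requested on one-class training data."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples-by-genes real-valued expression matrix with identifiers.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_genes)``; must be finite.
    sample_ids, gene_ids
        Unique identifiers for rows and columns.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, p = values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need at least 2 samples and 1 gene, got {n}x{p}")
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n or len(set(self.gene_ids)) != p:
            raise ValueError("sample and gene identifiers must be unique")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ExpressionMatrix":
        """Wrap a plain array with generated ``s0..`` / ``g0..`` identifiers."""
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        return cls(values, tuple(f"s{i}" for i in range(n)), tuple(f"g{j}" for j in range(p)))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ModelState:
    """A fitted L1-logistic model: intercept, coefficient vector, penalty."""

    intercept: float
    coefficients: np.ndarray
    penalty: float
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1:
            raise ValueError("coefficients must be a 1-D vector")
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")

    @property
    def support(self) -> np.ndarray:
        """Indices of genes with a nonzero coefficient (the selected genes)."""
        return np.flatnonzero(self.coefficients != 0.0)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients.tolist(),
                "penalty": self.penalty,
                "gene_ids": list(self.gene_ids) if self.gene_ids is not None else None,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelState":
        d = json.loads(text)
        gene_ids = tuple(d["gene_ids"]) if d.get("gene_ids") is not None else None
        return cls(d["intercept"], np.asarray(d["coefficients"]), d["penalty"], gene_ids)


def _values(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _weighted_standardize(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sw = w / w.sum()
    mu = sw @ X
    sd = np.sqrt(sw @ (X - mu) ** 2)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def fit_l1_logistic(
    X: ExpressionMatrix | np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    penalty: float = 1.0,
    *,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> ModelState:
    """Fit the weighted lasso-logistic model.

    Samples with weight 0 are removed before fitting and have no influence on
    the result; a weight of ``k`` is exactly equivalent to duplicating the
    sample ``k`` times.  ``penalty`` is the lasso tuning parameter ``lambda``;
    ``penalty=0`` gives the unregularized maximum-likelihood fit.

    Raises
    ------
    DegenerateFitError
        If only one class remains after dropping zero-weight samples.
    ValueError
        On non-finite expression values or shape mismatches.
    """
    V = _values(X)
    if not np.isfinite(V).all():
        raise ValueError("expression matrix contains non-finite values")
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    y = y.astype(float)
    n, p = V.shape
    if y.shape != (n,):
        raise ValueError("label vector length does not match matrix")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or (w < 0).any():
        raise ValueError("weights must be a nonnegative vector of length n")
    keep = w > 0
    if not keep.any():
        raise ValueError("all sample weights are zero")
    Xk, yk, wk = V[keep], y[keep], w[keep]
    if yk.min() == yk.max():
        raise DegenerateFitError("training labels are all one class")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")

    Z, mu, sd = _weighted_standardize(Xk, wk)
    if penalty == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10, max_iter=10_000)
    else:
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / penalty,
            solver="liblinear",
            tol=tol,
            max_iter=max_iter,
            intercept_scaling=_INTERCEPT_SCALING,
            random_state=0,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Liblinear failed to converge")
        clf.fit(Z, yk, sample_weight=wk)
    beta_std = clf.coef_[0].copy()
    beta_std[np.abs(beta_std) < COEF_ZERO_TOL] = 0.0
    b0 = float(clf.intercept_[0])
    if penalty > 0 and not beta_std.any():
        # In the full-shrinkage regime the minimizer has a closed form: all
        # slopes zero and the intercept at the weighted empirical log-odds.
        ybar = float((wk / wk.sum()) @ yk)
        b0 = float(np.log(ybar / (1.0 - ybar)))
    beta = beta_std / sd
    intercept = b0 - float(beta @ mu)
    gene_ids = X.gene_ids if isinstance(X, ExpressionMatrix) else None
    return ModelState(intercept, beta, float(penalty), gene_ids)


def predict_prob(model: ModelState, X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Class-1 probabilities ``sigmoid(b0 + x . beta)``, clipped into (0, 1)."""
    V = _values(X)
    if V.ndim != 2 or V.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"matrix has {V.shape[1] if V.ndim == 2 else '?'} genes, "
            f"model expects {model.coefficients.shape[0]}"
        )
    eta = model.intercept + V @ model.coefficients
    return np.clip(expit(eta), _PROB_EPS, 1.0 - _PROB_EPS)


def penalized_objective(
    model: ModelState,
    X: ExpressionMatrix | np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """The lasso-logistic objective value of ``model`` on the given data."""
    V = _values(X)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    eta = model.intercept + V @ model.coefficients
    # log(1 + exp(eta)) - y*eta, computed stably
    loglik_terms = np.logaddexp(0.0, eta) - y * eta
    return float(w @ loglik_terms + model.penalty * np.abs(model.coefficients).sum())


def lambda_grid(
    X: ExpressionMatrix | np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    n_points: int = 50,
    min_ratio: float = 1e-3,
) -> np.ndarray:
    """Log-spaced penalty grid from ``lambda_max`` down to ``min_ratio * lambda_max``.

    ``lambda_max`` is the smallest penalty at which every coefficient is zero,
    computed from the gradient of the weighted log-likelihood at the null model
    on the standardized matrix.  Returned in ascending order.
    """
    V = _values(X)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    keep = w > 0
    Xk, yk, wk = V[keep], y[keep], w[keep]
    Z, _, _ = _weighted_standardize(Xk, wk)
    ybar = (wk / wk.sum()) @ yk
    lam_max = float(np.abs(Z.T @ (wk * (yk - ybar))).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(min_ratio * lam_max, lam_max, n_points)


def tune_penalty(
    X: ExpressionMatrix | np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
    *,
    scoring: str = "loglik",
    one_se: bool = False,
    tol: float = 1e-7,
) -> float:
    """Pick the penalty by stratified cross-validation on the positive-weight samples.

    By default returns the grid value maximizing the mean cross-validated
    log-likelihood; on ties the largest penalty (sparsest model) wins.
    ``scoring="class"`` scores by CV misclassification rate instead, and
    ``one_se=True`` applies the one-standard-error rule: the largest penalty
    whose mean score is within one standard error of the best.  Deterministic
    given ``seed``.
    """
    V = _values(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    keep = np.flatnonzero(w > 0)
    if len(keep) < folds:
        raise ValueError(f"{len(keep)} positive-weight samples < {folds} folds")
    if grid is None:
        grid = lambda_grid(V, y, w)
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("penalty grid is empty")
    if scoring not in ("loglik", "class"):
        raise ValueError(f"unknown scoring {scoring!r}")
    Xk, yk, wk = V[keep], y[keep], w[keep]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores = []
    for train, test in cv.split(Xk, yk):
        wt = wk[test]
        row = []
        for lam in grid:
            m = fit_l1_logistic(Xk[train], yk[train], wk[train], lam, tol=tol)
            probs = predict_prob(m, Xk[test])
            if scoring == "class":
                row.append(-float(wt @ ((probs > 0.5) != yk[test])) / wt.sum())
            else:
                ll = wt @ (yk[test] * np.log(probs) + (1 - yk[test]) * np.log(1 - probs))
                row.append(float(ll) / wt.sum())
        fold_scores.append(row)
    F = np.asarray(fold_scores)
    mean = F.mean(axis=0)
    best = int(np.flatnonzero(mean == mean.max()).max())
    if one_se:
        se = float(F[:, best].std(ddof=1) / np.sqrt(F.shape[0]))
        eligible = np.flatnonzero(mean >= mean[best] - se)
        best = int(eligible.max())
    return float(grid[best])
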