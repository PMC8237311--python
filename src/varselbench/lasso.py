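"""Embedded variable selection via L1-penalized linear regression.

The penalty weight lambda is chosen from a fixed grid (default
2^-15 ... 2^-1) by 5-fold cross-validated r2; the model is then refit on
the full training set at the chosen lambda and every column with a
non-zero coefficient is selected.  Coordinate-descent solvers return
exact zeros, so selection tests coefficients against 0 with no epsilon.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import Lasso
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataset import Dataset
from .selection import SelectionResult, result_from_support


def default_lambda_grid() -> np.ndarray:
    """The default penalty grid: 2^k for k = -15 ... -1, ascending."""
    return 2.0 ** np.arange(-15, 0)


class LassoSelector(SelectorMixin, BaseEstimator):
    """Select variables with non-zero LASSO coefficients.

    Parameters
    ----------
    lambda_grid : array-like of float, optional
        Candidate penalty weights, strictly positive and ascending.
        Defaults to :func:`default_lambda_grid`.
    cv_folds : int, default 5
        Number of shuffled CV folds used to score each penalty by pooled
        out-of-fold r2.
    random_state : int, default 0
        Seed for the fold shuffle.

    Attributes
    ----------
    support_ : ndarray of bool
        Mask of selected columns.
    lambda_ : float
        Chosen penalty (grid member; ties broken toward the smaller value).
    cv_r2_ : float
        Pooled out-of-fold r2 at the chosen penalty.
    cv_r2_path_ : ndarray
        Pooled out-of-fold r2 for every grid value.
    coef_ : ndarray
        Full-train coefficients at the chosen penalty.
    """

    def __init__(self, lambda_grid=None, cv_folds: int = 5, random_state: int = 0):
        self.lambda_grid = lambda_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _resolve_grid(self) -> np.ndarray:
        if self.lambda_grid is None or (
            isinstance(self.lambda_grid, str) and self.lambda_grid == "paper_default"
        ):
            return default_lambda_grid()
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or (grid <= 0).any():
            raise ValueError("lambda_grid must be non-empty and strictly positive")
        if (np.diff(grid) <= 0).any():
            raise ValueError("lambda_grid must be strictly ascending")
        return grid

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2, y_numeric=True)
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if X.shape[0] < self.cv_folds:
            raise ValueError("need at least cv_folds samples")
        grid = self._resolve_grid()
        folds = list(
            KFold(
                n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
            ).split(X)
        )
        r2_path = np.empty(grid.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for i, lam in enumerate(grid):
                oof = np.empty_like(y)
                for tr, va in folds:
                    model = Lasso(alpha=lam, max_iter=10000)
                    model.fit(X[tr], y[tr])
                    oof[va] = model.predict(X[va])
                r2_path[i] = r2_score(y, oof)
            best = int(np.argmax(r2_path))  # first max -> smallest lambda on ties
            final = Lasso(alpha=grid[best], max_iter=10000).fit(X, y)
        self.lambda_ = float(grid[best])
        self.cv_r2_ = float(r2_path[best])
        self.cv_r2_path_ = r2_path
        self.coef_ = final.coef_
        self.support_ = final.coef_ != 0.0
        self.empty_selection_ = not bool(self.support_.any())
        if self.empty_selection_:
            warnings.warn(
                "LASSO selected no variables at any grid penalty", UserWarning
            )
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def to_selection_result(self, names: list[str] | None = None) -> SelectionResult:
        check_is_fitted(self, "support_")
        meta = {
            "lambda": self.lambda_,
            "cv_r2": self.cv_r2_,
            "seed": self.random_state,
            "empty_selection": self.empty_selection_,
        }
        return result_from_support("lasso", self.support_, meta, names)


def select_lasso(
    train: Dataset,
    lambda_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Run LASSO selection on a (pre-autoscaled) training dataset."""
    sel = LassoSelector(lambda_grid=lambda_grid, cv_folds=cv_folds, random_state=seed)
    sel.fit(train.X, train.y)
    return sel.to_selection_result(names=train.names)
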