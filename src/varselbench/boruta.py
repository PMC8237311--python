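"""All-relevant variable selection with shadow features (Boruta, r-Boruta).

Each iteration permutes every active column independently to make
"shadow" copies that keep the marginal distribution but lose any relation
to the response, fits a random-forest regressor on [originals | shadows],
and counts a *hit* for every original whose importance strictly exceeds
the p-th percentile of the shadow importances (p = 100, the shadow
maximum, in plain Boruta).  Accumulated hit counts are tested against
Binomial(trials, 1/2) with a two-sided test at level alpha: columns in
the upper tail are confirmed, lower tail rejected (and removed from
subsequent iterations), others stay tentative.

r-Boruta calibrates the percentile to chance correlation: it draws a
large batch of standard-normal columns, computes their absolute Pearson
correlations with y, and uses 100 x max|r| as p.  At small sample sizes
chance correlations are large, so p drops well below 100 and the hit bar
becomes less extreme, preventing over-deletion of weakly relevant
descriptors.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataset import Dataset
from .selection import SelectionResult, result_from_support

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


def make_shadow(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute the rows of every column of X."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("X must be non-empty")
    return rng.permuted(X, axis=0)


def hit_update(
    importances: np.ndarray, n_original: int, percentile: float = 100.0
) -> np.ndarray:
    """Compare original importances against the shadow percentile reference.

    ``importances`` stacks the originals first and their shadows second.
    The reference is the ``percentile``-th percentile of the shadow
    importances (linear interpolation between order statistics; at 100
    this is exactly the shadow maximum).  A column is a hit only when its
    importance is strictly greater than the reference.
    """
    importances = np.asarray(importances, dtype=float)
    if importances.shape[0] <= n_original:
        raise ValueError("importances must cover originals and their shadows")
    reference = np.percentile(importances[n_original:], percentile)
    return importances[:n_original] > reference


def binomial_decision(hits: int, trials: int, alpha: float = 0.05) -> str:
    """Two-sided exact binomial test of the hit count against p = 1/2.

    Returns ``confirmed`` when P[H >= hits] < alpha/2 under
    Binomial(trials, 1/2), ``rejected`` when P[H <= hits] < alpha/2, and
    ``tentative`` otherwise.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= hits <= trials:
        raise ValueError("hits must lie in [0, trials]")
    upper = binom.sf(hits - 1, trials, 0.5)  # P[H >= hits]
    lower = binom.cdf(hits, trials, 0.5)  # P[H <= hits]
    if upper < alpha / 2.0:
        return CONFIRMED
    if lower < alpha / 2.0:
        return REJECTED
    return TENTATIVE


def rboruta_percentile(
    y: np.ndarray, n_random: int = 10_000, rng: np.random.Generator | None = None
) -> float:
    """Chance-correlation percentile: 100 x max |Pearson r(y, random N(0,1))|.

    Draws ``n_random`` standard-normal columns of the same length as y and
    returns 100 times the largest absolute correlation, a value in
    (0, 100] that shrinks toward 0 as the sample size grows.
    """
    y = np.asarray(y, dtype=float).ravel()
    if rng is None:
        rng = np.random.default_rng()
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    sd = y.std()
    if sd == 0:
        raise ValueError("y is constant; correlation undefined")
    z = (y - y.mean()) / sd
    R = rng.standard_normal((y.size, n_random))
    R = (R - R.mean(axis=0)) / R.std(axis=0)
    r = np.abs(z @ R) / y.size
    return float(min(100.0 * r.max(), 100.0))


class BorutaSelector(SelectorMixin, BaseEstimator):
    """Boruta all-relevant selection with a random-forest importance engine.

    Parameters
    ----------
    percentile : float, default 100
        Shadow-importance percentile used as the hit reference.
    alpha : float, default 0.05
        Two-sided significance level of the binomial decisions.
    max_iter : int, default 100
        Maximum number of shuffle/fit/test iterations.
    rf_trees : int, default 500
        Trees per random forest.
    rf_max_features : float or str, default 1/3
        Features considered per split (regression-forest convention).
    tentative_policy : {"exclude", "include"}, default "exclude"
        Whether columns still tentative at the end count as selected.
    random_state : int, default 0
        Seeds both the shadow shuffles and the forests.

    Attributes
    ----------
    support_ : ndarray of bool
    decision_ : ndarray of str  — confirmed / rejected / tentative per column
    hits_ : ndarray of int      — accumulated hit counts (frozen on rejection)
    trials_ : ndarray of int    — iterations each column participated in
    n_iter_ : int
    percentile_ : float         — the percentile actually used
    """

    _method_name = "boruta"

    def __init__(
        self,
        percentile: float = 100.0,
        alpha: float = 0.05,
        max_iter: int = 100,
        rf_trees: int = 500,
        rf_max_features=1.0 / 3.0,
        tentative_policy: str = "exclude",
        random_state: int = 0,
    ):
        self.percentile = percentile
        self.alpha = alpha
        self.max_iter = max_iter
        self.rf_trees = rf_trees
        self.rf_max_features = rf_max_features
        self.tentative_policy = tentative_policy
        self.random_state = random_state

    # hook for the chance-correlation variant
    def _resolve_percentile(self, X: np.ndarray, y: np.ndarray) -> float:
        if not 0.0 < self.percentile <= 100.0:
            raise ValueError("percentile must lie in (0, 100]")
        return float(self.percentile)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=5, y_numeric=True)
        if self.max_iter < 5:
            raise ValueError("max_iter must be >= 5")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tentative_policy not in ("exclude", "include"):
            raise ValueError("tentative_policy must be 'exclude' or 'include'")
        nz = X.std(axis=0) > 0
        if nz.sum() < 2:
            raise ValueError("need at least 2 non-constant columns")
        percentile = self._resolve_percentile(X, y)
        rng = np.random.default_rng(self.random_state)

        p = X.shape[1]
        hits = np.zeros(p, dtype=int)
        trials = np.zeros(p, dtype=int)
        decision = np.full(p, TENTATIVE, dtype=object)
        active = np.ones(p, dtype=bool)  # confirmed stay in the model matrix

        it = 0
        while it < self.max_iter and (decision == TENTATIVE).any():
            it += 1
            idx = np.flatnonzero(active)
            Xa = X[:, idx]
            shadows = make_shadow(Xa, rng)
            rf = RandomForestRegressor(
                n_estimators=self.rf_trees,
                max_features=self.rf_max_features,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            try:
                rf.fit(np.hstack([Xa, shadows]), y)
            except Exception as exc:  # pragma: no cover - backend failure path
                raise RuntimeError(
                    f"random-forest fit failed at iteration {it}"
                ) from exc
            hit = hit_update(rf.feature_importances_, idx.size, percentile)
            hits[idx] += hit
            trials[idx] += 1
            for j in idx[decision[idx] == TENTATIVE]:
                decision[j] = binomial_decision(int(hits[j]), int(trials[j]), self.alpha)
                if decision[j] == REJECTED:
                    active[j] = False  # removed from further iterations

        self.n_iter_ = it
        self.percentile_ = percentile
        self.hits_ = hits
        self.trials_ = trials
        self.decision_ = decision
        selected = decision == CONFIRMED
        if self.tentative_policy == "include":
            selected = selected | (decision == TENTATIVE)
        self.support_ = selected
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def to_selection_result(self, names: list[str] | None = None) -> SelectionResult:
        check_is_fitted(self, "support_")
        meta = {
            "percentile": self.percentile_,
            "alpha": self.alpha,
            "iterations": self.n_iter_,
            "hits": self.hits_.tolist(),
            "trials": self.trials_.tolist(),
            "decision": list(self.decision_),
            "seed": self.random_state,
            "tentative_policy": self.tentative_policy,
        }
        tentative = self.decision_ == TENTATIVE
        return result_from_support(
            self._method_name, self.support_, meta, names, tentative=tentative
        )


class RBorutaSelector(BorutaSelector):
    """Boruta with the percentile set by chance-correlation calibration.

    Before the Boruta loop runs, ``n_random`` standard-normal columns are
    drawn (from a generator seeded independently of the loop, so the loop
    consumes an identical random stream to :class:`BorutaSelector`) and
    the percentile is set to 100 x max |Pearson r| with y.  Setting
    ``percentile_override`` bypasses the calibration while exercising the
    same code path, which makes r-Boruta at an override of 100 exactly
    reproduce Boruta.
    """

    _method_name = "rboruta"

    def __init__(
        self,
        n_random: int = 10_000,
        percentile_override: float | None = None,
        alpha: float = 0.05,
        max_iter: int = 100,
        rf_trees: int = 500,
        rf_max_features=1.0 / 3.0,
        tentative_policy: str = "exclude",
        random_state: int = 0,
    ):
        super().__init__(
            percentile=100.0,
            alpha=alpha,
            max_iter=max_iter,
            rf_trees=rf_trees,
            rf_max_features=rf_max_features,
            tentative_policy=tentative_policy,
            random_state=random_state,
        )
        self.n_random = n_random
        self.percentile_override = percentile_override

    def _resolve_percentile(self, X: np.ndarray, y: np.ndarray) -> float:
        if self.percentile_override is not None:
            return float(self.percentile_override)
        rng = np.random.default_rng([self.random_state, 0x5EED])
        return rboruta_percentile(y, self.n_random, rng)


def run_boruta(
    train: Dataset,
    percentile: float = 100.0,
    alpha: float = 0.05,
    max_iter: int = 100,
    rf_trees: int = 500,
    tentative_policy: str = "exclude",
    seed: int = 0,
) -> SelectionResult:
    """Run Boruta on a training dataset and return a SelectionResult."""
    sel = BorutaSelector(
        percentile=percentile,
        alpha=alpha,
        max_iter=max_iter,
        rf_trees=rf_trees,
        tentative_policy=tentative_policy,
        random_state=seed,
    )
    sel.fit(train.X, train.y)
    return sel.to_selection_result(names=train.names)


def run_rboruta(
    train: Dataset,
    n_random: int = 10_000,
    percentile_override: float | None = None,
    alpha: float = 0.05,
    max_iter: int = 100,
    rf_trees: int = 500,
    tentative_policy: str = "exclude",
    seed: int = 0,
) -> SelectionResult:
    """Run r-Boruta (chance-correlation percentile) on a training dataset."""
    sel = RBorutaSelector(
        n_random=n_random,
        percentile_override=percentile_override,
        alpha=alpha,
        max_iter=max_iter,
        rf_trees=rf_trees,
        tentative_policy=tentative_policy,
        random_state=seed,
    )
    sel.fit(train.X, train.y)
    return sel.to_selection_result(names=train.names)
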