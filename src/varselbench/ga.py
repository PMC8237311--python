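"""Wrapper variable selection by a genetic algorithm (GAPLS / GASVR).

Chromosomes are real vectors in [0,1]: one gene per descriptor, binarized
at a threshold (gene >= 0.5 means the column enters the model), plus, for
GASVR, three trailing genes that decode on log2 scales to the SVR
regularization parameter C, the epsilon-insensitive tube width, and the
Gaussian-kernel width gamma.  Fitness is the pooled out-of-fold r2 of a
5-fold cross-validation of the wrapped model (PLS with an internally
chosen component count, or Gaussian-kernel SVR) on the masked columns.
The GA itself is a plain generational scheme: tournament selection,
uniform crossover, per-gene uniform-reset mutation, and elitism of one,
which makes the best fitness monotone non-decreasing across generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataset import Dataset
from .selection import SelectionResult, result_from_support

NEG_INF = float("-inf")

DEFAULT_SVR_GENE_RANGES = ((-5.0, 10.0), (-10.0, 0.0), (-20.0, 10.0))


def decode_mask(genes: np.ndarray, threshold: float = 0.5, n_vars: int | None = None) -> np.ndarray:
    """Binarize the first ``n_vars`` genes: included iff gene >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    genes = np.asarray(genes, dtype=float)
    if n_vars is None:
        n_vars = genes.size
    return genes[:n_vars] >= threshold


def decode_svr_params(
    genes: np.ndarray, ranges=DEFAULT_SVR_GENE_RANGES
) -> tuple[float, float, float]:
    """Map the 3 trailing genes to (C, epsilon, gamma) via 2^(lo + g*(hi-lo))."""
    genes = np.asarray(genes, dtype=float)
    if genes.size < 3:
        raise ValueError("chromosome must carry 3 trailing SVR genes")
    out = []
    for g, (lo, hi) in zip(genes[-3:], ranges):
        if lo >= hi:
            raise ValueError(f"invalid gene range ({lo}, {hi}): lo must be < hi")
        out.append(2.0 ** (lo + g * (hi - lo)))
    return tuple(out)  # type: ignore[return-value]


def _pooled_cv_r2(model_factory, X, y, folds) -> float:
    oof = np.empty_like(y, dtype=float)
    for tr, va in folds:
        m = model_factory()
        m.fit(X[tr], y[tr])
        oof[va] = np.asarray(m.predict(X[va])).ravel()
    return float(r2_score(y, oof))


def fitness_gapls(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    folds,
    max_pls_components: int = 30,
) -> float:
    """Pooled CV r2 of a PLS model on the masked columns.

    The component count is chosen internally: the pooled CV r2 is
    evaluated for every count from 1 to min(max_pls_components, number of
    masked columns, smallest-fold size - 1) and the best is returned.
    Empty masks score -inf.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return NEG_INF
    Xm = X[:, mask]
    min_train = min(len(tr) for tr, _ in folds)
    max_comp = min(max_pls_components, Xm.shape[1], min_train - 1)
    best = NEG_INF
    for ncomp in range(1, max_comp + 1):
        r2 = _pooled_cv_r2(lambda: PLSRegression(n_components=ncomp, scale=False), Xm, y, folds)
        if r2 > best:
            best = r2
    return best


def fitness_gasvr(
    genes: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    folds,
    mask_threshold: float = 0.5,
    ranges=DEFAULT_SVR_GENE_RANGES,
) -> float:
    """Pooled CV r2 of a Gaussian-kernel SVR decoded from the chromosome."""
    n_vars = X.shape[1]
    mask = decode_mask(genes, mask_threshold, n_vars)
    if not mask.any():
        return NEG_INF
    C, eps, gamma = decode_svr_params(genes, ranges)
    return _pooled_cv_r2(
        lambda: SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma), X[:, mask], y, folds
    )


@dataclass
class GAConfig:
    """GA settings shared by GAPLS and GASVR (see class docstrings)."""

    population_size: int = 100
    generations: int = 50
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # None -> 1/chromosome_length
    mask_threshold: float = 0.5
    cv_folds: int = 5
    max_pls_components: int = 30
    svr_gene_ranges: tuple = DEFAULT_SVR_GENE_RANGES
    seed: int = 0


class _BaseGASelector(SelectorMixin, BaseEstimator):
    """Shared GA engine; subclasses define chromosome length and fitness."""

    _method_name = "ga"
    _extra_genes = 0

    def __init__(
        self,
        population_size: int = 100,
        generations: int = 50,
        crossover_prob: float = 0.9,
        mutation_prob: float | None = None,
        mask_threshold: float = 0.5,
        cv_folds: int = 5,
        max_pls_components: int = 30,
        svr_gene_ranges=DEFAULT_SVR_GENE_RANGES,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.mask_threshold = mask_threshold
        self.cv_folds = cv_folds
        self.max_pls_components = max_pls_components
        self.svr_gene_ranges = svr_gene_ranges
        self.random_state = random_state

    # subclass hook ---------------------------------------------------
    def _evaluate(self, genes: np.ndarray, X, y, folds) -> float:
        raise NotImplementedError

    def _cache_key(self, genes: np.ndarray, n_vars: int):
        return decode_mask(genes, self.mask_threshold, n_vars).tobytes()

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=5, y_numeric=True)
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for p in (self.crossover_prob,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("crossover_prob must lie in [0, 1]")
        n_vars = X.shape[1]
        length = n_vars + self._extra_genes
        mut_p = self.mutation_prob if self.mutation_prob is not None else 1.0 / length
        if not 0.0 <= mut_p <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        rng = np.random.default_rng(self.random_state)
        folds = list(
            KFold(self.cv_folds, shuffle=True, random_state=self.random_state).split(X)
        )
        cache: dict = {}

        def evaluate(genes: np.ndarray) -> float:
            key = self._cache_key(genes, n_vars)
            if key not in cache:
                cache[key] = self._evaluate(genes, X, y, folds)
            return cache[key]

        def tournament(pop, fits, k=3):
            idx = rng.integers(len(pop), size=k)
            return pop[idx[np.argmax(fits[idx])]]

        pop = rng.random((self.population_size, length))
        fits = np.array([evaluate(ind) for ind in pop])
        best_i = int(np.argmax(fits))
        best, best_fit = pop[best_i].copy(), float(fits[best_i])
        history = [best_fit]

        for _ in range(self.generations):
            children = [best.copy()]  # elitism of 1
            while len(children) < self.population_size:
                a = tournament(pop, fits).copy()
                b = tournament(pop, fits).copy()
                if rng.random() < self.crossover_prob:  # uniform crossover
                    swap = rng.random(length) < 0.5
                    a[swap], b[swap] = b[swap].copy(), a[swap].copy()
                for child in (a, b):
                    mut = rng.random(length) < mut_p
                    child[mut] = rng.random(int(mut.sum()))
                children.append(a)
                if len(children) < self.population_size:
                    children.append(b)
            pop = np.asarray(children)
            fits = np.array([evaluate(ind) for ind in pop])
            gen_best = int(np.argmax(fits))
            if fits[gen_best] > best_fit:
                best, best_fit = pop[gen_best].copy(), float(fits[gen_best])
            history.append(best_fit)

        self.best_chromosome_ = best
        self.best_fitness_ = best_fit
        self.history_ = np.asarray(history)
        self.support_ = decode_mask(best, self.mask_threshold, n_vars)
        self.n_evaluations_ = len(cache)
        self._post_fit(best)
        return self

    def _post_fit(self, best: np.ndarray) -> None:
        pass

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def to_selection_result(self, names: list[str] | None = None) -> SelectionResult:
        check_is_fitted(self, "support_")
        meta = {
            "best_fitness": self.best_fitness_,
            "history": self.history_.tolist(),
            "seed": self.random_state,
            "n_unique_evaluations": self.n_evaluations_,
        }
        meta.update(self._extra_meta())
        return result_from_support(self._method_name, self.support_, meta, names)

    def _extra_meta(self) -> dict:
        return {}


class GAPLSSelector(_BaseGASelector):
    """GA-wrapped PLS variable selection (linear fitness)."""

    _method_name = "gapls"
    _extra_genes = 0

    def _evaluate(self, genes, X, y, folds):
        mask = decode_mask(genes, self.mask_threshold, X.shape[1])
        return fitness_gapls(mask, X, y, folds, self.max_pls_components)


class GASVRSelector(_BaseGASelector):
    """GA-wrapped Gaussian-kernel SVR selection with 3 hyperparameter genes."""

    _method_name = "gasvr"
    _extra_genes = 3

    def _cache_key(self, genes, n_vars):
        mask = decode_mask(genes, self.mask_threshold, n_vars)
        params = decode_svr_params(genes, self.svr_gene_ranges)
        return (mask.tobytes(), params)

    def _evaluate(self, genes, X, y, folds):
        return fitness_gasvr(
            genes, X, y, folds, self.mask_threshold, self.svr_gene_ranges
        )

    def _post_fit(self, best):
        self.svr_params_ = decode_svr_params(best, self.svr_gene_ranges)

    def _extra_meta(self):
        C, eps, gamma = self.svr_params_
        return {"svr_params": {"C": C, "epsilon": eps, "gamma": gamma}}


def run_ga(train: Dataset, mode: str, cfg: GAConfig | None = None) -> SelectionResult:
    """Run GAPLS or GASVR on a (pre-autoscaled) training dataset."""
    cfg = cfg or GAConfig()
    cls = {"gapls": GAPLSSelector, "gasvr": GASVRSelector}.get(mode)
    if cls is None:
        raise ValueError(f"mode must be 'gapls' or 'gasvr', got {mode!r}")
    sel = cls(
        population_size=cfg.population_size,
        generations=cfg.generations,
        crossover_prob=cfg.crossover_prob,
        mutation_prob=cfg.mutation_prob,
        mask_threshold=cfg.mask_threshold,
        cv_folds=cfg.cv_folds,
        max_pls_components=cfg.max_pls_components,
        svr_gene_ranges=cfg.svr_gene_ranges,
        random_state=cfg.seed,
    )
    sel.fit(train.X, train.y)
    return sel.to_selection_result(names=train.names)
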