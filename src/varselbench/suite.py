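"""The multi-regressor evaluation suite and its MAE reduction.

Judging a variable selection by a single regressor confounds the
selection with the regressor's own inductive bias, so the benchmark fits
many regression families on the selected columns and summarizes their
test MAEs by the 10th percentile ("the best decile of models").  The
default ("paper") profile holds 24 configurations: PLS, ridge, LASSO,
elastic net, SVR with linear and Gaussian kernels, decision tree, random
forest, Gaussian-process regression with 11 registered kernels,
gradient-boosted trees, XGBoost, LightGBM, a histogram gradient-boosted
tree config, and a small multilayer-perceptron network.  A "fast"
profile keeps 8 lightweight configurations for quick runs; the reducer
contract is identical for any profile size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process import kernels as gk
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.metrics import mean_absolute_error
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .dataset import Dataset

# ---------------------------------------------------------------------------
# GPR kernel registry: 11 named kernels, swappable by editing this dict.
# ---------------------------------------------------------------------------
GPR_KERNELS = {
    "linear": lambda: gk.DotProduct(),
    "rbf": lambda: gk.RBF(),
    "matern15": lambda: gk.Matern(nu=1.5),
    "matern25": lambda: gk.Matern(nu=2.5),
    "rq": lambda: gk.RationalQuadratic(),
    "linear+white": lambda: gk.DotProduct() + gk.WhiteKernel(),
    "rbf+white": lambda: gk.RBF() + gk.WhiteKernel(),
    "matern15+white": lambda: gk.Matern(nu=1.5) + gk.WhiteKernel(),
    "matern25+white": lambda: gk.Matern(nu=2.5) + gk.WhiteKernel(),
    "rq+white": lambda: gk.RationalQuadratic() + gk.WhiteKernel(),
    "linear+rbf": lambda: gk.DotProduct() + gk.RBF(),
}


@dataclass
class RegressorConfig:
    """One regression configuration: a family, an optional kernel, a grid."""

    config_id: str
    family: str
    make: "callable"  # (seed) -> unfitted estimator
    param_grid: dict = field(default_factory=dict)
    kernel: str | None = None
    seed: int = 0

    def build(self):
        return self.make(self.seed)


def _log2_grid(lo: int, hi: int, step: int = 2) -> list[float]:
    return [2.0**k for k in range(lo, hi + 1, step)]


def build_default_suite(seed: int = 0, profile: str = "paper") -> list[RegressorConfig]:
    """Construct the regression suite for a profile.

    ``"paper"`` returns the full 24 configurations (SVR expanded to linear
    and Gaussian kernels, GPR expanded to the 11 registered kernels);
    ``"fast"`` returns 8 lightweight configurations.
    """
    cfgs: list[RegressorConfig] = []

    def add(config_id, family, make, grid=None, kernel=None):
        cfgs.append(
            RegressorConfig(
                config_id=config_id,
                family=family,
                make=make,
                param_grid=grid or {},
                kernel=kernel,
                seed=seed,
            )
        )

    add(
        "pls", "PLS",
        lambda s: PLSRegression(scale=False),
        {"n_components": list(range(1, 11))},
    )
    add("rr", "RR", lambda s: Ridge(), {"alpha": _log2_grid(-5, 10)})
    add(
        "lasso", "LASSO",
        lambda s: Lasso(max_iter=10000),
        {"alpha": _log2_grid(-15, -1)},
    )
    add(
        "en", "EN",
        lambda s: ElasticNet(max_iter=10000),
        {"alpha": _log2_grid(-10, 0), "l1_ratio": [0.1, 0.5, 0.9]},
    )
    add(
        "svr_linear", "SVR",
        lambda s: SVR(kernel="linear"),
        {"C": [0.1, 1.0, 10.0], "epsilon": [0.01, 0.1]},
        kernel="linear",
    )
    add(
        "svr_gaussian", "SVR",
        lambda s: SVR(kernel="rbf"),
        {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
        kernel="gaussian",
    )
    add(
        "dt", "DT",
        lambda s: DecisionTreeRegressor(random_state=s),
        {"max_depth": [2, 4, 8, None]},
    )
    add(
        "rf", "RF",
        lambda s: RandomForestRegressor(n_estimators=300, random_state=s, n_jobs=1),
        {"max_features": [1.0 / 3.0, "sqrt"]},
    )

    if profile == "fast":
        return cfgs

    if profile != "paper":
        raise ValueError(f"unknown suite profile {profile!r}")

    for kname, kfactory in GPR_KERNELS.items():
        add(
            f"gpr_{kname}", "GPR",
            (lambda s, kf=kfactory: GaussianProcessRegressor(
                kernel=kf(), alpha=1e-2, normalize_y=True, random_state=s
            )),
            kernel=kname,
        )
    add(
        "gbdt", "GBDT",
        lambda s: GradientBoostingRegressor(random_state=s),
        {"max_depth": [2, 3]},
    )

    def _xgb(s):
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=200, learning_rate=0.1, random_state=s, verbosity=0,
            n_jobs=1,
        )

    add("xgb", "XGBoost", _xgb, {"max_depth": [2, 4]})

    def _lgbm(s):
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            n_estimators=200, learning_rate=0.1, random_state=s, verbose=-1,
            n_jobs=1,
        )

    add("lgbm", "LightGBM", _lgbm, {"num_leaves": [7, 31]})
    add(
        "hgb", "HistGB",
        lambda s: HistGradientBoostingRegressor(random_state=s),
        {"learning_rate": [0.05, 0.1]},
    )
    add(
        "dnn", "DNN",
        lambda s: MLPRegressor(
            hidden_layer_sizes=(64, 64), max_iter=800, random_state=s
        ),
    )
    return cfgs


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------
def mae(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error, in the units of y."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape or y_obs.size == 0:
        raise ValueError("y_obs and y_pred must be equal-length, non-empty")
    return float(mean_absolute_error(y_obs, y_pred))


def percentile_mae(values, q: float = 10.0) -> float:
    """Percentile of a set of MAEs, linear interpolation between order stats."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if not 0.0 <= q <= 100.0:
        raise ValueError("q must lie in [0, 100]")
    return float(np.percentile(values, q))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------
def _clip_grid(config: RegressorConfig, n_features: int, n_train: int) -> dict:
    grid = dict(config.param_grid)
    if config.family == "PLS" and "n_components" in grid:
        cap = max(1, min(n_features, n_train - 2))
        vals = [v for v in grid["n_components"] if v <= cap] or [1]
        grid["n_components"] = vals
    return grid


def fit_predict_mae(
    config: RegressorConfig,
    train: Dataset,
    test: Dataset,
    mask: np.ndarray,
    y_center: float = 0.0,
    y_scale: float = 1.0,
) -> float:
    """Tune, refit, predict and score one configuration.

    Hyperparameters are tuned by seeded shuffled 5-fold CV (r2 scoring)
    over the config's grid on the masked training columns; the tuned
    model is refit on the full training partition and scored by test MAE
    reported in original response units via ``y_center``/``y_scale``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must select at least one column")
    if train.names != test.names:
        raise ValueError("train and test are not column-compatible")
    Xtr, Xte = train.X[:, mask], test.X[:, mask]
    grid = _clip_grid(config, Xtr.shape[1], Xtr.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        if grid:
            cv = KFold(5, shuffle=True, random_state=config.seed)
            model = GridSearchCV(config.build(), grid, cv=cv, scoring="r2", n_jobs=1)
        else:
            model = config.build()
        model.fit(Xtr, train.y)
        pred = np.asarray(model.predict(Xte)).ravel()
    return mae(test.y * y_scale + y_center, pred * y_scale + y_center)


@dataclass
class SuiteResult:
    """Per-configuration test MAEs plus their 10th-percentile summary."""

    per_config_mae: dict
    mae_p10: float
    n_selected: int
    profile: str
    failures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.per_config_mae:
            vals = np.asarray(list(self.per_config_mae.values()))
            if not (vals.min() - 1e-12 <= self.mae_p10 <= vals.max() + 1e-12):
                raise ValueError("mae_p10 must lie between the min and max MAE")


def run_suite(
    configs: list[RegressorConfig],
    train: Dataset,
    test: Dataset,
    mask: np.ndarray,
    y_center: float = 0.0,
    y_scale: float = 1.0,
    profile: str = "custom",
) -> SuiteResult:
    """Fit every configuration on the masked columns and reduce to p10 MAE.

    A configuration whose fit raises is recorded under ``failures`` (with
    the error message) and excluded from the percentile rather than
    voiding the whole suite.
    """
    per_config = {}
    failures = []
    for cfg in configs:
        try:
            per_config[cfg.config_id] = fit_predict_mae(
                cfg, train, test, mask, y_center, y_scale
            )
        except ValueError:
            raise  # contract errors (empty mask, incompatible columns)
        except Exception as exc:
            warnings.warn(f"suite config {cfg.config_id} failed: {exc}", UserWarning)
            failures.append({"config_id": cfg.config_id, "error": str(exc)})
    if not per_config:
        raise RuntimeError("every suite configuration failed")
    return SuiteResult(
        per_config_mae=per_config,
        mae_p10=percentile_mae(list(per_config.values()), 10.0),
        n_selected=int(np.asarray(mask, dtype=bool).sum()),
        profile=profile,
        failures=failures,
    )
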