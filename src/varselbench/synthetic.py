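"""Synthetic regression datasets with known informative structure.

The generator emulates the shape of small QSAR/QSPR descriptor tables:
a block of mutually correlated informative descriptors with decaying
effect sizes, plus independent noise descriptors unrelated to the
response.  Because the informative set is known, selector output can be
scored as recall/precision against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .selection import SelectionResult


def _default_coefficients() -> np.ndarray:
    # geometric decay from 3 down to 0.3 across the informative block
    return np.geomspace(3.0, 0.3, 10)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset draw.

    Defaults give the benchmark fixture used throughout: n=200 samples,
    10 informative + 65 noise descriptors (close to a 75-descriptor
    small-molecule table), informative effect sizes decaying
    geometrically from 3 to 0.3, equicorrelation 0.3 inside the
    informative block, and unit-variance response noise.
    """

    n_samples: int = 200
    n_informative: int = 10
    n_noise: int = 65
    coefficients: np.ndarray = field(default_factory=_default_coefficients)
    within_block_correlation: float = 0.3
    noise_sd: float = 1.0
    response: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.n_informative < 1:
            raise ValueError("need at least one informative variable")
        if self.n_noise < 0 or self.n_samples < 2:
            raise ValueError("counts must be positive")
        if len(self.coefficients) != self.n_informative:
            raise ValueError("coefficients length must equal n_informative")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError("within_block_correlation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.response not in ("linear", "quadratic_interaction"):
            raise ValueError(f"unknown response kind {self.response!r}")


@dataclass
class GroundTruth:
    """Which generated columns actually drive the response."""

    informative_mask: np.ndarray

    def __post_init__(self) -> None:
        self.informative_mask = np.asarray(self.informative_mask, dtype=bool)

    @property
    def informative_idx(self) -> np.ndarray:
        return np.flatnonzero(self.informative_mask)


def generate(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset from the spec; deterministic per seed.

    The informative block is multivariate normal with an equicorrelation
    matrix (rho = ``within_block_correlation``, always positive definite
    for rho < 1); noise columns are i.i.d. standard normal.  The response
    is ``X_inf @ coefficients`` plus, for ``quadratic_interaction``, the
    product of the first two informative columns, plus N(0, noise_sd)
    observation noise.
    """
    rng = np.random.default_rng(spec.seed)
    k, n = spec.n_informative, spec.n_samples
    rho = spec.within_block_correlation
    # equicorrelated draw via the one-factor construction:
    # x_j = sqrt(rho) * z + sqrt(1-rho) * e_j
    z = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, k))
    X_inf = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * e
    X_noise = rng.standard_normal((n, spec.n_noise))
    y = X_inf @ spec.coefficients
    if spec.response == "quadratic_interaction" and k >= 2:
        y = y + X_inf[:, 0] * X_inf[:, 1]
    if spec.noise_sd > 0:
        y = y + rng.normal(scale=spec.noise_sd, size=n)
    X = np.hstack([X_inf, X_noise])
    names = [f"inf_{i + 1}" for i in range(k)] + [
        f"noise_{i + 1}" for i in range(spec.n_noise)
    ]
    mask = np.zeros(k + spec.n_noise, dtype=bool)
    mask[:k] = True
    return Dataset(X=X, y=y, names=names), GroundTruth(informative_mask=mask)


def recovery_metrics(
    sel: SelectionResult | np.ndarray, truth: GroundTruth
) -> tuple[float, float]:
    """Recall and precision of a selection against the informative set.

    Conventions for degenerate inputs: precision is 1 when nothing is
    selected and nothing is informative, 0 when the selection is empty
    but informative variables exist.
    """
    if isinstance(sel, SelectionResult):
        selected = sel.support
    else:
        selected = np.asarray(sel, dtype=bool)
    informative = truth.informative_mask
    if selected.shape != informative.shape:
        raise ValueError(
            f"selection covers {selected.shape[0]} columns but the ground "
            f"truth covers {informative.shape[0]}"
        )
    tp = int((selected & informative).sum())
    n_inf = int(informative.sum())
    n_sel = int(selected.sum())
    recall = tp / n_inf if n_inf else 1.0
    if n_sel == 0:
        precision = 1.0 if n_inf == 0 else 0.0
    else:
        precision = tp / n_sel
    return recall, precision
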