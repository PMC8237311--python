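"""Tabular regression datasets with per-column origin tracking.

A :class:`Dataset` holds a numeric descriptor matrix ``X`` (samples x
variables), a continuous target ``y``, unique column names, and a per-column
``origin`` flag distinguishing the original descriptors from spiked random
probe columns.  The origin flags are what let the evaluation layer measure
how many probe variables a selector wrongly picked.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ORIGIN_ORIGINAL = "original"
ORIGIN_PROBE = "random_probe"


@dataclass
class Dataset:
    """Numeric regression table with per-column origin flags.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_vars)
        Descriptor matrix, finite floats.
    y : ndarray of shape (n_samples,)
        Continuous response.
    names : list of str
        Unique column labels, one per column of ``X``.
    origin : ndarray of str
        Per-column flag, ``"original"`` or ``"random_probe"``.
    """

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]}"
            )
        self.names = list(self.names)
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names length must equal the number of columns")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate column names: {dupes}")
        if self.origin is None:
            self.origin = np.full(self.X.shape[1], ORIGIN_ORIGINAL, dtype=object)
        self.origin = np.asarray(self.origin, dtype=object)
        if self.origin.shape[0] != self.X.shape[1]:
            raise ValueError("origin length must equal the number of columns")
        bad = set(self.origin) - {ORIGIN_ORIGINAL, ORIGIN_PROBE}
        if bad:
            raise ValueError(f"unknown origin flags: {bad}")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise ValueError("X and y must be finite with no missing values")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    @property
    def original_mask(self) -> np.ndarray:
        """Boolean mask of columns carrying real descriptors."""
        return self.origin == ORIGIN_ORIGINAL

    @property
    def probe_mask(self) -> np.ndarray:
        """Boolean mask of spiked random-probe columns."""
        return self.origin == ORIGIN_PROBE

    @property
    def n_original(self) -> int:
        return int(self.original_mask.sum())

    # -- slicing --------------------------------------------------------
    def take_rows(self, idx: Sequence[int] | np.ndarray) -> "Dataset":
        idx = np.asarray(idx)
        return replace(self, X=self.X[idx], y=self.y[idx])

    def take_columns(self, idx: Sequence[int] | np.ndarray) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            X=self.X[:, idx],
            y=self.y,
            names=[self.names[i] for i in idx],
            origin=self.origin[idx],
        )

    def to_frame(self, target_name: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, target_name, self.y)
        return df


@dataclass
class SplitPair:
    """A train/test split sharing an identical column layout.

    ``y_center``/``y_scale`` record the train-set response statistics once
    :func:`varselbench.preprocess.autoscale` has run, so downstream MAE can
    be reported in the original response units.
    """

    train: Dataset
    test: Dataset
    seed: int
    y_center: float = 0.0
    y_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.train.names != self.test.names:
            raise ValueError("train and test must share column names and order")
        if not np.array_equal(self.train.origin, self.test.origin):
            raise ValueError("train and test must share origin flags")

    def inverse_y(self, y_scaled: np.ndarray) -> np.ndarray:
        """Map a (possibly scaled) response back to original units."""
        return np.asarray(y_scaled) * self.y_scale + self.y_center


def load_table(path: str | Path, target_column: str) -> Dataset:
    """Load a CSV with a header row into a :class:`Dataset`.

    All non-target columns must be numeric; any blank or non-numeric cell
    raises a :class:`ValueError` naming the offending row and column.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names in {path.name}: {dupes}")
    if target_column not in header:
        raise KeyError(
            f"target column {target_column!r} not found in {path.name}; "
            f"available: {header}"
        )
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    numeric = {}
    for col in raw.columns:
        vals = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            row = int(bad[0])
            cell = raw.at[bad[0], col]
            raise ValueError(
                f"non-numeric or missing value {cell!r} at row {row + 2} "
                f"(1-based, incl. header), column {col!r} of {path.name}"
            )
        numeric[col] = vals.to_numpy(dtype=float)
    y = numeric.pop(target_column)
    names = [c for c in raw.columns if c != target_column]
    X = np.column_stack([numeric[c] for c in names]) if names else np.empty((len(y), 0))
    return Dataset(X=X, y=y, names=names)


def write_table(ds: Dataset, path: str | Path, target_name: str = "y") -> None:
    """Write a dataset back to CSV (target first, descriptors after)."""
    ds.to_frame(target_name).to_csv(path, index=False)
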