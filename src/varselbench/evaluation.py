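"""Benchmark orchestration: selector x repeat runs and the three metrics.

Each run preprocesses a dataset (split, filter, probe-spike, autoscale),
applies every requested selector to the training partition, and scores
the selection three ways: the fraction of original descriptors selected,
the fraction of random probes selected (both relative to the number of
original descriptors), and the 10th-percentile test MAE of the
regression suite fitted on the selected columns — probes included when a
selector picked them, since a wrongly selected probe is part of the
model that selector proposes.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boruta import BorutaSelector, RBorutaSelector
from .dataset import Dataset, SplitPair, load_table
from .ga import GAPLSSelector, GASVRSelector
from .lasso import LassoSelector
from .preprocess import preprocess
from .selection import SelectionResult
from .suite import build_default_suite, run_suite
from .synthetic import SyntheticSpec, generate

SEED_STRIDE = 10007  # fixed stride so individual repeats are reproducible


def ratio_selected(sel: SelectionResult, ds: Dataset) -> float:
    """Selected original columns / all original columns."""
    orig = ds.original_mask
    n_orig = int(orig.sum())
    if n_orig == 0:
        raise ValueError("dataset has no original columns")
    return float((sel.support & orig).sum() / n_orig)


def ratio_random(sel: SelectionResult, ds: Dataset) -> float:
    """Selected probe columns / all *original* columns (the probe count)."""
    probes = ds.probe_mask
    if not probes.any():
        raise ValueError("dataset has no random_probe columns; spike it first")
    n_orig = int(ds.original_mask.sum())
    return float((sel.support & probes).sum() / n_orig)


# ---------------------------------------------------------------------------
# Selector registry
# ---------------------------------------------------------------------------
def make_selector(name: str, seed: int, **overrides):
    """Instantiate a selector by benchmark name with a run seed."""
    registry = {
        "lasso": LassoSelector,
        "gapls": GAPLSSelector,
        "gasvr": GASVRSelector,
        "boruta": BorutaSelector,
        "rboruta": RBorutaSelector,
    }
    if name not in registry:
        raise KeyError(f"unknown selector {name!r}; choose from {sorted(registry)}")
    return registry[name](random_state=seed, **overrides)


@dataclass
class RunSpec:
    """Everything one benchmark run needs, fully seeded.

    ``selectors`` maps selector names to keyword overrides for
    :func:`make_selector` (empty dict = defaults).  ``suite_profile`` may
    be None to skip MAE computation (ratio metrics only).
    """

    selectors: dict = field(
        default_factory=lambda: {
            "lasso": {}, "gapls": {}, "gasvr": {}, "boruta": {}, "rboruta": {}
        }
    )
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    data_path: str | None = None
    target_column: str = "y"
    n_repeats: int = 10
    base_seed: int = 0
    suite_profile: str | None = "fast"
    train_fraction: float = 0.7
    same_value_threshold: float = 0.8
    dedup_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.selectors:
            raise ValueError("selector list must be non-empty")


@dataclass
class EvaluationRecord:
    """One (selector, repeat) row of the benchmark."""

    method: str
    repeat: int
    seed: int
    n_original: int
    n_selected_original: int
    n_selected_random: int
    ratio_selected: float
    ratio_random: float
    mae_p10: float = float("nan")  # NaN flags a missing/omitted suite run
    error: str = ""


def _prepare_pair(spec: RunSpec, seed: int) -> SplitPair:
    if spec.data_path is not None:
        ds = load_table(spec.data_path, spec.target_column)
    else:
        ds, _ = generate(replace(spec.synthetic, seed=seed))
    return preprocess(
        ds,
        train_fraction=spec.train_fraction,
        same_value_threshold=spec.same_value_threshold,
        dedup_tol=spec.dedup_tol,
        seed=seed,
    )


def run_benchmark(
    spec: RunSpec, selection_dir: str | Path | None = None
) -> list[EvaluationRecord]:
    """Run every selector for every repeat and collect the three metrics.

    A failing selector yields a record carrying the error message instead
    of aborting the other selectors; an empty selection yields ratios of
    0 with the MAE flagged missing (NaN).
    """
    records: list[EvaluationRecord] = []
    for r in range(spec.n_repeats):
        seed_r = spec.base_seed + r * SEED_STRIDE
        pair = _prepare_pair(spec, seed_r)
        train, test = pair.train, pair.test
        suite = (
            build_default_suite(seed=seed_r, profile=spec.suite_profile)
            if spec.suite_profile
            else None
        )
        for name, overrides in spec.selectors.items():
            rec = EvaluationRecord(
                method=name, repeat=r, seed=seed_r,
                n_original=train.n_original,
                n_selected_original=0, n_selected_random=0,
                ratio_selected=0.0, ratio_random=0.0,
            )
            try:
                selector = make_selector(name, seed_r, **overrides)
                selector.fit(train.X, train.y)
                sel = selector.to_selection_result(names=train.names)
                if selection_dir is not None:
                    out = Path(selection_dir)
                    out.mkdir(parents=True, exist_ok=True)
                    sel.to_json(out / f"{name}_repeat{r}.json")
                rec.n_selected_original = int((sel.support & train.original_mask).sum())
                rec.n_selected_random = int((sel.support & train.probe_mask).sum())
                rec.ratio_selected = ratio_selected(sel, train)
                rec.ratio_random = ratio_random(sel, train)
                if suite is not None and sel.support.any():
                    res = run_suite(
                        suite, train, test, sel.support,
                        y_center=pair.y_center, y_scale=pair.y_scale,
                        profile=spec.suite_profile,
                    )
                    rec.mae_p10 = res.mae_p10
            except Exception as exc:
                rec.error = f"{type(exc).__name__}: {exc}"
            records.append(rec)
    return records


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def write_results(
    records: list[EvaluationRecord],
    path: str | Path,
    run_config: dict | None = None,
) -> Path:
    """Write a tidy CSV plus a JSON sidecar with configs and versions."""
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)
    import sklearn

    sidecar = {
        "run_config": run_config or {},
        "versions": {
            "python": platform.python_version(),
            "varselbench": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path.with_suffix(".config.json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def plot_benchmark(records: list[EvaluationRecord] | pd.DataFrame, save_to=None):
    """Three-panel scatter: (a) ratio vs ratio, (b) ratio vs MAE, (c) probe ratio vs MAE."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    panels = [
        ("ratio_selected", "ratio_random"),
        ("ratio_selected", "mae_p10"),
        ("ratio_random", "mae_p10"),
    ]
    for ax, (xcol, ycol) in zip(axes, panels):
        for method, grp in df.groupby("method"):
            ax.scatter(grp[xcol], grp[ycol], label=method, alpha=0.7)
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if save_to is not None:
        fig.savefig(save_to, dpi=120)
    return fig
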