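"""Train/test splitting, column filtering, probe spiking and autoscaling.

All column-dropping decisions are made on the training partition only and
then applied to both partitions, so the test set never influences which
descriptors survive.  The probe spiking step appends one uniform(0,1)
column per surviving original descriptor; the fraction of these probes a
selector later picks measures its tendency to select variables unrelated
to the response.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .dataset import ORIGIN_ORIGINAL, ORIGIN_PROBE, Dataset, SplitPair

PROBE_PREFIX = "RANDPROBE_"


def split_train_test(ds: Dataset, train_fraction: float = 0.7, seed: int = 0) -> SplitPair:
    """Randomly partition samples into train and test sets.

    ``n_train = round(train_fraction * n)`` with symmetric half-up rounding;
    the permutation is drawn from ``numpy.random.default_rng(seed)`` so the
    same seed always yields the same membership.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = ds.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty partition for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return SplitPair(
        train=ds.take_rows(np.sort(perm[:n_train])),
        test=ds.take_rows(np.sort(perm[n_train:])),
        seed=seed,
    )


def _apply_keep(pair: SplitPair, keep: np.ndarray, context: str) -> SplitPair:
    if not keep.any():
        raise ValueError(
            f"{context} removed every column; relax the threshold or check the data"
        )
    return replace(
        pair,
        train=pair.train.take_columns(np.flatnonzero(keep)),
        test=pair.test.take_columns(np.flatnonzero(keep)),
    )


def filter_low_variation(pair: SplitPair, threshold: float = 0.8) -> SplitPair:
    """Drop columns whose modal value dominates the training partition.

    A column is removed from both partitions when the relative frequency of
    its most common training value is >= ``threshold`` (exact value
    equality, no binning).  Idempotent.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    Xtr = pair.train.X
    n = Xtr.shape[0]
    keep = np.empty(Xtr.shape[1], dtype=bool)
    for j in range(Xtr.shape[1]):
        _, counts = np.unique(Xtr[:, j], return_counts=True)
        keep[j] = counts.max() / n < threshold
    return _apply_keep(pair, keep, "low-variation filter")


def dedup_perfect_correlation(pair: SplitPair, tol: float = 1e-12) -> SplitPair:
    """Drop the later column of every perfectly correlated train-column pair.

    Columns are scanned left to right; column ``j`` is removed when some
    surviving earlier column has ``|Pearson r| >= 1 - tol`` with it on the
    training partition.  Survivors are therefore always first occurrences,
    which makes the operation deterministic and idempotent.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    Xtr = pair.train.X
    p = Xtr.shape[1]
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(Xtr, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    keep = np.ones(p, dtype=bool)
    for j in range(1, p):
        earlier = np.flatnonzero(keep[:j])
        if earlier.size and (corr[earlier, j] >= 1.0 - tol).any():
            keep[j] = False
    return _apply_keep(pair, keep, "perfect-correlation dedup")


def spike_random_variables(pair: SplitPair, seed: int = 0) -> SplitPair:
    """Append one uniform(0,1) probe column per original descriptor.

    Probe values are drawn independently for the train and test partitions
    from a single seeded generator, flagged ``origin="random_probe"`` and
    named with the reserved ``RANDPROBE_`` prefix.  The call doubles the
    column count.
    """
    if (pair.train.origin == ORIGIN_PROBE).any():
        raise ValueError("dataset already contains random_probe columns")
    if any(n.startswith(PROBE_PREFIX) for n in pair.train.names):
        raise ValueError(
            f"column names colliding with reserved prefix {PROBE_PREFIX!r}"
        )
    k = pair.train.n_vars
    rng = np.random.default_rng(seed)
    probes_tr = rng.uniform(size=(pair.train.n_samples, k))
    probes_te = rng.uniform(size=(pair.test.n_samples, k))
    names = pair.train.names + [f"{PROBE_PREFIX}{i + 1}" for i in range(k)]
    origin = np.concatenate(
        [pair.train.origin, np.full(k, ORIGIN_PROBE, dtype=object)]
    )

    def extend(ds: Dataset, probes: np.ndarray) -> Dataset:
        return Dataset(
            X=np.hstack([ds.X, probes]), y=ds.y, names=names, origin=origin
        )

    return replace(
        pair, train=extend(pair.train, probes_tr), test=extend(pair.test, probes_te)
    )


def autoscale(pair: SplitPair) -> SplitPair:
    """Center and scale X and y by training-set mean and standard deviation.

    The identical transform (train statistics) is applied to the test
    partition, so test columns generally do not have mean zero.  The train
    response statistics are stored on the returned pair so predictions can
    be mapped back to original units via :meth:`SplitPair.inverse_y`.
    """
    mu = pair.train.X.mean(axis=0)
    sd = pair.train.X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [pair.train.names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero train standard deviation in columns {bad}")
    y_mu = float(pair.train.y.mean())
    y_sd = float(pair.train.y.std(ddof=1))
    if y_sd == 0:
        raise ValueError("constant training response; cannot autoscale y")

    def scale(ds: Dataset) -> Dataset:
        return replace(ds, X=(ds.X - mu) / sd, y=(ds.y - y_mu) / y_sd)

    return replace(
        pair,
        train=scale(pair.train),
        test=scale(pair.test),
        y_center=y_mu,
        y_scale=y_sd,
    )


def preprocess(
    ds: Dataset,
    *,
    train_fraction: float = 0.7,
    same_value_threshold: float = 0.8,
    dedup_tol: float = 1e-12,
    spike: bool = True,
    do_autoscale: bool = True,
    seed: int = 0,
) -> SplitPair:
    """Full pipeline: split -> same-value filter -> dedup -> spike -> autoscale."""
    pair = split_train_test(ds, train_fraction, seed)
    pair = filter_low_variation(pair, same_value_threshold)
    pair = dedup_perfect_correlation(pair, dedup_tol)
    if spike:
        pair = spike_random_variables(pair, seed)
    if do_autoscale:
        pair = autoscale(pair)
    return pair
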