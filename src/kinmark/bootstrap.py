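"""Percentile bootstrap intervals for the pair-count estimators.

The resampling unit is the individual: a resample draws ``n`` rows with
replacement from the subsample table. Each juvenile row carries its pair
status from the original subsample (father sampled / mother sampled), so a
resample's ``m_FC`` is the number of juvenile copies whose father was in the
original subsample; this keeps ``m <= n_J`` within every resample and keeps
the bootstrap distribution centred on the point estimate. (Recounting pairs
by joint presence within the resample instead is badly off-centre: only
~63% of distinct individuals enter a with-replacement resample, deflating
``m / n_J`` by that factor and inflating every resampled estimate by ~1.6x.)
Resamples in which a pair count falls to zero are degenerate: they are
dropped, counted, and reported; quantiles are taken over the valid resamples
only.

One master seed expands deterministically into per-resample streams (via
``numpy.random.SeedSequence.spawn``), so increasing ``n_boot`` extends the
resample sequence without reshuffling earlier resamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateBootstrapError
from .estimators import PairCounts, PointEstimates, _point_tuple, estimate_total
from .simulate import Individual, SeedLike, count_pairs

__all__ = ["BootstrapResult", "resample_subsample", "bootstrap_estimate"]

_ESTIMATOR_NAMES = ("N_hat_M", "N_hat_F", "N_hat_A", "J_hat", "N_hat")


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimates with percentile-bootstrap interval bounds.

    ``lower``/``upper`` hold the empirical alpha/2 and 1 - alpha/2 quantiles
    of each estimator over the valid resamples. Percentile intervals need not
    bracket the point estimate in pathological resamples; only
    ``lower <= upper`` is guaranteed.
    """

    point: PointEstimates
    lower: PointEstimates
    upper: PointEstimates
    n_boot: int
    n_valid: int
    n_degenerate: int
    alpha: float


def resample_subsample(
    subsample: Sequence[Individual], seed: SeedLike = None
) -> list[Individual]:
    """One bootstrap resample: ``n`` draws with replacement from the subsample."""
    if len(subsample) == 0:
        raise ValueError("cannot resample an empty subsample")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.integers(0, len(subsample), size=len(subsample))
    return [subsample[i] for i in idx]


def _subsample_arrays(subsample: Sequence[Individual]):
    """Precompute per-row attributes of a subsample for fast recounting."""
    n = len(subsample)
    ids = {ind.id for ind in subsample}
    is_m = np.zeros(n, dtype=bool)
    is_f = np.zeros(n, dtype=bool)
    is_juv = np.zeros(n, dtype=bool)
    father_pair = np.zeros(n, dtype=bool)
    mother_pair = np.zeros(n, dtype=bool)
    for i, ind in enumerate(subsample):
        if ind.is_juvenile:
            is_juv[i] = True
            father_pair[i] = ind.father_id in ids
            mother_pair[i] = ind.mother_id in ids
        elif ind.sex == "male":
            is_m[i] = True
        else:
            is_f[i] = True
    return is_m, is_f, is_juv, father_pair, mother_pair


def _recount(idx: np.ndarray, arrays) -> tuple[int, int, int, int, int]:
    """Pair counts within one resample given by row-index array ``idx``."""
    is_m, is_f, is_juv, father_pair, mother_pair = arrays
    n_m = int(is_m[idx].sum())
    n_f = int(is_f[idx].sum())
    n_j = int(is_juv[idx].sum())
    m_fc = int(father_pair[idx].sum())
    m_mc = int(mother_pair[idx].sum())
    return n_m, n_f, n_j, m_fc, m_mc


def bootstrap_estimate(
    subsample: Sequence[Individual],
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: SeedLike = None,
    min_valid_fraction: float = 0.5,
) -> BootstrapResult:
    """Point estimates plus percentile bootstrap intervals for all estimators.

    Parameters
    ----------
    subsample
        Individuals of the original subsample; must yield pair counts with
        ``m_FC >= 1`` and ``m_MC >= 1`` (else the point estimate itself
        raises :class:`~kinmark.errors.ZeroPairsError`).
    n_boot
        Number of resamples (default 200).
    alpha
        Two-sided nominal error rate; bounds are the alpha/2 and 1 - alpha/2
        empirical quantiles (linear interpolation between order statistics).
    min_valid_fraction
        Raise :class:`~kinmark.errors.DegenerateBootstrapError` when fewer
        than this fraction of resamples yields a defined estimate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    counts: PairCounts = count_pairs(subsample)
    point = estimate_total(counts)  # raises if not estimable

    arrays = _subsample_arrays(subsample)
    n = len(subsample)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(n_boot)
    values = np.empty((n_boot, 5), dtype=float)
    n_valid = 0
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        n_m, n_f, n_j, m_fc, m_mc = _recount(idx, arrays)
        if m_fc == 0 or m_mc == 0 or n_m + n_f == 0:
            continue
        values[n_valid] = _point_tuple(n_m, n_f, n_j, m_fc, m_mc)
        n_valid += 1
    n_degenerate = n_boot - n_valid
    if n_valid < min_valid_fraction * n_boot or n_valid == 0:
        raise DegenerateBootstrapError(
            f"only {n_valid}/{n_boot} resamples were estimable "
            f"(minimum fraction {min_valid_fraction}); subsample too sparse for intervals"
        )
    valid = values[:n_valid]
    lo = np.quantile(valid, alpha / 2.0, axis=0)
    hi = np.quantile(valid, 1.0 - alpha / 2.0, axis=0)
    return BootstrapResult(
        point=point,
        lower=PointEstimates(*lo),
        upper=PointEstimates(*hi),
        n_boot=n_boot,
        n_valid=n_valid,
        n_degenerate=n_degenerate,
        alpha=alpha,
    )
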