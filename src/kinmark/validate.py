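"""Monte Carlo validation experiments: relative bias, coverage, hunting bias.

The headline statistic is the relative bias N_hat / N (1 = unbiased),
summarized as its mean over estimable replicates. Replicates in which a pair
count is zero are not errors: they are recorded with ``estimable = False``
and excluded from bias and coverage summaries, making the conditioning on
estimability explicit and measurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_estimate
from .errors import DegenerateBootstrapError, InsufficientReplicatesError, ZeroPairsError
from .estimators import PairCounts, estimate_total
from .simulate import (
    Population,
    SeedLike,
    SimulationConfig,
    count_pairs,
    draw_subsample,
    generate_population,
)

__all__ = [
    "ReplicateRecord",
    "CoverageResult",
    "replicate_estimates",
    "sweep_subsample_size",
    "coverage_experiment",
    "nonrandom_bias_experiment",
    "pairs_vs_bias_summary",
    "mean_relative_bias",
    "records_to_frame",
]


@dataclass(frozen=True)
class ReplicateRecord:
    """One Monte Carlo replicate: inputs, estimate, interval, coverage flag."""

    n: int
    counts: PairCounts
    estimable: bool
    N_hat: Optional[float]
    rel_bias: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    covered: Optional[bool]
    total_pairs: int
    nonrandom_bias: float


@dataclass(frozen=True)
class CoverageResult:
    """Empirical coverage of the nominal bootstrap interval for N."""

    coverage: float
    n_reps: int
    n_estimable: int
    n_non_estimable: int
    n_degenerate_interval: int

    @property
    def n_with_interval(self) -> int:
        return self.n_estimable - self.n_degenerate_interval


def _one_replicate(
    pop: Population,
    n: int,
    seed: np.random.SeedSequence,
    nonrandom_bias: float,
    bias_mode: str,
    with_ci: bool,
    n_boot: int,
    alpha: float,
) -> ReplicateRecord:
    sub_seed, boot_seed = seed.spawn(2)
    subsample = draw_subsample(
        pop, n, nonrandom_bias=nonrandom_bias, seed=np.random.default_rng(sub_seed),
        bias_mode=bias_mode,  # type: ignore[arg-type]
    )
    counts = count_pairs(subsample)
    base = dict(
        n=n,
        counts=counts,
        total_pairs=counts.total_pairs,
        nonrandom_bias=nonrandom_bias,
        ci_lower=None,
        ci_upper=None,
        covered=None,
    )
    try:
        point = estimate_total(counts)
    except ZeroPairsError:
        return ReplicateRecord(estimable=False, N_hat=None, rel_bias=None, **base)
    base.update(estimable=True, N_hat=point.N_hat, rel_bias=point.N_hat / pop.N)
    if with_ci:
        try:
            boot = bootstrap_estimate(subsample, n_boot=n_boot, alpha=alpha, seed=boot_seed)
        except DegenerateBootstrapError:
            pass
        else:
            base.update(
                ci_lower=boot.lower.N_hat,
                ci_upper=boot.upper.N_hat,
                covered=bool(boot.lower.N_hat <= pop.N <= boot.upper.N_hat),
            )
    return ReplicateRecord(**base)


def replicate_estimates(
    pop: Population,
    n: int,
    n_reps: int,
    seed: SeedLike = None,
    nonrandom_bias: float = 0.0,
    bias_mode: str = "independent",
    with_ci: bool = False,
    n_boot: int = 200,
    alpha: float = 0.05,
) -> list[ReplicateRecord]:
    """Repeatedly subsample one fixed population and estimate N.

    The workhorse behind the bias experiments: one record per replicate, each
    an independent subsample of size ``n`` from ``pop``.
    """
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        _one_replicate(pop, n, child, nonrandom_bias, bias_mode, with_ci, n_boot, alpha)
        for child in master.spawn(n_reps)
    ]


def sweep_subsample_size(
    pop: Population,
    n_grid: Sequence[int],
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: SeedLike = None,
    nonrandom_bias: float = 0.0,
) -> list[ReplicateRecord]:
    """One subsample, estimate and interval per grid point (the scatter of the
    bias-versus-n/N validation), on a single fixed population."""
    if max(n_grid) > pop.N:
        raise ValueError("n_grid exceeds the population size")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        _one_replicate(pop, int(n), child, nonrandom_bias, "independent", True, n_boot, alpha)
        for n, child in zip(n_grid, master.spawn(len(n_grid)))
    ]


def coverage_experiment(
    config: SimulationConfig,
    n_reps: int,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: SeedLike = None,
) -> CoverageResult:
    """Empirical coverage of the nominal (1 - alpha) interval for N.

    Each replicate draws a fresh population from ``config``, subsamples it
    with ``config.n`` and the configured bias scheme, and checks whether the
    bootstrap interval contains the true N of that replicate's population.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(seed, np.random.SeedSequence):
        master = seed
    else:
        master = np.random.SeedSequence(config.seed if seed is None else seed)
    n_est = n_non = n_degen = n_cov = 0
    for child in master.spawn(n_reps):
        pop_seed, rep_seed = child.spawn(2)
        pop = generate_population(config, seed=np.random.default_rng(pop_seed))
        rec = _one_replicate(
            pop, config.n, rep_seed, config.nonrandom_bias, config.bias_mode,
            True, n_boot, alpha,
        )
        if not rec.estimable:
            n_non += 1
        elif rec.covered is None:
            n_est += 1
            n_degen += 1
        else:
            n_est += 1
            n_cov += int(rec.covered)
    n_with_interval = n_est - n_degen
    if n_with_interval == 0:
        raise InsufficientReplicatesError(
            f"none of {n_reps} replicates produced an interval "
            f"({n_non} non-estimable, {n_degen} with degenerate bootstrap)"
        )
    return CoverageResult(
        coverage=n_cov / n_with_interval,
        n_reps=n_reps,
        n_estimable=n_est,
        n_non_estimable=n_non,
        n_degenerate_interval=n_degen,
    )


def nonrandom_bias_experiment(
    pop: Population,
    n: int,
    bias_grid: Sequence[float],
    n_reps: int,
    seed: SeedLike = None,
    bias_mode: str = "independent",
) -> tuple[list[ReplicateRecord], pd.DataFrame]:
    """Mean relative bias across a grid of "shot together" probabilities.

    Returns all replicate records plus a per-grid-point summary frame with
    columns ``nonrandom_bias``, ``mean_rel_bias``, ``n_estimable``,
    ``n_reps``.
    """
    if n > pop.N:
        raise ValueError("subsample size exceeds the population")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    records: list[ReplicateRecord] = []
    rows = []
    for b, child in zip(bias_grid, master.spawn(len(bias_grid))):
        recs = replicate_estimates(
            pop, n, n_reps, seed=child, nonrandom_bias=float(b), bias_mode=bias_mode
        )
        records.extend(recs)
        biases = [r.rel_bias for r in recs if r.estimable]
        rows.append(
            {
                "nonrandom_bias": float(b),
                "mean_rel_bias": float(np.mean(biases)) if biases else np.nan,
                "n_estimable": len(biases),
                "n_reps": n_reps,
            }
        )
    return records, pd.DataFrame(rows)


def mean_relative_bias(records: Sequence[ReplicateRecord]) -> float:
    """Mean N_hat / N over estimable records."""
    biases = [r.rel_bias for r in records if r.estimable]
    if not biases:
        raise InsufficientReplicatesError("no estimable records to summarize")
    return float(np.mean(biases))


def records_to_frame(records: Sequence[ReplicateRecord]) -> pd.DataFrame:
    """Tidy per-replicate frame (one row per record, pair counts unpacked)."""
    return pd.DataFrame(
        {
            "n": r.n,
            "n_M": r.counts.n_M,
            "n_F": r.counts.n_F,
            "n_J": r.counts.n_J,
            "m_FC": r.counts.m_FC,
            "m_MC": r.counts.m_MC,
            "total_pairs": r.total_pairs,
            "estimable": r.estimable,
            "N_hat": r.N_hat,
            "rel_bias": r.rel_bias,
            "ci_lower": r.ci_lower,
            "ci_upper": r.ci_upper,
            "covered": r.covered,
            "nonrandom_bias": r.nonrandom_bias,
        }
        for r in records
    )


def pairs_vs_bias_summary(
    records: Sequence[ReplicateRecord], bins: Optional[Sequence[float]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative bias as a function of the total number of pairs per sample.

    Returns the per-record table (estimable records only; the number excluded
    is in the binned frame's attrs) and binned means of the relative bias.
    """
    if len(records) == 0:
        raise ValueError("no records")
    estimable = [r for r in records if r.estimable]
    table = pd.DataFrame(
        {"total_pairs": r.total_pairs, "rel_bias": r.rel_bias} for r in estimable
    )
    if bins is None:
        bins = [0, 5, 10, 20, 50, 100, np.inf]
    if table.empty:
        binned = pd.DataFrame(columns=["pairs_bin", "mean_rel_bias", "n_records"])
    else:
        grouped = table.groupby(
            pd.cut(table["total_pairs"], bins=list(bins)), observed=True
        )["rel_bias"]
        binned = grouped.agg(["mean", "size"]).reset_index()
        binned.columns = ["pairs_bin", "mean_rel_bias", "n_records"]
    binned.attrs["n_excluded_non_estimable"] = len(records) - len(estimable)
    return table, binned
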