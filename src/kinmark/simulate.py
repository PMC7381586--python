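"""Virtual closed populations and subsampling schemes for estimator validation.

The generative model is a single-generation pedigree: ``N_M`` adult males and
``N_F`` adult females are founders; each mother's offspring count is drawn
from a Poisson distribution with mean ``offspring_rate`` (the rate written
lambda elsewhere in this package's docs), and each offspring's father is
assigned uniformly at random among the adult males, independently. Offspring
sex is assigned uniformly at random; it is carried in the data model but the
estimators classify juveniles as a single class.

Two subsampling schemes are provided: uniform sampling without replacement
(random harvest), and a "shot together" scheme in which each time a juvenile
enters the sample its parents join with a configurable probability, modelling
family groups harvested together.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InvalidPedigreeError
from .estimators import PairCounts

__all__ = [
    "Individual",
    "Population",
    "SimulationConfig",
    "generate_population",
    "draw_subsample",
    "count_pairs",
    "read_individuals_csv",
    "write_individuals_csv",
]

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]

ADULT = "adult"
JUVENILE = "juvenile"
MALE = "male"
FEMALE = "female"


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Individual:
    """One animal: the pedigree atom.

    Adults are founders and carry no parent identifiers; every juvenile's
    ``mother_id`` and ``father_id`` refer to adults of the appropriate sex.
    """

    id: str
    age_class: str  # "adult" | "juvenile"
    sex: str  # "male" | "female"
    mother_id: Optional[str] = None
    father_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_class not in (ADULT, JUVENILE):
            raise ValueError(f"unknown age_class {self.age_class!r}")
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def is_juvenile(self) -> bool:
        return self.age_class == JUVENILE


@dataclass
class Population:
    """A closed population with a resolved one-generation pedigree."""

    individuals: tuple[Individual, ...]
    N_M: int = field(init=False)
    N_F: int = field(init=False)
    N_J: int = field(init=False)

    def __post_init__(self) -> None:
        self.individuals = tuple(self.individuals)
        index: dict[str, int] = {}
        for pos, ind in enumerate(self.individuals):
            if ind.id in index:
                raise InvalidPedigreeError(f"duplicate individual id {ind.id!r}")
            index[ind.id] = pos
        self._index = index
        n_m = n_f = n_j = 0
        for ind in self.individuals:
            if ind.is_juvenile:
                n_j += 1
                for pid, sex, label in (
                    (ind.mother_id, FEMALE, "mother"),
                    (ind.father_id, MALE, "father"),
                ):
                    if pid is None:
                        raise InvalidPedigreeError(f"juvenile {ind.id} lacks a {label}_id")
                    parent = self.individuals[index[pid]] if pid in index else None
                    if parent is None or parent.age_class != ADULT or parent.sex != sex:
                        raise InvalidPedigreeError(
                            f"{label}_id {pid!r} of juvenile {ind.id} does not resolve "
                            f"to an adult {sex}"
                        )
            else:
                if ind.mother_id is not None or ind.father_id is not None:
                    raise InvalidPedigreeError(
                        f"adult {ind.id} carries parent identifiers (adults are founders)"
                    )
                if ind.sex == MALE:
                    n_m += 1
                else:
                    n_f += 1
        self.N_M, self.N_F, self.N_J = n_m, n_f, n_j

    @property
    def N(self) -> int:
        return self.N_M + self.N_F + self.N_J

    @property
    def N_A(self) -> int:
        return self.N_M + self.N_F

    def position_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    def census(self) -> list[Individual]:
        """The whole population as a subsample (pair counts equal N_J on both sides)."""
        return list(self.individuals)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a virtual population plus a sampling scenario.

    Parameters
    ----------
    N_M, N_F
        Founder adult males and females.
    offspring_rate
        Poisson mean number of offspring per mother (lambda).
    N_J
        If None (free mode) the juvenile total is whatever the Poisson draws
        sum to. If an integer (fixed mode), whole offspring-count vectors are
        redrawn until the total matches, conditioning the Poisson draws on
        their sum.
    n
        Subsample size.
    nonrandom_bias
        Probability that a sampled juvenile drags each parent into the sample
        ("shot together"); 0 is random harvest.
    bias_mode
        "independent": mother and father each join with probability
        ``nonrandom_bias`` independently. "single": with probability
        ``nonrandom_bias`` one parent, chosen uniformly, joins.
    seed
        Master seed for all randomness of the scenario.
    """

    N_M: int = 100
    N_F: int = 100
    offspring_rate: float = 2.0
    N_J: Optional[int] = 200
    n: int = 50
    nonrandom_bias: float = 0.0
    bias_mode: Literal["independent", "single"] = "independent"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N_M < 1 or self.N_F < 1:
            raise ValueError("need at least one adult of each sex")
        if self.offspring_rate < 0:
            raise ValueError("offspring_rate must be >= 0")
        if not 0.0 <= self.nonrandom_bias <= 1.0:
            raise ValueError("nonrandom_bias must lie in [0, 1]")
        if self.bias_mode not in ("independent", "single"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")


def _offspring_counts(
    rng: np.random.Generator, n_mothers: int, rate: float, fixed_total: Optional[int]
) -> np.ndarray:
    if fixed_total is None:
        return rng.poisson(rate, size=n_mothers)
    if fixed_total > 0 and rate == 0:
        raise ValueError("cannot fix a positive juvenile total with offspring_rate = 0")
    if fixed_total == 0 and rate == 0:
        return np.zeros(n_mothers, dtype=np.int64)
    # Rejection: redraw whole vectors until the Poisson total hits the target,
    # i.e. condition the offspring-number vector on its sum.
    for _ in range(1_000_000):
        counts = rng.poisson(rate, size=n_mothers)
        if counts.sum() == fixed_total:
            return counts
    raise RuntimeError("offspring-count rejection sampling did not converge")


def generate_population(config: SimulationConfig, seed: SeedLike = None) -> Population:
    """Draw one virtual population from the generative model in ``config``.

    ``seed`` overrides ``config.seed`` when given (useful for replicated
    experiments driven by one master stream).
    """
    rng = as_rng(config.seed if seed is None else seed)
    males = [Individual(id=f"M{i + 1}", age_class=ADULT, sex=MALE) for i in range(config.N_M)]
    females = [Individual(id=f"F{i + 1}", age_class=ADULT, sex=FEMALE) for i in range(config.N_F)]
    counts = _offspring_counts(rng, config.N_F, config.offspring_rate, config.N_J)
    n_j = int(counts.sum())
    mother_ids = np.repeat([f.id for f in females], counts)
    father_idx = rng.integers(0, config.N_M, size=n_j)
    sexes = rng.random(n_j) < 0.5
    juveniles = [
        Individual(
            id=f"J{k + 1}",
            age_class=JUVENILE,
            sex=MALE if sexes[k] else FEMALE,
            mother_id=str(mother_ids[k]),
            father_id=males[father_idx[k]].id,
        )
        for k in range(n_j)
    ]
    return Population(individuals=tuple(males + females + juveniles))


def draw_subsample(
    pop: Population,
    n: int,
    nonrandom_bias: float = 0.0,
    seed: SeedLike = None,
    bias_mode: Literal["independent", "single"] = "independent",
) -> list[Individual]:
    """Draw a subsample of exactly ``n`` distinct individuals.

    With ``nonrandom_bias = 0`` this is a uniform sample without replacement.
    With bias ``b > 0``, individuals are visited in uniform random order; each
    time a juvenile enters the sample its parents join according to
    ``bias_mode`` (each with probability ``b`` independently, or one uniformly
    chosen parent with probability ``b``). The sample is truncated exactly at
    size ``n``, discarding pending parent additions.
    """
    if not 1 <= n <= pop.N:
        raise ValueError(f"subsample size {n} outside [1, {pop.N}]")
    rng = as_rng(seed)
    inds = pop.individuals
    if nonrandom_bias == 0.0:
        idx = rng.choice(pop.N, size=n, replace=False)
        return [inds[i] for i in idx]

    b = nonrandom_bias
    order = rng.permutation(pop.N)
    chosen: list[int] = []
    in_sample: set[int] = set()

    def add(pos: int) -> None:
        chosen.append(pos)
        in_sample.add(pos)

    for pos in order:
        if len(chosen) >= n:
            break
        if pos in in_sample:
            continue
        add(pos)
        ind = inds[pos]
        if not ind.is_juvenile:
            continue
        if bias_mode == "independent":
            for pid in (ind.mother_id, ind.father_id):
                if len(chosen) >= n:
                    break
                if rng.random() < b:
                    ppos = pop.position_of(pid)  # type: ignore[arg-type]
                    if ppos not in in_sample:
                        add(ppos)
        else:  # single
            if len(chosen) < n and rng.random() < b:
                pid = ind.mother_id if rng.random() < 0.5 else ind.father_id
                ppos = pop.position_of(pid)  # type: ignore[arg-type]
                if ppos not in in_sample:
                    add(ppos)
    return [inds[i] for i in chosen]


def count_pairs(subsample: Sequence[Individual]) -> PairCounts:
    """Tally the pair-count summary of a subsample.

    ``m_FC`` is the number of sampled juveniles whose father is also in the
    subsample; ``m_MC`` analogously for mothers, so each juvenile contributes
    at most one pair of each kind.
    """
    ids = {ind.id for ind in subsample}
    n_m = n_f = n_j = m_fc = m_mc = 0
    for ind in subsample:
        if ind.is_juvenile:
            n_j += 1
            if ind.father_id is None or ind.mother_id is None:
                raise InvalidPedigreeError(f"juvenile {ind.id} lacks parent identifiers")
            if ind.father_id in ids:
                m_fc += 1
            if ind.mother_id in ids:
                m_mc += 1
        elif ind.sex == MALE:
            n_m += 1
        else:
            n_f += 1
    return PairCounts(n_M=n_m, n_F=n_f, n_J=n_j, m_FC=m_fc, m_MC=m_mc)


_CSV_COLUMNS = ["id", "age_class", "sex", "mother_id", "father_id"]


def write_individuals_csv(individuals: Iterable[Individual], path) -> None:
    """Write an individual table; adults have empty parent fields."""
    rows = [
        {
            "id": ind.id,
            "age_class": ind.age_class,
            "sex": ind.sex,
            "mother_id": ind.mother_id or "",
            "father_id": ind.father_id or "",
        }
        for ind in individuals
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_individuals_csv(path) -> list[Individual]:
    """Read an individual table written by :func:`write_individuals_csv`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"individual table lacks columns: {sorted(missing)}")
    return [
        Individual(
            id=row.id,
            age_class=row.age_class,
            sex=row.sex,
            mother_id=row.mother_id or None,
            father_id=row.father_id or None,
        )
        for row in df.itertuples(index=False)
    ]


def all_subsamples(pop: Population, size: int) -> Iterable[list[Individual]]:
    """Enumerate every subsample of the given size (for exhaustive checks on tiny populations)."""
    for combo in itertools.combinations(pop.individuals, size):
        yield list(combo)
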