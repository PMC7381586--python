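"""Microsatellite genotype simulation and exclusion-based parentage assignment.

This layer closes the loop from genotypes to pair counts: multilocus
genotypes are simulated down the pedigree under Mendelian inheritance, and
parent-offspring pairs are then recovered by Mendelian exclusion — a sampled
adult is a candidate parent of a sampled juvenile only if the two share at
least one allele at (all but at most ``max_mismatch_loci`` of) the compared
loci. Exclusion is deliberately simple plumbing: no likelihood-based
assignment, no sibship reconstruction.

Assignment is conservative where it is ambiguous: at most one pair per
juvenile per parental sex is counted; among non-excluded candidates the one
with the fewest mismatching loci wins, and ties are resolved by assigning
none (and emitting :class:`~kinmark.errors.AmbiguityWarning`). False pairs
bias the abundance estimator downward, so conservatism preserves its stated
small-sample behaviour.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguityWarning, InsufficientLociError
from .estimators import PairCounts
from .simulate import Individual, Population, SeedLike, as_rng

__all__ = [
    "LocusModel",
    "GenotypeTable",
    "Assignment",
    "equifrequent_loci",
    "simulate_genotypes",
    "assign_parent_offspring",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "read_locus_models_json",
    "write_locus_models_json",
]


@dataclass(frozen=True)
class LocusModel:
    """One microsatellite locus: named alleles with population frequencies."""

    locus_id: str
    allele_frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.allele_frequencies) < 2:
            raise ValueError(f"locus {self.locus_id}: need at least 2 alleles")
        freqs = np.array(list(self.allele_frequencies.values()), dtype=float)
        if (freqs <= 0).any():
            raise ValueError(f"locus {self.locus_id}: frequencies must be positive")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError(f"locus {self.locus_id}: frequencies sum to {freqs.sum()}, not 1")

    @property
    def alleles(self) -> list[str]:
        return list(self.allele_frequencies)


def equifrequent_loci(n_loci: int, n_alleles: int) -> list[LocusModel]:
    """Convenience panel: ``n_loci`` loci with ``n_alleles`` equally frequent alleles."""
    return [
        LocusModel(
            locus_id=f"L{i + 1}",
            allele_frequencies={f"a{j + 1}": 1.0 / n_alleles for j in range(n_alleles)},
        )
        for i in range(n_loci)
    ]


@dataclass
class GenotypeTable:
    """Per-individual, per-locus unordered allele pairs; ``None`` marks a missing call."""

    loci: list[LocusModel]
    genotypes: dict[str, list[Optional[tuple[str, str]]]]
    missing_rate: float = 0.0

    def called_loci(self, individual_id: str) -> int:
        return sum(g is not None for g in self.genotypes[individual_id])


@dataclass(frozen=True)
class Assignment:
    """One assigned pair, for audit."""

    juvenile_id: str
    parent_id: str
    parent_sex: str
    mismatches: int
    compared_loci: int


def simulate_genotypes(
    pop: Population,
    loci: Sequence[LocusModel],
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: SeedLike = None,
) -> GenotypeTable:
    """Simulate multilocus genotypes down the pedigree.

    Founders draw two alleles independently from the locus frequencies
    (Hardy-Weinberg); each offspring receives one uniformly chosen allele
    from each parent's true genotype. Genotyping error replaces each recorded
    allele, independently with probability ``error_rate``, by a
    frequency-weighted draw; each locus call is then dropped with probability
    ``missing_rate``.
    """
    if not 0.0 <= missing_rate < 1.0 or not 0.0 <= error_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1)")
    rng = as_rng(seed)
    loci = list(loci)
    true: dict[str, list[tuple[str, str]]] = {}
    # Founders first (population lists adults before juveniles, but don't rely on it).
    adults = [ind for ind in pop.individuals if not ind.is_juvenile]
    juveniles = [ind for ind in pop.individuals if ind.is_juvenile]
    for locus_index, locus in enumerate(loci):
        alleles = np.array(locus.alleles)
        freqs = np.array(list(locus.allele_frequencies.values()))
        draws = rng.choice(len(alleles), size=(len(adults), 2), p=freqs)
        for i, ind in enumerate(adults):
            true.setdefault(ind.id, [None] * len(loci))  # type: ignore[arg-type]
            true[ind.id][locus_index] = (str(alleles[draws[i, 0]]), str(alleles[draws[i, 1]]))
    for ind in juveniles:
        true[ind.id] = [
            (
                true[ind.mother_id][k][rng.integers(0, 2)],
                true[ind.father_id][k][rng.integers(0, 2)],
            )
            for k in range(len(loci))
        ]
    observed: dict[str, list[Optional[tuple[str, str]]]] = {}
    for ind in pop.individuals:
        calls: list[Optional[tuple[str, str]]] = []
        for k, locus in enumerate(loci):
            if missing_rate > 0.0 and rng.random() < missing_rate:
                calls.append(None)
                continue
            a, b = true[ind.id][k]
            if error_rate > 0.0:
                alleles = locus.alleles
                freqs = list(locus.allele_frequencies.values())
                if rng.random() < error_rate:
                    a = str(alleles[rng.choice(len(alleles), p=freqs)])
                if rng.random() < error_rate:
                    b = str(alleles[rng.choice(len(alleles), p=freqs)])
            calls.append((a, b))
        observed[ind.id] = calls
    return GenotypeTable(loci=loci, genotypes=observed, missing_rate=missing_rate)


def _mismatches(
    juv: list[Optional[tuple[str, str]]], adult: list[Optional[tuple[str, str]]]
) -> tuple[int, int]:
    """(#loci sharing no allele, #loci compared) over loci called in both."""
    mism = compared = 0
    for gj, ga in zip(juv, adult):
        if gj is None or ga is None:
            continue
        compared += 1
        if gj[0] not in ga and gj[1] not in ga:
            mism += 1
    return mism, compared


def assign_parent_offspring(
    table: GenotypeTable,
    subsample: Sequence[Individual],
    max_mismatch_loci: int = 0,
    min_compared_loci: int = 5,
) -> tuple[PairCounts, list[Assignment]]:
    """Recover pair counts from genotypes alone by Mendelian exclusion.

    ``subsample`` supplies the age class and sex of each sampled individual
    (its parent identifiers are deliberately ignored): candidate fathers are
    the sampled adult males, candidate mothers the sampled adult females. The
    returned ``PairCounts`` reflects assigned, not pedigree-true, pairs; the
    assignment list is returned for audit.

    Raises
    ------
    InsufficientLociError
        When the table has no loci, or ``min_compared_loci`` < 1 (comparing
        zero loci would make every adult a candidate).
    """
    if len(table.loci) == 0 or min_compared_loci < 1:
        raise InsufficientLociError(
            "exclusion needs at least one compared locus per candidate pair"
        )
    missing = [ind.id for ind in subsample if ind.id not in table.genotypes]
    if missing:
        raise KeyError(f"subsample ids absent from genotype table: {missing[:5]}")

    juveniles = [ind for ind in subsample if ind.is_juvenile]
    males = [ind for ind in subsample if not ind.is_juvenile and ind.sex == "male"]
    females = [ind for ind in subsample if not ind.is_juvenile and ind.sex == "female"]

    assignments: list[Assignment] = []

    def best_candidate(juv: Individual, candidates: list[Individual], sex: str) -> None:
        gj = table.genotypes[juv.id]
        kept: list[tuple[int, int, str]] = []  # (mismatches, compared, id)
        for cand in candidates:
            mism, compared = _mismatches(gj, table.genotypes[cand.id])
            if compared < min_compared_loci:
                continue
            if mism <= max_mismatch_loci:
                kept.append((mism, compared, cand.id))
        if not kept:
            return
        kept.sort()
        if len(kept) > 1 and kept[0][0] == kept[1][0]:
            warnings.warn(
                f"juvenile {juv.id}: {len(kept)} non-excluded candidate {sex}s tie at "
                f"{kept[0][0]} mismatches; assigning none",
                AmbiguityWarning,
                stacklevel=3,
            )
            return
        if len(kept) > 1:
            warnings.warn(
                f"juvenile {juv.id}: multiple non-excluded candidate {sex}s; "
                "keeping the fewest-mismatch one",
                AmbiguityWarning,
                stacklevel=3,
            )
        mism, compared, cand_id = kept[0]
        assignments.append(
            Assignment(
                juvenile_id=juv.id,
                parent_id=cand_id,
                parent_sex=sex,
                mismatches=mism,
                compared_loci=compared,
            )
        )

    for juv in juveniles:
        best_candidate(juv, males, "male")
        best_candidate(juv, females, "female")

    m_fc = sum(a.parent_sex == "male" for a in assignments)
    m_mc = sum(a.parent_sex == "female" for a in assignments)
    counts = PairCounts(
        n_M=len(males), n_F=len(females), n_J=len(juveniles), m_FC=m_fc, m_MC=m_mc
    )
    return counts, assignments


def write_genotypes_csv(table: GenotypeTable, path) -> None:
    """Long-format genotype CSV: individual_id, locus_id, allele_1, allele_2."""
    rows = []
    for ind_id, calls in table.genotypes.items():
        for locus, call in zip(table.loci, calls):
            a1, a2 = call if call is not None else ("", "")
            rows.append(
                {"individual_id": ind_id, "locus_id": locus.locus_id, "allele_1": a1, "allele_2": a2}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotypes_csv(path, loci: Sequence[LocusModel]) -> GenotypeTable:
    """Read a long-format genotype CSV against a known locus panel."""
    loci = list(loci)
    order = {locus.locus_id: k for k, locus in enumerate(loci)}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    genotypes: dict[str, list[Optional[tuple[str, str]]]] = {}
    for row in df.itertuples(index=False):
        calls = genotypes.setdefault(row.individual_id, [None] * len(loci))
        if row.locus_id not in order:
            raise ValueError(f"unknown locus {row.locus_id!r}")
        if row.allele_1 and row.allele_2:
            calls[order[row.locus_id]] = (row.allele_1, row.allele_2)
    return GenotypeTable(loci=loci, genotypes=genotypes)


def write_locus_models_json(loci: Sequence[LocusModel], path) -> None:
    with open(path, "w") as fh:
        json.dump({locus.locus_id: locus.allele_frequencies for locus in loci}, fh, indent=2)


def read_locus_models_json(path) -> list[LocusModel]:
    with open(path) as fh:
        data = json.load(fh)
    return [LocusModel(locus_id=k, allele_frequencies=v) for k, v in data.items()]
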