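"""Tests for genotype simulation and exclusion-based parentage assignment."""

import warnings

import numpy as np
import pytest

from kinmark import (
    AmbiguityWarning,
    Individual,
    InsufficientLociError,
    SimulationConfig,
    count_pairs,
    draw_subsample,
    estimate_total,
    generate_population,
)
from kinmark.parentage import (
    GenotypeTable,
    LocusModel,
    assign_parent_offspring,
    equifrequent_loci,
    read_genotypes_csv,
    read_locus_models_json,
    simulate_genotypes,
    write_genotypes_csv,
    write_locus_models_json,
)


@pytest.fixture(scope="module")
def small_population():
    return generate_population(
        SimulationConfig(N_M=15, N_F=15, offspring_rate=2.0, N_J=30, seed=100)
    )


class TestLocusModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            LocusModel("L1", {"a": 1.0})
        with pytest.raises(ValueError):
            LocusModel("L1", {"a": 0.6, "b": 0.6})
        panel = equifrequent_loci(3, 4)
        assert len(panel) == 3 and len(panel[0].alleles) == 4


class TestSimulateGenotypes:
    def test_mendelian_sharing(self, small_population):
        """Error-free inheritance: every true parent-offspring duo shares at
        least one allele at every locus."""
        loci = equifrequent_loci(6, 6)
        table = simulate_genotypes(small_population, loci, seed=0)
        for ind in small_population.individuals:
            if not ind.is_juvenile:
                continue
            for parent_id in (ind.mother_id, ind.father_id):
                for gj, gp in zip(table.genotypes[ind.id], table.genotypes[parent_id]):
                    assert gj[0] in gp or gj[1] in gp

    def test_hardy_weinberg_founders(self):
        """One biallelic locus at frequencies (0.5, 0.5) over 10,000 founders:
        genotype frequencies match Hardy-Weinberg (0.25, 0.5, 0.25) within 3
        standard errors."""
        pop = generate_population(
            SimulationConfig(N_M=5000, N_F=5000, offspring_rate=0.0, N_J=None, seed=1)
        )
        locus = LocusModel("L1", {"A": 0.5, "B": 0.5})
        table = simulate_genotypes(pop, [locus], seed=2)
        tallies = {"AA": 0, "AB": 0, "BB": 0}
        for calls in table.genotypes.values():
            a, b = sorted(calls[0])
            tallies[a + b] += 1
        n = 10_000
        for genotype, p in (("AA", 0.25), ("AB", 0.5), ("BB", 0.25)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(tallies[genotype] / n - p) < 3 * se

    def test_seed_reproducibility(self, small_population):
        loci = equifrequent_loci(4, 4)
        t1 = simulate_genotypes(small_population, loci, missing_rate=0.1, error_rate=0.05, seed=3)
        t2 = simulate_genotypes(small_population, loci, missing_rate=0.1, error_rate=0.05, seed=3)
        assert t1.genotypes == t2.genotypes

    def test_missing_rate_applied(self, small_population):
        loci = equifrequent_loci(10, 4)
        table = simulate_genotypes(small_population, loci, missing_rate=0.3, seed=4)
        total = sum(len(calls) for calls in table.genotypes.values())
        missing = sum(c is None for calls in table.genotypes.values() for c in calls)
        assert 0.2 < missing / total < 0.4


class TestAssignment:
    def test_no_loci_refused(self, small_population):
        sub = list(small_population.individuals[:10])
        with pytest.raises(InsufficientLociError):
            assign_parent_offspring(GenotypeTable(loci=[], genotypes={}), sub)
        loci = equifrequent_loci(6, 6)
        table = simulate_genotypes(small_population, loci, seed=5)
        with pytest.raises(InsufficientLociError):
            assign_parent_offspring(table, sub, min_compared_loci=0)

    def test_roundtrip_with_high_power_panel(self, small_population):
        """With 16 loci x 10 alleles the false-candidate probability per
        comparison is ~4e-8, so assignment reproduces the pedigree-true
        counts and the downstream estimate exactly."""
        loci = equifrequent_loci(16, 10)
        table = simulate_genotypes(small_population, loci, seed=6)
        for trial_seed in range(5):
            sub = draw_subsample(small_population, 30, seed=trial_seed)
            assigned, assignments = assign_parent_offspring(table, sub)
            truth = count_pairs(sub)
            assert assigned == truth
            for a in assignments:
                juv = small_population.individuals[small_population.position_of(a.juvenile_id)]
                true_parent = juv.father_id if a.parent_sex == "male" else juv.mother_id
                assert a.parent_id == true_parent
                assert a.mismatches == 0
            if truth.estimable:
                assert estimate_total(assigned) == estimate_total(truth)

    def test_absent_parent_contributes_nothing(self):
        """A juvenile whose father is outside the subsample and who has no
        false candidate adds nothing to m_FC."""
        pop = generate_population(
            SimulationConfig(N_M=10, N_F=10, offspring_rate=2.0, N_J=20, seed=7)
        )
        loci = equifrequent_loci(16, 10)
        table = simulate_genotypes(pop, loci, seed=8)
        juv = next(ind for ind in pop.individuals if ind.is_juvenile)
        mother = pop.individuals[pop.position_of(juv.mother_id)]
        others = [
            ind for ind in pop.individuals
            if not ind.is_juvenile and ind.id not in (juv.mother_id, juv.father_id)
        ][:6]
        counts, _ = assign_parent_offspring(table, [juv, mother] + others)
        assert counts.m_FC == 0
        assert counts.m_MC == 1

    def test_false_positive_rate_decreases_with_loci(self, small_population):
        """Assignment errors (wrong parent, or a tie suppressing a present
        true parent) decrease monotonically as loci are added: 4, 8, 16 loci
        of 4 alleles each."""
        errors = []
        for n_loci in (4, 8, 16):
            loci = equifrequent_loci(n_loci, 4)
            wrong = 0
            for trial in range(10):
                table = simulate_genotypes(small_population, loci, seed=200 + trial)
                sub = draw_subsample(small_population, 30, seed=300 + trial)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", AmbiguityWarning)
                    assigned, _ = assign_parent_offspring(table, sub)
                truth = count_pairs(sub)
                wrong += abs(assigned.m_FC - truth.m_FC) + abs(assigned.m_MC - truth.m_MC)
            errors.append(wrong)
        assert errors[0] > errors[-1]
        assert errors == sorted(errors, reverse=True)

    def test_min_compared_loci_blocks_sparse_comparison(self):
        """A juvenile with fewer called loci than the comparison floor is
        never assigned, even against its true parent."""
        loci = equifrequent_loci(6, 4)
        genotypes = {
            "M1": [("a1", "a2")] * 6,
            "J1": [("a1", "a3")] * 3 + [None] * 3,
        }
        table = GenotypeTable(loci=loci, genotypes=genotypes)
        sub = [
            Individual("M1", "adult", "male"),
            Individual("J1", "juvenile", "male", mother_id="F9", father_id="M1"),
        ]
        counts, assignments = assign_parent_offspring(table, sub, min_compared_loci=5)
        assert counts.m_FC == 0 and not assignments

    def test_ambiguity_tie_assigns_none_with_warning(self):
        loci = equifrequent_loci(6, 4)
        genotypes = {
            "M1": [("a1", "a2")] * 6,
            "M2": [("a1", "a2")] * 6,
            "J1": [("a1", "a3")] * 6,
        }
        table = GenotypeTable(loci=loci, genotypes=genotypes)
        sub = [
            Individual("M1", "adult", "male"),
            Individual("M2", "adult", "male"),
            Individual("J1", "juvenile", "male", mother_id="F9", father_id="M1"),
        ]
        with pytest.warns(AmbiguityWarning):
            counts, assignments = assign_parent_offspring(table, sub)
        assert counts.m_FC == 0 and not assignments


class TestIo:
    def test_genotype_csv_round_trip(self, small_population, tmp_path):
        loci = equifrequent_loci(5, 4)
        table = simulate_genotypes(small_population, loci, missing_rate=0.2, seed=9)
        path = tmp_path / "genotypes.csv"
        write_genotypes_csv(table, path)
        back = read_genotypes_csv(path, loci)
        assert back.genotypes == table.genotypes

    def test_locus_json_round_trip(self, tmp_path):
        loci = equifrequent_loci(3, 5)
        path = tmp_path / "loci.json"
        write_locus_models_json(loci, path)
        back = read_locus_models_json(path)
        assert back == loci
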