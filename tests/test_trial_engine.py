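import numpy as np
import pytest

from allovax import (
    AntigenScorer,
    DriverSpec,
    ExpressionModel,
    GermlineVariant,
    SharingMode,
    TrialConfig,
    alloantigen_variants,
    allo_counts,
    count_neoantigens,
    expression_gate,
    generate_cohort,
    pool_vaccine,
    run_trials,
    shared_neoantigens,
    simulate_trial,
    taa_count,
)
from allovax.reporting import results_to_table
from allovax.synthetic_cohort import CohortSpec

from conftest import (
    HAPLO_1,
    HAPLO_2,
    PROTEIN_DB,
    ConstantPredictor,
    PeptideSetPredictor,
    make_missense,
    make_patient,
)


def _mutant_peptide(gene: str, position: int, alt_aa: str, start: int, k: int = 9) -> str:
    """Slice the expected 9-mer straight from the substituted sequence."""
    seq = PROTEIN_DB[gene]
    mut = seq[: position - 1] + alt_aa + seq[position:]
    return mut[start - 1 : start - 1 + k]


def _scorer(algorithms, **config_kw) -> AntigenScorer:
    return AntigenScorer(PROTEIN_DB, algorithms, TrialConfig(**config_kw))


class TestSimulateTrial:
    def test_cohort_of_exactly_33_partitions_fully(self, rng):
        cohort = [make_patient(f"P{i}") for i in range(33)]
        vaccine, patients = simulate_trial(cohort, TrialConfig(), rng)
        assert len(vaccine) == 3 and len(patients) == 30
        ids = {p.sample_id for p in vaccine} | {p.sample_id for p in patients}
        assert ids == {p.sample_id for p in cohort}

    def test_cohort_smaller_than_n_total_errors(self, rng):
        cohort = [make_patient(f"P{i}") for i in range(32)]
        with pytest.raises(ValueError):
            simulate_trial(cohort, TrialConfig(), rng)

    def test_vaccine_membership_uniform_over_cohort(self):
        """Any given sample lands in the vaccine with probability
        (33/100)*(3/33) = 3/100; check one designated sample over 10k trials."""
        cohort = [make_patient(f"P{i}") for i in range(100)]
        rng = np.random.default_rng(42)
        config = TrialConfig()
        n, hits = 10_000, 0
        for _ in range(n):
            vaccine, _ = simulate_trial(cohort, config, rng)
            hits += any(p.sample_id == "P0" for p in vaccine)
        expected = 3 / 100
        se = (expected * (1 - expected) / n) ** 0.5
        assert abs(hits / n - expected) < 3 * se


class TestPoolVaccine:
    def test_shared_variant_deduplicated_with_carriers(self):
        v = make_missense("GENEA", 10, "E")
        s1 = make_patient("V1", variants=[v])
        s2 = make_patient("V2", variants=[make_missense("GENEA", 10, "E")])
        s3 = make_patient("V3")
        pool = pool_vaccine([s1, s2, s3])
        assert len(pool.variant_identities) == 1
        assert pool.per_variant_carriers[v.identity] == ("V1", "V2")

    def test_variant_free_samples_give_empty_pool(self):
        pool = pool_vaccine([make_patient(f"V{i}") for i in range(3)])
        assert pool.variant_identities == frozenset()

    def test_identical_variant_in_all_three(self):
        samples = [
            make_patient(f"V{i}", variants=[make_missense("GENEA", 10, "E")])
            for i in range(3)
        ]
        pool = pool_vaccine(samples)
        assert len(pool.variant_identities) == 1
        (carriers,) = pool.per_variant_carriers.values()
        assert carriers == ("V0", "V1", "V2")

    def test_adding_a_sample_never_shrinks_the_pool(self):
        samples = [
            make_patient("V0", variants=[make_missense("GENEA", 10, "E")],
                         genotypes={("2", 5000, "A", "G"): "0/1"}),
            make_patient("V1"),
            make_patient("V2"),
            make_patient("V3", variants=[make_missense("GENEB", 5, "R")],
                         genotypes={("2", 6000, "A", "G"): "1/1"}),
        ]
        small = pool_vaccine(samples[:3])
        big = pool_vaccine(samples)
        assert small.variant_identities <= big.variant_identities
        assert set(small.germline_alt_presence) <= set(big.germline_alt_presence)


class TestCountNeoantigens:
    def test_multiple_strong_windows_count_once(self):
        v = make_missense("GENEA", 10, "E")
        strong = {
            (_mutant_peptide("GENEA", 10, "E", start), "HLA-A*01:01")
            for start in (2, 5, 10)
        }
        patient = make_patient("P1", variants=[v])
        assert count_neoantigens(patient, _scorer([PeptideSetPredictor(strong)])) == 1

    def test_variant_without_strong_window_not_counted(self):
        va = make_missense("GENEA", 10, "E")
        vb = make_missense("GENEB", 5, "R")
        strong = {(_mutant_peptide("GENEA", 10, "E", 2), "HLA-A*01:01")}
        patient = make_patient("P1", variants=[va, vb])
        assert count_neoantigens(patient, _scorer([PeptideSetPredictor(strong)])) == 1

    def test_no_variants_no_neoantigens(self):
        assert count_neoantigens(make_patient("P1"), _scorer([ConstantPredictor(100)])) == 0

    def test_raising_threshold_never_decreases_counts(self):
        patient = make_patient(
            "P1", variants=[make_missense("GENEA", 10, "E"), make_missense("GENEB", 5, "R")]
        )
        pred = PeptideSetPredictor(
            {(_mutant_peptide("GENEA", 10, "E", 2), "HLA-A*01:01")}
        )
        low = count_neoantigens(patient, _scorer([pred], ic50_threshold=50.0))
        mid = count_neoantigens(patient, _scorer([pred], ic50_threshold=500.0))
        high = count_neoantigens(patient, _scorer([pred], ic50_threshold=60000.0))
        assert low <= mid <= high
        assert (low, mid, high) == (0, 1, 2)


class TestSharedNeoantigens:
    def _fixture(self, strong_pairs, carrier_haplotype=HAPLO_2, **config_kw):
        identity_variant = make_missense("GENEA", 10, "E")
        vaccine = [
            make_patient("V1", haplotype=carrier_haplotype, variants=[identity_variant]),
            make_patient("V2", haplotype=HAPLO_2),
            make_patient("V3", haplotype=HAPLO_2),
        ]
        pool = pool_vaccine(vaccine)
        patient = make_patient("P1", haplotype=HAPLO_1,
                               variants=[make_missense("GENEA", 10, "E")])
        scorer = _scorer([PeptideSetPredictor(strong_pairs)], **config_kw)
        return pool, patient, scorer, identity_variant.identity

    def test_lysate_needs_patient_allele_only(self):
        pep = _mutant_peptide("GENEA", 10, "E", 2)
        pool, patient, scorer, identity = self._fixture({(pep, "HLA-A*01:01")})
        assert shared_neoantigens(pool, patient, SharingMode.LYSATE, scorer) == {identity}
        # no vaccine-context binding -> cell-based set is empty (strict subset)
        assert shared_neoantigens(pool, patient, SharingMode.CELL, scorer) == frozenset()

    def test_cell_requires_both_contexts_by_default(self):
        pep = _mutant_peptide("GENEA", 10, "E", 2)
        pool, patient, scorer, identity = self._fixture(
            {(pep, "HLA-A*01:01"), (pep, "HLA-A*03:01")}  # patient + carrier allele
        )
        assert shared_neoantigens(pool, patient, SharingMode.CELL, scorer) == {identity}

    def test_cell_shared_allele_rule(self):
        pep = _mutant_peptide("GENEA", 10, "E", 2)
        # carrier shares HAPLO_1 with the patient: the strong allele is common
        pool, patient, scorer, identity = self._fixture(
            {(pep, "HLA-A*01:01")},
            carrier_haplotype=HAPLO_1,
            cell_mode_neoantigen_rule="shared_allele",
        )
        assert shared_neoantigens(pool, patient, SharingMode.CELL, scorer) == {identity}
        # disjoint haplotypes: no shared allele, cell set empty
        pool2, patient2, scorer2, _ = self._fixture(
            {(pep, "HLA-A*01:01")},
            carrier_haplotype=HAPLO_2,
            cell_mode_neoantigen_rule="shared_allele",
        )
        assert shared_neoantigens(pool2, patient2, SharingMode.CELL, scorer2) == frozenset()

    def test_no_shared_variant_no_shared_neoantigen(self):
        pool = pool_vaccine([make_patient(f"V{i}", haplotype=HAPLO_2) for i in range(3)])
        patient = make_patient("P1", variants=[make_missense("GENEA", 10, "E")])
        scorer = _scorer([ConstantPredictor(100)])
        for mode in SharingMode:
            assert shared_neoantigens(pool, patient, mode, scorer) == frozenset()


class TestExpressionGate:
    TABLE = {"g1": 0.0, "g2": 1.0, "g3": 10.0, "g4": 100.0}

    def test_above_nonzero_median_passes(self):
        assert expression_gate(self.TABLE, "g4") is True

    def test_exactly_median_fails_strict_above(self):
        assert expression_gate(self.TABLE, "g3") is False  # nonzero median is 10

    def test_zero_expression_fails(self):
        assert expression_gate(self.TABLE, "g1") is False

    def test_absent_gene_fails(self):
        assert expression_gate(self.TABLE, "missing") is False

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            expression_gate({}, "g1")


class TestTAACount:
    def _pool(self, haplotype=HAPLO_2):
        return pool_vaccine([make_patient(f"V{i}", haplotype=haplotype) for i in range(3)])

    def test_unexpressed_gene_contributes_zero(self):
        strong = {(PROTEIN_DB["TAA1"][0:9], "HLA-A*01:01")}
        patient = make_patient("P1", expression={"GENEA": 10.0, "GENEB": 20.0, "TAA1": 1.0})
        scorer = _scorer([PeptideSetPredictor(strong)])
        assert taa_count(["TAA1"], patient, self._pool(), SharingMode.LYSATE, scorer) == 0

    def test_overlapping_strong_binders_collapse(self):
        taa = PROTEIN_DB["TAA1"]
        strong = {
            (taa[start - 1 : start + 8], "HLA-A*01:01") for start in (1, 5, 20)
        }
        patient = make_patient("P1", expression={"GENEA": 1.0, "GENEB": 2.0, "TAA1": 100.0})
        scorer = _scorer([PeptideSetPredictor(strong)])
        # starts 1 and 5 share 5 of 9 residues -> one kept; start 20 separate
        assert taa_count(["TAA1"], patient, self._pool(), SharingMode.LYSATE, scorer) == 2

    def test_cell_mode_with_disjoint_alleles_is_zero(self):
        patient = make_patient("P1", haplotype=HAPLO_1,
                               expression={"GENEA": 1.0, "GENEB": 2.0, "TAA1": 100.0})
        scorer = _scorer([ConstantPredictor(100)])
        assert taa_count(["TAA1"], patient, self._pool(HAPLO_2), SharingMode.CELL, scorer) == 0
        # lysate mode is unaffected by the vaccine's alleles
        assert taa_count(["TAA1"], patient, self._pool(HAPLO_2), SharingMode.LYSATE, scorer) > 0

    def test_cell_count_never_exceeds_lysate_count(self):
        patient = make_patient("P1", haplotype=HAPLO_1,
                               expression={"GENEA": 1.0, "GENEB": 2.0, "TAA1": 100.0})
        pool = self._pool(HAPLO_1)
        scorer = _scorer([ConstantPredictor(100)])
        cell = taa_count(["TAA1"], patient, pool, SharingMode.CELL, scorer)
        lysate = taa_count(["TAA1"], patient, pool, SharingMode.LYSATE, scorer)
        assert cell <= lysate

    def test_missing_taa_gene_errors_with_name(self):
        patient = make_patient("P1")
        scorer = _scorer([ConstantPredictor(100)])
        with pytest.raises(KeyError, match="NOSUCH"):
            taa_count(["NOSUCH"], patient, self._pool(), SharingMode.LYSATE, scorer)


def _germline_missense(locus_id=("2", 5000, "A", "G"), position=3, alt="E"):
    return GermlineVariant(
        locus_id=locus_id,
        qd=20.0, fs=5.0, mq=60.0, sor=1.0,
        gene="GENEB",
        consequence="missense",
        protein_position=str(position),
        amino_acids=f"{PROTEIN_DB['GENEB'][position - 1]}/{alt}",
    )


class TestAlloantigens:
    LOCUS = ("2", 5000, "A", "G")

    def _pool(self, genotype: str, haplotype=HAPLO_2):
        samples = [
            make_patient("V1", haplotype=haplotype, genotypes={self.LOCUS: genotype}),
            make_patient("V2", haplotype=haplotype, genotypes={self.LOCUS: "0/0"}),
            make_patient("V3", haplotype=haplotype, genotypes={self.LOCUS: "0/0"}),
        ]
        return pool_vaccine(samples)

    def test_vaccine_het_patient_ref_is_foreign(self):
        patient = make_patient("P1", genotypes={self.LOCUS: "0/0"})
        foreign = alloantigen_variants(self._pool("0/1"), patient, [_germline_missense()])
        assert len(foreign) == 1

    def test_patient_carrying_allele_not_foreign(self):
        patient = make_patient("P1", genotypes={self.LOCUS: "0/1"})
        assert alloantigen_variants(self._pool("1/1"), patient, [_germline_missense()]) == []

    def test_missing_patient_genotype_skipped(self):
        patient = make_patient("P1", genotypes={})
        assert alloantigen_variants(self._pool("0/1"), patient, [_germline_missense()]) == []

    def test_self_vaccine_null(self):
        """A patient germline-identical to every vaccine sample has (0,0,0)."""
        genotypes = {self.LOCUS: "0/1", ("2", 6000, "A", "G"): "1/1"}
        pool = pool_vaccine([
            make_patient(f"V{i}", genotypes=genotypes) for i in range(3)
        ])
        patient = make_patient("P1", genotypes=genotypes)
        panel = [_germline_missense(), _germline_missense(("2", 6000, "A", "G"), 6, "R")]
        foreign = alloantigen_variants(pool, patient, panel)
        counts = allo_counts(foreign, patient, pool, _scorer([ConstantPredictor(100)]))
        assert (counts.pav_count, counts.strong_lysate, counts.strong_cell) == (0, 0, 0)

    def test_lysate_and_cell_tallies_are_independent(self):
        gv = _germline_missense()
        mut_pep = _mutant_peptide("GENEB", 3, "E", 1)
        # strong only on a vaccine allele (HLA-A*03:01 in HAPLO_2)
        scorer = _scorer([PeptideSetPredictor({(mut_pep, "HLA-A*03:01")})])
        patient = make_patient("P1", haplotype=HAPLO_1, genotypes={self.LOCUS: "0/0"})
        pool = self._pool("0/1", haplotype=HAPLO_2)
        foreign = alloantigen_variants(pool, patient, [gv])
        counts = allo_counts(foreign, patient, pool, scorer)
        assert (counts.pav_count, counts.strong_lysate, counts.strong_cell) == (1, 0, 1)

    def test_tight_threshold_zeroes_strong_but_not_pav(self):
        gv = _germline_missense()
        patient = make_patient("P1", genotypes={self.LOCUS: "0/0"})
        pool = self._pool("0/1")
        foreign = alloantigen_variants(pool, patient, [gv])
        counts = allo_counts(
            foreign, patient, pool, _scorer([ConstantPredictor(100)], ic50_threshold=1.0)
        )
        assert (counts.pav_count, counts.strong_lysate, counts.strong_cell) == (1, 0, 0)

    def test_no_foreign_variants_all_zero(self):
        patient = make_patient("P1")
        pool = self._pool("0/0")
        counts = allo_counts([], patient, pool, _scorer([ConstantPredictor(100)]))
        assert (counts.pav_count, counts.strong_lysate, counts.strong_cell) == (0, 0, 0)


def _trial_cohort_spec(n=40) -> CohortSpec:
    return CohortSpec(
        n_individuals=n,
        hla_frequencies={
            "A": [("HLA-A*01:01", 0.5), ("HLA-A*02:01", 0.5)],
            "B": [("HLA-B*07:02", 1.0)],
            "C": [("HLA-C*07:01", 1.0)],
        },
        drivers=[DriverSpec("GENEA", PROTEIN_DB["GENEA"][9], 10, "E", 0.5)],
        passenger_rate=1.0,
        expression_model={"default": ExpressionModel(1.0, 1.0, 0.1)},
        protein_db=dict(PROTEIN_DB),
    )


class TestRunTrials:
    def test_ten_iterations_yield_300_patient_records(self):
        cohort = generate_cohort(_trial_cohort_spec(), seed=2)
        config = TrialConfig(n_iterations=10, seed=9)
        results = run_trials(cohort, config, PROTEIN_DB, [ConstantPredictor(100)])
        assert len(results) == 10
        assert sum(len(r.patients) for r in results) == 300

    def test_same_seed_reproduces_identical_output(self):
        cohort = generate_cohort(_trial_cohort_spec(), seed=2)
        config = TrialConfig(n_iterations=4, seed=9)
        tables = [
            results_to_table(
                run_trials(cohort, config, PROTEIN_DB, [ConstantPredictor(100)])
            ).to_csv()
            for _ in range(2)
        ]
        assert tables[0] == tables[1]
        other = results_to_table(
            run_trials(
                cohort,
                TrialConfig(n_iterations=4, seed=10),
                PROTEIN_DB,
                [ConstantPredictor(100)],
            )
        ).to_csv()
        assert other != tables[0]

    def test_zero_iterations_empty(self):
        cohort = generate_cohort(_trial_cohort_spec(), seed=2)
        config = TrialConfig(n_iterations=0, seed=9)
        assert run_trials(cohort, config, PROTEIN_DB, [ConstantPredictor(100)]) == []

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(n_vaccine=4)  # 4 + 30 != 33
        with pytest.raises(ValueError):
            TrialConfig(cell_mode_neoantigen_rule="bogus")
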