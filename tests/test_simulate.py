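import math

import numpy as np
import pytest
import scipy.stats

from rarearch.architecture import summarize_probands
from rarearch.classify import classify_cohort
from rarearch.model import Architecture, ChromosomeClass, InheritanceMode, Sex, Zygosity
from rarearch.panel_io import write_manifest, write_variant_table
from rarearch.simulate import (
    GeneSimConfig,
    MafSpectrum,
    SimulationConfig,
    expected_architecture_fractions,
    recover_parameters,
    scale_frequencies,
    simulate_cohort,
    simulate_reference,
    study_config,
)


def simple_config(
    seed=0,
    n=100,
    f=0.1,
    n_genes=5,
    rho=1.0,
    mode=InheritanceMode.DOMINANT,
    groups=("KS",),
    **kwargs,
):
    genes = [
        GeneSimConfig(
            symbol=f"GENE{i}",
            inheritance_mode=mode,
            carrier_frequency=f,
            fraction_ptv=0.3,
        )
        for i in range(n_genes)
    ]
    return SimulationConfig(
        seed=seed,
        n_probands={g: n for g in groups},
        genes=genes,
        oligogenic_coupling=rho,
        **kwargs,
    )


class TestSimulateCohort:
    def test_zero_frequency_means_empty_cohort(self):
        cohort = simulate_cohort(simple_config(f=0.0))
        assert cohort.variants == [] and cohort.genotypes == []
        assert all(a is Architecture.NONE for a in cohort.truth.architectures.values())

    def test_degenerate_certain_dominant_gene(self):
        config = simple_config(f=1.0, n_genes=1, n=10)
        cohort = simulate_cohort(config)
        assert len(cohort.genotypes) == 10
        assert all(
            a is Architecture.MONOGENIC for a in cohort.truth.architectures.values()
        )
        assert all(c.zygosity is Zygosity.HET for c in cohort.genotypes)

    def test_recessive_genes_emit_biallelic_genotypes(self):
        config = simple_config(f=1.0, n_genes=1, n=40, mode=InheritanceMode.RECESSIVE)
        cohort = simulate_cohort(config)
        by_proband = {}
        for call in cohort.genotypes:
            by_proband.setdefault(call.proband_id, []).append(call)
        for calls in by_proband.values():
            zygosities = sorted(c.zygosity.value for c in calls)
            assert zygosities in (["hom"], ["het", "het"])

    def test_x_linked_gene_respects_sex(self):
        config = simple_config(f=1.0, n_genes=1, n=60, mode=InheritanceMode.X_LINKED)
        config.genes[0].chromosome_class = ChromosomeClass.X
        cohort = simulate_cohort(config)
        sex_of = {p.proband_id: p.sex for p in cohort.probands}
        for call in cohort.genotypes:
            expected = Zygosity.HEMI if sex_of[call.proband_id] is Sex.MALE else Zygosity.HET
            assert call.zygosity is expected

    def test_determinism_byte_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            cohort = simulate_cohort(simple_config(seed=42, background_rate=0.5))
            write_variant_table(
                cohort.variants, cohort.genotypes, str(tmp_path / f"{run}.tsv")
            )
            write_manifest(cohort.probands, str(tmp_path / f"{run}_manifest.tsv"))
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert (
            tmp_path / "a_manifest.tsv"
        ).read_bytes() == (tmp_path / "b_manifest.tsv").read_bytes()

    def test_oligogenic_fraction_matches_closed_form(self):
        """Independence (rho=1): P(oligogenic) = 1 - (1-f)^G - G f (1-f)^(G-1)."""
        f, n_genes, n = 0.1, 25, 10_000
        config = simple_config(seed=5, n=n, f=f, n_genes=n_genes)
        cohort = simulate_cohort(config)
        observed = sum(
            1 for a in cohort.truth.architectures.values() if a is Architecture.OLIGOGENIC
        )
        expected_p = 1 - (1 - f) ** n_genes - n_genes * f * (1 - f) ** (n_genes - 1)
        sd = math.sqrt(n * expected_p * (1 - expected_p))
        assert abs(observed - n * expected_p) <= 3 * sd

    def test_carrier_rate_unaffected_by_coupling(self):
        """P(no mutated gene) = prod(1 - f_g) for any rho."""
        for rho in (1.0, 3.0):
            config = simple_config(seed=11, n=8000, f=0.05, rho=rho)
            cohort = simulate_cohort(config)
            carriers = sum(
                1 for a in cohort.truth.architectures.values() if a is not Architecture.NONE
            )
            p = 1 - (1 - 0.05) ** 5
            sd = math.sqrt(8000 * p * (1 - p))
            assert abs(carriers - 8000 * p) <= 3 * sd

    def test_coupling_strictly_increases_oligogenic_fraction(self):
        fs = [0.08] * 6
        expected = [expected_architecture_fractions(fs, rho)[2] for rho in (1, 2, 4, 8)]
        assert expected == sorted(expected)
        assert expected[0] < expected[-1]
        observed = []
        for rho in (1.0, 8.0):
            cohort = simulate_cohort(
                simple_config(seed=3, n=4000, f=0.08, n_genes=6, rho=rho)
            )
            observed.append(
                sum(1 for a in cohort.truth.architectures.values() if a is Architecture.OLIGOGENIC)
            )
        assert observed[0] < observed[1]

    def test_independence_at_rho_one(self):
        """Pairwise gene co-mutation is consistent with independence."""
        config = simple_config(seed=9, n=5000, f=0.2, n_genes=2)
        cohort = simulate_cohort(config)
        carriers = {g.symbol: set() for g in config.genes}
        for m in cohort.truth.mutations:
            carriers[m.gene_symbol].add(m.proband_id)
        n = len(cohort.probands)
        both = len(carriers["GENE0"] & carriers["GENE1"])
        only0 = len(carriers["GENE0"]) - both
        only1 = len(carriers["GENE1"]) - both
        neither = n - both - only0 - only1
        _, p, _, _ = scipy.stats.chi2_contingency([[both, only0], [only1, neither]])
        assert p > 1e-3

    def test_infeasible_coupling_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            simple_config(f=0.6, rho=2.0)
        with pytest.raises(ValueError, match="rho"):
            simple_config(rho=0.5)


class TestMafSpectrum:
    def test_private_mass_and_rare_tail(self):
        rng = np.random.default_rng(0)
        spectrum = MafSpectrum()
        draws = [spectrum.draw(rng) for _ in range(4000)]
        private = sum(1 for d in draws if d == 0.0)
        assert abs(private - 2000) < 3 * math.sqrt(4000 * 0.25)
        assert max(draws) < 0.025
        rare = [spectrum.draw_rare(rng) for _ in range(1000)]
        assert max(rare) < 0.01


class TestSimulateReference:
    def test_binomial_moments(self):
        counts = []
        for seed in range(20):
            config = simple_config(seed=seed, n_genes=1, reference_alleles=10_000)
            config.genes[0].control_allele_frequency = 0.01
            table = simulate_reference(config)
            counts.append(table.lookup("GENE0", "NFE")[0])
        mean = sum(counts) / len(counts)
        sd = math.sqrt(10_000 * 0.01 * 0.99)
        assert abs(mean - 100) <= 3 * sd / math.sqrt(len(counts))

    def test_zero_frequency_all_zero(self):
        config = simple_config(n_genes=3)
        for g in config.genes:
            g.control_allele_frequency = 0.0
        table = simulate_reference(config)
        assert all(
            table.lookup(g.symbol, "NFE")[0] == 0 for g in config.genes
        )

    def test_deterministic_under_seed(self):
        tables = [simulate_reference(simple_config(seed=7)) for _ in range(2)]
        assert tables[0].records == tables[1].records


class TestRecovery:
    def _pipeline(self, config):
        cohort = simulate_cohort(config)
        mutations, _ = classify_cohort(
            cohort.variants,
            cohort.genotypes,
            cohort.probands,
            cohort.panel,
            {group: config.reference_population for group in config.n_probands},
        )
        return cohort, mutations

    def test_noiseless_config_recovers_truth_exactly(self):
        config = simple_config(seed=21, n=200, background_rate=0.0)
        cohort, mutations = self._pipeline(config)
        report = recover_parameters(cohort.truth, mutations, cohort.probands)
        assert report.concordance == 1.0

    def test_blind_predictors_suppress_missense_recovery(self):
        """With damaging-rate 0 the classifier cannot see missense
        mutations; only the PTV fraction survives."""
        config = simple_config(seed=22, n=300, predictor_damaging_rate=0.0)
        cohort, mutations = self._pipeline(config)
        assert all(m.is_ptv for m in mutations)
        report = recover_parameters(cohort.truth, mutations, cohort.probands)
        assert report.concordance < 0.6

    def test_mismatched_probands_rejected(self):
        config = simple_config(seed=23, n=20)
        cohort, mutations = self._pipeline(config)
        with pytest.raises(ValueError, match="unknown probands"):
            recover_parameters(cohort.truth, mutations, cohort.probands[:5])


class TestStudyConfig:
    def test_group_sizes_and_sex_ratio(self):
        config = study_config(1)
        assert config.n_probands == {"KS": 61, "nCHH": 55, "CDGP": 72, "CONTROL": 405}
        assert config.male_fraction["KS"] == pytest.approx(2 / 3)

    def test_expected_carrier_rates_match_targets(self):
        config = study_config(1)
        targets = {"KS": 0.51, "nCHH": 0.51, "CDGP": 5 / 72, "CONTROL": 72 / 405}
        for group, target in targets.items():
            p_none = math.prod(1 - g.f_of(group) for g in config.genes)
            assert 1 - p_none == pytest.approx(target, abs=1e-6)

    def test_scale_frequencies_solves_the_carrier_equation(self):
        weights = [3.0, 1.0, 0.0, 2.0]
        fs = scale_frequencies(weights, 0.4)
        assert fs[2] == 0.0
        assert 1 - math.prod(1 - f for f in fs) == pytest.approx(0.4, abs=1e-9)

    def test_yaml_round_trip(self, tmp_path):
        config = study_config(3)
        path = tmp_path / "config.yaml"
        config.to_yaml(str(path))
        again = SimulationConfig.from_yaml(str(path))
        assert again == config
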