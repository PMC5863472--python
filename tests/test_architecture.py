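import pytest

from rarearch.architecture import (
    cohort_counts,
    collapse_gene_states,
    digenic_matrix,
    gene_state,
    proband_architecture,
    summarize_probands,
)
from rarearch.model import (
    Architecture,
    GeneStateClass,
    Group,
    MutationCall,
    MutationRule,
    Sex,
    ValidationError,
    Zygosity,
)

from conftest import make_proband


def mutation(pid="P1", vid="chr8:1:A:G", gene="FGFR1", zygosity=Zygosity.HET):
    return MutationCall(
        proband_id=pid,
        variant_id=vid,
        gene_symbol=gene,
        rule_fired=MutationRule.RARE_DAMAGING_MISSENSE,
        is_ptv=False,
        zygosity=zygosity,
    )


class TestGeneState:
    def test_two_hets_presumed_compound_heterozygous(self):
        calls = [
            mutation(vid="chr4:1:A:G", gene="GNRHR"),
            mutation(vid="chr4:2:C:T", gene="GNRHR"),
        ]
        state = gene_state(calls)
        assert state.state is GeneStateClass.BIALLELIC
        assert state.n_mutations == 2
        assert state.allele_count == 2

    def test_compound_het_presumption_can_be_demoted(self):
        calls = [
            mutation(vid="chr4:1:A:G", gene="GNRHR"),
            mutation(vid="chr4:2:C:T", gene="GNRHR"),
        ]
        assert (
            gene_state(calls, presume_compound_het=False).state
            is GeneStateClass.MONOALLELIC
        )

    def test_homozygous_is_biallelic_with_two_alleles(self):
        state = gene_state([mutation(zygosity=Zygosity.HOM)])
        assert state.state is GeneStateClass.BIALLELIC
        assert state.allele_count == 2

    def test_hemizygous_male_is_monoallelic(self):
        state = gene_state([mutation(gene="ANOS1", zygosity=Zygosity.HEMI)])
        assert state.state is GeneStateClass.MONOALLELIC
        assert state.allele_count == 1

    def test_single_het_is_monoallelic(self):
        assert gene_state([mutation()]).state is GeneStateClass.MONOALLELIC

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError, match="one proband and one gene"):
            gene_state([mutation(gene="FGFR1"), mutation(gene="CHD7", vid="x")])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gene_state([])


class TestProbandArchitecture:
    def test_two_monoallelic_genes_is_oligogenic(self):
        states = collapse_gene_states(
            [mutation(gene="FGFR1"), mutation(gene="CHD7", vid="chr8:2:C:T")]
        )
        summary = proband_architecture(make_proband(), states)
        assert summary.architecture is Architecture.OLIGOGENIC
        assert summary.mutated_genes == {"FGFR1", "CHD7"}

    def test_one_biallelic_gene_is_monogenic(self):
        states = collapse_gene_states(
            [
                mutation(gene="GNRHR", vid="chr4:1:A:G"),
                mutation(gene="GNRHR", vid="chr4:2:C:T"),
            ]
        )
        summary = proband_architecture(make_proband(), states)
        assert summary.architecture is Architecture.MONOGENIC
        assert summary.has_biallelic

    def test_biallelic_plus_monoallelic_counts_two_genes(self):
        """A biallelic gene counts once toward the gene tally, so one
        biallelic plus one monoallelic gene is oligogenic."""
        states = collapse_gene_states(
            [
                mutation(gene="GNRHR", vid="chr4:1:A:G"),
                mutation(gene="GNRHR", vid="chr4:2:C:T"),
                mutation(gene="FGFR1", vid="chr8:1:A:G"),
            ]
        )
        summary = proband_architecture(make_proband(), states)
        assert summary.architecture is Architecture.OLIGOGENIC

    def test_no_mutations_is_none(self):
        summary = proband_architecture(make_proband(), [])
        assert summary.architecture is Architecture.NONE
        assert summary.mutated_genes == frozenset()


class TestCohortCounts:
    def _fixture(self, panel):
        """Ten CONTROL probands; one female carries a homozygous GNRHR
        mutation, the rest carry nothing."""
        probands = [
            make_proband(f"P{i}", Group.CONTROL, Sex.FEMALE if i == 0 else Sex.MALE)
            for i in range(10)
        ]
        mutations = [mutation(pid="P0", vid="chr4:1:A:G", gene="GNRHR", zygosity=Zygosity.HOM)]
        summaries, states = summarize_probands(probands, mutations)
        return probands, summaries, states

    def test_hand_counted_allele_tallies(self, panel):
        probands, summaries, states = self._fixture(panel)
        counts = cohort_counts(summaries, states, probands, panel)
        control = counts["CONTROL"]
        assert control.n_probands == 10
        assert control.n_carriers == control.n_monogenic == 1
        assert control.n_with_biallelic == 1
        gnrhr = control.genes["GNRHR"]
        assert gnrhr.mutated_alleles == 2
        assert gnrhr.alleles_inspected == 20
        # X-linked gene: 2 alleles for the female + 1 per male
        assert control.genes["ANOS1"].alleles_inspected == 2 + 9

    def test_partition_none_monogenic_oligogenic(self, panel):
        probands, summaries, states = self._fixture(panel)
        counts = cohort_counts(summaries, states, probands, panel)
        for cc in counts.values():
            n_arch = sum(
                1 for s in summaries if s.architecture is not Architecture.NONE
            )
            assert cc.n_none + cc.n_monogenic + cc.n_oligogenic == cc.n_probands

    def test_empty_cohort_all_zero(self, panel):
        probands = [make_proband(f"P{i}", Group.CDGP) for i in range(5)]
        summaries, states = summarize_probands(probands, [])
        counts = cohort_counts(summaries, states, probands, panel)
        cdgp = counts["CDGP"]
        assert cdgp.n_carriers == cdgp.n_oligogenic == cdgp.n_with_biallelic == 0
        assert all(g.mutated_alleles == 0 for g in cdgp.genes.values())

    def test_orphan_proband_rejected(self, panel):
        probands = [make_proband("P1", Group.KS)]
        with pytest.raises(ValidationError, match="GHOST"):
            summarize_probands(probands, [mutation(pid="GHOST")])

    def test_chh_pooled_group(self, panel):
        probands = [
            make_proband("K1", Group.KS),
            make_proband("N1", Group.NCHH),
            make_proband("C1", Group.CONTROL),
        ]
        mutations = [mutation(pid="K1"), mutation(pid="N1", vid="chr8:9:G:A")]
        summaries, states = summarize_probands(probands, mutations)
        counts = cohort_counts(summaries, states, probands, panel)
        assert counts["CHH"].n_probands == 2
        assert counts["CHH"].n_carriers == 2
        assert counts["CONTROL"].n_carriers == 0

    def test_monotonicity_under_deletion(self, panel):
        """Removing one proband's mutations never increases any count."""
        probands = [make_proband(f"P{i}", Group.KS) for i in range(4)]
        mutations = [
            mutation(pid="P0", vid="v1", gene="FGFR1"),
            mutation(pid="P0", vid="v2", gene="CHD7"),
            mutation(pid="P1", vid="v3", gene="FGFR1"),
            mutation(pid="P2", vid="v4", gene="GNRHR", zygosity=Zygosity.HOM),
        ]
        full_summaries, full_states = summarize_probands(probands, mutations)
        full = cohort_counts(full_summaries, full_states, probands, panel)["KS"]
        reduced_mutations = [m for m in mutations if m.proband_id != "P0"]
        summaries, states = summarize_probands(probands, reduced_mutations)
        reduced = cohort_counts(summaries, states, probands, panel)["KS"]
        assert reduced.n_carriers <= full.n_carriers
        assert reduced.n_oligogenic <= full.n_oligogenic
        assert reduced.n_with_biallelic <= full.n_with_biallelic
        for gene in full.genes:
            assert reduced.genes[gene].mutated_alleles <= full.genes[gene].mutated_alleles


class TestDigenicMatrix:
    def test_most_frequent_pair_count(self, panel):
        probands = [make_proband(f"P{i}", Group.KS) for i in range(4)]
        mutations = []
        for i in range(4):
            mutations.append(mutation(pid=f"P{i}", vid=f"a{i}", gene="FGFR1"))
            mutations.append(mutation(pid=f"P{i}", vid=f"b{i}", gene="CHD7"))
        summaries, _ = summarize_probands(probands, mutations)
        matrix = digenic_matrix(summaries, panel)
        assert matrix.loc["FGFR1", "CHD7"] == 4
        assert matrix.loc["CHD7", "FGFR1"] == 4

    def test_three_gene_proband_increments_three_pairs(self, panel):
        probands = [make_proband("P1", Group.KS)]
        mutations = [
            mutation(pid="P1", vid="v1", gene="FGFR1"),
            mutation(pid="P1", vid="v2", gene="CHD7"),
            mutation(pid="P1", vid="v3", gene="SOX10"),
        ]
        summaries, _ = summarize_probands(probands, mutations)
        matrix = digenic_matrix(summaries, panel)
        assert matrix.to_numpy().sum() == 6  # 3 pairs, counted symmetrically
        for g1, g2 in (("FGFR1", "CHD7"), ("FGFR1", "SOX10"), ("CHD7", "SOX10")):
            assert matrix.loc[g1, g2] == 1

    def test_symmetry_and_zero_diagonal(self, panel):
        probands = [make_proband(f"P{i}", Group.KS) for i in range(3)]
        mutations = [
            mutation(pid="P0", vid="v1", gene="FGFR1"),
            mutation(pid="P0", vid="v2", gene="CHD7"),
            mutation(pid="P1", vid="v3", gene="CHD7"),
            mutation(pid="P1", vid="v4", gene="HS6ST1"),
        ]
        summaries, _ = summarize_probands(probands, mutations)
        matrix = digenic_matrix(summaries, panel)
        assert (matrix.to_numpy() == matrix.to_numpy().T).all()
        assert (matrix.to_numpy().diagonal() == 0).all()

    def test_pair_sum_bounds_oligogenic_count(self, panel):
        """Sum of upper-triangle entries >= number of oligogenic probands,
        with equality iff every oligogenic proband has exactly two genes."""
        probands = [make_proband(f"P{i}", Group.KS) for i in range(3)]
        mutations = [
            mutation(pid="P0", vid="v1", gene="FGFR1"),
            mutation(pid="P0", vid="v2", gene="CHD7"),
            mutation(pid="P1", vid="v3", gene="FGFR1"),
            mutation(pid="P1", vid="v4", gene="CHD7"),
            mutation(pid="P1", vid="v5", gene="SOX10"),
        ]
        summaries, _ = summarize_probands(probands, mutations)
        matrix = digenic_matrix(summaries, panel)
        n_oligogenic = sum(
            1 for s in summaries if s.architecture is Architecture.OLIGOGENIC
        )
        assert matrix.to_numpy().sum() // 2 == 4 >= n_oligogenic

    def test_no_oligogenic_probands_zero_matrix(self, panel):
        probands = [make_proband("P1", Group.KS)]
        summaries, _ = summarize_probands(probands, [mutation(pid="P1")])
        assert digenic_matrix(summaries, panel).to_numpy().sum() == 0
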