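"""Collapse mutation calls to per-gene allelic states and per-proband
genetic architecture, then to cohort-level count surfaces.

Allelic state per (proband, gene): a homozygous mutation, or two or more
heterozygous mutations (presumed compound heterozygous in the absence of
phasing), is *biallelic*; a single heterozygous or hemizygous mutation is
*monoallelic*. A proband's architecture counts mutated genes: one gene is
*monogenic*, two or more are *oligogenic* — a biallelic gene still counts
as one gene.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .model import (
    Architecture,
    ChromosomeClass,
    GenePanelEntry,
    GeneState,
    GeneStateClass,
    MutationCall,
    Proband,
    Sex,
    ValidationError,
    Zygosity,
)


@dataclass(frozen=True)
class AllelicState(GeneState):
    """Gene state with the mutated-allele tally (het/hemi = 1, hom = 2)."""

    allele_count: int = 0


def gene_state(
    calls: list[MutationCall],
    presume_compound_het: bool = True,
) -> AllelicState:
    """Collapse one proband's mutation calls in one gene to an allelic state.

    With ``presume_compound_het`` (default), two or more unphased
    heterozygous mutations are treated as compound heterozygous, hence
    biallelic; set it to False to demote such pairs to monoallelic for
    sensitivity analysis.
    """
    if not calls:
        raise ValueError("gene_state requires at least one mutation call")
    probands = {c.proband_id for c in calls}
    genes = {c.gene_symbol for c in calls}
    if len(probands) > 1 or len(genes) > 1:
        raise ValueError(
            f"gene_state calls must share one proband and one gene, "
            f"got {probands} x {genes}"
        )
    n_hom = sum(1 for c in calls if c.zygosity is Zygosity.HOM)
    n_het = sum(1 for c in calls if c.zygosity is Zygosity.HET)
    n_hemi = sum(1 for c in calls if c.zygosity is Zygosity.HEMI)
    if n_hemi and (n_hom or n_het):
        raise ValidationError(
            f"{calls[0].proband_id}/{calls[0].gene_symbol}: hemizygous and "
            "diploid calls cannot coexist in one gene"
        )
    if n_hom > 0:
        state = GeneStateClass.BIALLELIC
    elif n_het >= 2 and presume_compound_het:
        state = GeneStateClass.BIALLELIC
    else:
        state = GeneStateClass.MONOALLELIC
    return AllelicState(
        proband_id=calls[0].proband_id,
        gene_symbol=calls[0].gene_symbol,
        state=state,
        n_mutations=len(calls),
        allele_count=sum(c.allele_count for c in calls),
    )


def collapse_gene_states(
    mutations: list[MutationCall],
    presume_compound_het: bool = True,
) -> list[AllelicState]:
    """Group mutation calls by (proband, gene) and collapse each group."""
    grouped: dict[tuple[str, str], list[MutationCall]] = defaultdict(list)
    for m in mutations:
        grouped[(m.proband_id, m.gene_symbol)].append(m)
    return [
        gene_state(calls, presume_compound_het)
        for _, calls in sorted(grouped.items())
    ]


def proband_architecture(
    proband: Proband, states: list[AllelicState]
) -> "ProbandSummary":
    """Classify one proband from their per-gene states."""
    mutated = frozenset(
        s.gene_symbol for s in states if s.state is not GeneStateClass.NONE
    )
    for s in states:
        if s.proband_id != proband.proband_id:
            raise ValueError(
                f"state for {s.proband_id} passed to {proband.proband_id}"
            )
    n = len(mutated)
    architecture = (
        Architecture.NONE
        if n == 0
        else Architecture.MONOGENIC
        if n == 1
        else Architecture.OLIGOGENIC
    )
    has_biallelic = any(s.state is GeneStateClass.BIALLELIC for s in states)
    return ProbandSummary(
        proband_id=proband.proband_id,
        group=proband.group.value,
        mutated_genes=mutated,
        architecture=architecture,
        has_biallelic=has_biallelic,
    )


@dataclass(frozen=True)
class ProbandSummary:
    proband_id: str
    group: str
    mutated_genes: frozenset[str]
    architecture: Architecture
    has_biallelic: bool


def summarize_probands(
    probands: list[Proband],
    mutations: list[MutationCall],
    presume_compound_het: bool = True,
) -> tuple[list[ProbandSummary], list[AllelicState]]:
    """Per-proband architecture summaries for a whole cohort."""
    states = collapse_gene_states(mutations, presume_compound_het)
    states_by_proband: dict[str, list[AllelicState]] = defaultdict(list)
    for s in states:
        states_by_proband[s.proband_id].append(s)
    known = {p.proband_id for p in probands}
    orphans = sorted(set(states_by_proband) - known)
    if orphans:
        raise ValidationError(
            f"mutations for probands absent from the manifest: {', '.join(orphans)}"
        )
    summaries = [
        proband_architecture(p, states_by_proband.get(p.proband_id, []))
        for p in probands
    ]
    return summaries, states


@dataclass
class GeneCounts:
    """Per-gene cohort tallies for one group."""

    gene_symbol: str
    n_carriers: int = 0
    mutated_alleles: int = 0
    alleles_inspected: int = 0


@dataclass
class CohortCounts:
    """Cohort-level count surface for one group."""

    group: str
    n_probands: int = 0
    n_carriers: int = 0
    n_monogenic: int = 0
    n_oligogenic: int = 0
    n_with_biallelic: int = 0
    genes: dict[str, GeneCounts] = field(default_factory=dict)

    @property
    def n_none(self) -> int:
        return self.n_probands - self.n_carriers

    def validate(self) -> None:
        if self.n_carriers != self.n_monogenic + self.n_oligogenic:
            raise ValidationError(
                f"{self.group}: carriers != monogenic + oligogenic"
            )
        if self.n_carriers > self.n_probands:
            raise ValidationError(f"{self.group}: more carriers than probands")
        for gc in self.genes.values():
            if gc.mutated_alleles > gc.alleles_inspected:
                raise ValidationError(
                    f"{self.group}/{gc.gene_symbol}: mutated alleles exceed "
                    "alleles inspected"
                )


def alleles_inspected(
    entry: GenePanelEntry, probands: list[Proband]
) -> int:
    """Alleles inspected for one gene: 2N autosomal, 2F + M for X genes."""
    if entry.chromosome_class is ChromosomeClass.AUTOSOMAL:
        return 2 * len(probands)
    n_males = sum(1 for p in probands if p.sex is Sex.MALE)
    return 2 * (len(probands) - n_males) + n_males


def cohort_counts(
    summaries: list[ProbandSummary],
    states: list[AllelicState],
    probands: list[Proband],
    panel: list[GenePanelEntry],
    derived_groups: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, CohortCounts]:
    """Tally carriers, architecture classes, and per-gene allele counts.

    ``derived_groups`` adds pooled groups, e.g. ``{"CHH": ("KS", "nCHH")}``;
    the combined case group is included by default.
    """
    if derived_groups is None:
        derived_groups = {"CHH": ("KS", "nCHH")}
    seen: set[str] = set()
    for p in probands:
        if p.proband_id in seen:
            raise ValidationError(f"duplicate proband {p.proband_id}")
        seen.add(p.proband_id)
    summary_of = {s.proband_id: s for s in summaries}
    missing = [p.proband_id for p in probands if p.proband_id not in summary_of]
    if missing:
        raise ValidationError(
            f"probands without architecture summaries: {', '.join(missing)}"
        )

    base_groups = sorted({p.group.value for p in probands})
    membership: dict[str, list[Proband]] = {
        g: [p for p in probands if p.group.value == g] for g in base_groups
    }
    for name, parts in derived_groups.items():
        members = [p for p in probands if p.group.value in parts]
        if members:
            membership[name] = members

    states_by_proband: dict[str, list[AllelicState]] = defaultdict(list)
    for s in states:
        states_by_proband[s.proband_id].append(s)

    out: dict[str, CohortCounts] = {}
    for group, members in membership.items():
        counts = CohortCounts(group=group, n_probands=len(members))
        counts.genes = {
            e.gene_symbol: GeneCounts(
                gene_symbol=e.gene_symbol,
                alleles_inspected=alleles_inspected(e, members),
            )
            for e in panel
        }
        for p in members:
            s = summary_of[p.proband_id]
            if s.architecture is Architecture.MONOGENIC:
                counts.n_monogenic += 1
                counts.n_carriers += 1
            elif s.architecture is Architecture.OLIGOGENIC:
                counts.n_oligogenic += 1
                counts.n_carriers += 1
            if s.has_biallelic:
                counts.n_with_biallelic += 1
            for state in states_by_proband.get(p.proband_id, []):
                gc = counts.genes[state.gene_symbol]
                gc.n_carriers += 1
                gc.mutated_alleles += state.allele_count
        counts.validate()
        out[group] = counts
    return out


def digenic_matrix(
    summaries: list[ProbandSummary], panel: list[GenePanelEntry]
) -> pd.DataFrame:
    """Symmetric gene x gene matrix of digenic co-mutation counts.

    Entry (g1, g2) counts probands with both genes mutated; a proband with
    k >= 2 mutated genes contributes to all C(k, 2) pairs. The diagonal
    is zero.
    """
    genes = [e.gene_symbol for e in panel]
    matrix = pd.DataFrame(0, index=genes, columns=genes, dtype=int)
    for s in summaries:
        for g1, g2 in itertools.combinations(sorted(s.mutated_genes), 2):
            if g1 in matrix.index and g2 in matrix.index:
                matrix.loc[g1, g2] += 1
                matrix.loc[g2, g1] += 1
    return matrix


def write_architecture_table(summaries: list[ProbandSummary], path: str) -> None:
    pd.DataFrame(
        {
            "proband_id": [s.proband_id for s in summaries],
            "group": [s.group for s in summaries],
            "mutated_genes": [";".join(sorted(s.mutated_genes)) for s in summaries],
            "architecture": [s.architecture.value for s in summaries],
            "has_biallelic": [str(s.has_biallelic).lower() for s in summaries],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_counts(counts: dict[str, CohortCounts], path: str) -> None:
    rows = []
    for group, cc in sorted(counts.items()):
        for gene, gc in cc.genes.items():
            rows.append(
                {
                    "group": group,
                    "gene": gene,
                    "n_carriers": gc.n_carriers,
                    "mutated_alleles": gc.mutated_alleles,
                    "alleles_inspected": gc.alleles_inspected,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
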