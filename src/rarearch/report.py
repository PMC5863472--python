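"""Human-readable report surfaces: per-gene prevalence grids, inheritance
breakdowns, architecture histograms, the digenic matrix, and the
gene x group mutated-allele-frequency grid with burden-test p-values.

Every number in a report table is re-derivable from the upstream TSVs;
percentages are rounded half-up at one decimal and raw counts are always
carried alongside.
"""

from __future__ import annotations

import decimal
from collections import defaultdict

import pandas as pd

from .architecture import AllelicState, CohortCounts, ProbandSummary
from .model import (
    Architecture,
    ConsequenceClass,
    GenePanelEntry,
    GeneStateClass,
    MutationCall,
    Proband,
)
from .panel_io import ReferenceCountTable
from .stats import bonferroni_cutoff, rva_gene_test

#: Display classes used by the per-gene prevalence histograms.
_DISPLAY_CLASS = {
    ConsequenceClass.MISSENSE: "nonsynonymous",
    ConsequenceClass.INFRAME_INDEL: "nonsynonymous",
    ConsequenceClass.SPLICE_CANDIDATE: "splicing",
    ConsequenceClass.FRAMESHIFT: "nonsense",
    ConsequenceClass.STOP_GAIN: "nonsense",
    ConsequenceClass.OTHER: "other",
}


def round_half_up(value: float, digits: int = 1) -> float:
    """Round half away from zero at ``digits`` decimals (display rule)."""
    q = decimal.Decimal(1).scaleb(-digits)
    return float(
        decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def gene_prevalence_table(
    mutations: list[MutationCall],
    probands: list[Proband],
    panel: list[GenePanelEntry],
) -> pd.DataFrame:
    """Per-group, per-gene carrier prevalence split by consequence class.

    A proband counts once per (gene, display class) they carry; columns
    carry both raw carrier counts and percentages of the group size.
    """
    group_of = {p.proband_id: p.group.value for p in probands}
    group_sizes: dict[str, int] = defaultdict(int)
    for p in probands:
        group_sizes[p.group.value] += 1
    carriers: dict[tuple[str, str, str], set[str]] = defaultdict(set)
    for m in mutations:
        display = _DISPLAY_CLASS[m.consequence_class]
        carriers[(group_of[m.proband_id], m.gene_symbol, display)].add(m.proband_id)
    rows = []
    for group in sorted(group_sizes):
        n = group_sizes[group]
        for entry in panel:
            gene = entry.gene_symbol
            all_carriers: set[str] = set()
            row: dict[str, object] = {"group": group, "gene": gene, "n_probands": n}
            for display in ("nonsynonymous", "splicing", "nonsense"):
                ids = carriers.get((group, gene, display), set())
                all_carriers |= ids
                row[f"n_{display}"] = len(ids)
                row[f"pct_{display}"] = round_half_up(100.0 * len(ids) / n)
            row["n_carriers"] = len(all_carriers)
            row["pct_carriers"] = round_half_up(100.0 * len(all_carriers) / n)
            rows.append(row)
    return pd.DataFrame(rows)


def inheritance_breakdown(
    summaries: list[ProbandSummary],
    states: list[AllelicState],
    probands: list[Proband],
    panel: list[GenePanelEntry],
) -> pd.DataFrame:
    """Per-group, per-gene carrier counts by inheritance pattern.

    Each gene carrier is classified once: *oligogenic* when the proband has
    two or more mutated genes, else *biallelic* or *monoallelic* from the
    gene's allelic state.
    """
    group_of = {p.proband_id: p.group.value for p in probands}
    group_sizes: dict[str, int] = defaultdict(int)
    for p in probands:
        group_sizes[p.group.value] += 1
    arch_of = {s.proband_id: s.architecture for s in summaries}
    tallies: dict[tuple[str, str, str], int] = defaultdict(int)
    for state in states:
        if state.state is GeneStateClass.NONE:
            continue
        group = group_of[state.proband_id]
        if arch_of[state.proband_id] is Architecture.OLIGOGENIC:
            pattern = "oligogenic"
        elif state.state is GeneStateClass.BIALLELIC:
            pattern = "biallelic"
        else:
            pattern = "monoallelic"
        tallies[(group, state.gene_symbol, pattern)] += 1
    rows = []
    for group in sorted(group_sizes):
        n = group_sizes[group]
        for entry in panel:
            gene = entry.gene_symbol
            row: dict[str, object] = {"group": group, "gene": gene, "n_probands": n}
            for pattern in ("monoallelic", "biallelic", "oligogenic"):
                k = tallies.get((group, gene, pattern), 0)
                row[f"n_{pattern}"] = k
                row[f"pct_{pattern}"] = round_half_up(100.0 * k / n)
            rows.append(row)
    return pd.DataFrame(rows)


def architecture_histogram(
    summaries: list[ProbandSummary], derived_groups: dict[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Counts and percentages of none / monogenic / oligogenic per group."""
    if derived_groups is None:
        derived_groups = {"CHH": ("KS", "nCHH")}
    members: dict[str, list[ProbandSummary]] = defaultdict(list)
    for s in summaries:
        members[s.group].append(s)
    for name, parts in derived_groups.items():
        pooled = [s for s in summaries if s.group in parts]
        if pooled:
            members[name] = pooled
    rows = []
    for group in sorted(members):
        group_summaries = members[group]
        n = len(group_summaries)
        row: dict[str, object] = {"group": group, "n_probands": n}
        for arch in Architecture:
            k = sum(1 for s in group_summaries if s.architecture is arch)
            row[f"n_{arch.value}"] = k
            row[f"pct_{arch.value}"] = round_half_up(100.0 * k / n)
        row["n_biallelic_carriers"] = sum(1 for s in group_summaries if s.has_biallelic)
        rows.append(row)
    return pd.DataFrame(rows)


def burden_grid(
    counts: dict[str, CohortCounts],
    reference: ReferenceCountTable,
    panel: list[GenePanelEntry],
    case_groups: list[str],
    population: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene x group mutated-allele-frequency grid with burden p-values.

    For each case group and gene, the mutated-allele frequency and the
    gene-collapsed exact test against the reference population; the
    family-wise cutoff is alpha over the number of panel genes.
    """
    cutoff = bonferroni_cutoff(alpha, len(panel))
    rows = []
    for group in case_groups:
        cc = counts[group]
        for entry in panel:
            gene = entry.gene_symbol
            gc = cc.genes[gene]
            ref_alt, ref_total = reference.lookup(gene, population)
            result = rva_gene_test(
                gene,
                (gc.mutated_alleles, gc.alleles_inspected),
                (ref_alt, ref_total),
                cutoff,
            )
            rows.append(
                {
                    "group": group,
                    "gene": gene,
                    "case_alt_alleles": result.case_alt_alleles,
                    "case_total_alleles": result.case_total_alleles,
                    "pct_mutated_alleles": round_half_up(100.0 * result.case_frequency),
                    "ref_alt_alleles": result.ref_alt_alleles,
                    "ref_total_alleles": result.ref_total_alleles,
                    "p_value": result.p_value,
                    "cutoff": cutoff,
                    "significant": str(result.significant).lower(),
                }
            )
    return pd.DataFrame(rows)


def plot_architecture_histogram(histogram: pd.DataFrame, path: str) -> None:
    """Grouped bar chart of none / monogenic / oligogenic percentages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    classes = [a.value for a in Architecture]
    width = 0.8 / len(histogram)
    for i, row in enumerate(histogram.itertuples(index=False)):
        values = [getattr(row, f"pct_{c}") for c in classes]
        positions = [j + i * width for j in range(len(classes))]
        ax.bar(positions, values, width=width, label=row.group)
    ax.set_xticks([j + 0.4 - width / 2 for j in range(len(classes))])
    ax.set_xticklabels(classes)
    ax.set_ylabel("% of probands")
    ax.legend(title="group", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_digenic_matrix(matrix: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(matrix.to_numpy(), cmap="Reds")
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)))
    ax.set_yticklabels(matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="co-mutated probands")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
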