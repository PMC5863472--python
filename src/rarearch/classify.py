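"""Variant filtering cascade and the three-part mutation definition.

A variant-proband observation is called a *mutation* when, after genotype
quality and consequence-class filtering, it satisfies one of three rules,
in precedence order:

1. in-vitro loss of function: a rare (MAF < 1%) variant with experimental
   loss-of-function evidence, regardless of in-silico predictions;
2. rare PTV: a rare protein-truncating variant (frameshift, stop gain, or
   splice candidate);
3. rare damaging missense: a rare missense variant called damaging by at
   least one of the two in-silico predictors.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

from .model import (
    AnnotatedVariant,
    ConsequenceClass,
    GenePanelEntry,
    GenotypeCall,
    MutationCall,
    MutationRule,
    Proband,
    Verdict,
)
from .panel_io import ReferenceCountTable
from .splice import PWMScorer, SpliceSiteContext, passes_splice_filter

logger = logging.getLogger(__name__)

GQ_MIN = 50.0
MAF_THRESHOLD = 0.01


class ConfigurationError(ValueError):
    """A cohort/population configuration problem (not a data problem)."""


# SnpEff / Sequence Ontology terms mapped to the internal consequence classes.
_CONSEQUENCE_VOCABULARY: dict[str, ConsequenceClass] = {
    "missense_variant": ConsequenceClass.MISSENSE,
    "missense": ConsequenceClass.MISSENSE,
    "inframe_insertion": ConsequenceClass.INFRAME_INDEL,
    "inframe_deletion": ConsequenceClass.INFRAME_INDEL,
    "conservative_inframe_insertion": ConsequenceClass.INFRAME_INDEL,
    "conservative_inframe_deletion": ConsequenceClass.INFRAME_INDEL,
    "disruptive_inframe_insertion": ConsequenceClass.INFRAME_INDEL,
    "disruptive_inframe_deletion": ConsequenceClass.INFRAME_INDEL,
    "frameshift_variant": ConsequenceClass.FRAMESHIFT,
    "frameshift": ConsequenceClass.FRAMESHIFT,
    "stop_gained": ConsequenceClass.STOP_GAIN,
    "stop_gain": ConsequenceClass.STOP_GAIN,
    "nonsense": ConsequenceClass.STOP_GAIN,
    # Essential splice-site disruptions are splice candidates outright.
    "splice_donor_variant": ConsequenceClass.SPLICE_CANDIDATE,
    "splice_acceptor_variant": ConsequenceClass.SPLICE_CANDIDATE,
}

#: Raw terms treated as intronic: retained only via the splice filter.
_INTRONIC_TERMS = {
    "intron_variant",
    "intronic",
    "splice_region_variant",
}

#: PTV = protein-truncating consequence classes.
_PTV_CLASSES = {
    ConsequenceClass.FRAMESHIFT,
    ConsequenceClass.STOP_GAIN,
    ConsequenceClass.SPLICE_CANDIDATE,
}


def quality_filter(call: GenotypeCall, gq_min: float = GQ_MIN) -> bool:
    """True iff the call's genotype quality is present and >= ``gq_min``."""
    if call.genotype_quality is None:
        return False
    return call.genotype_quality >= gq_min


def is_intronic(raw_consequence: str) -> bool:
    return raw_consequence.strip().lower() in _INTRONIC_TERMS


def consequence_class(raw_consequence: str, splice_pass: bool = False) -> ConsequenceClass:
    """Map a raw annotation term to an internal consequence class.

    Intronic terms become ``splice_candidate`` only when the splice filter
    passed; unmapped terms become ``other`` with a logged warning.
    """
    term = raw_consequence.strip().lower()
    if term in _CONSEQUENCE_VOCABULARY:
        return _CONSEQUENCE_VOCABULARY[term]
    if is_intronic(term):
        return (
            ConsequenceClass.SPLICE_CANDIDATE if splice_pass else ConsequenceClass.OTHER
        )
    if term not in {"synonymous_variant", "synonymous", "other"}:
        logger.warning("unmapped consequence term %r recorded as 'other'", raw_consequence)
    return ConsequenceClass.OTHER


def is_ptv(variant: AnnotatedVariant) -> bool:
    """True for protein-truncating classes: frameshift, stop gain, splice."""
    return variant.consequence_class in _PTV_CLASSES


def _matched_maf(variant: AnnotatedVariant, population: str | Sequence[str]) -> float:
    """Reference MAF for the matched population(s).

    With several populations the maximum MAF is used, which is the
    conservative choice for a rarity test.
    """
    if isinstance(population, str):
        return variant.maf(population)
    if not population:
        raise ConfigurationError("no reference population configured")
    return max(variant.maf(pop) for pop in population)


def classify_mutation(
    variant: AnnotatedVariant,
    call: GenotypeCall,
    population: str | Sequence[str],
    maf_threshold: float = MAF_THRESHOLD,
) -> MutationCall | None:
    """Apply the three-part mutation definition to one genotyped variant.

    Assumes the call already passed :func:`quality_filter` and that the
    variant's consequence class is assigned. Returns ``None`` when no rule
    fires. Rarity (MAF < ``maf_threshold`` in the matched population) is
    required by every rule, including the in-vitro override.
    """
    maf = _matched_maf(variant, population)
    if maf >= maf_threshold:
        return None
    ptv = is_ptv(variant)
    if variant.invitro_lof:
        rule = MutationRule.INVITRO_LOF
    elif ptv:
        rule = MutationRule.RARE_PTV
    elif variant.consequence_class is ConsequenceClass.MISSENSE and (
        variant.predictor_a is Verdict.DAMAGING
        or variant.predictor_b is Verdict.DAMAGING
    ):
        rule = MutationRule.RARE_DAMAGING_MISSENSE
    else:
        return None
    return MutationCall(
        proband_id=call.proband_id,
        variant_id=variant.variant_id,
        gene_symbol=variant.gene_symbol,
        rule_fired=rule,
        is_ptv=ptv,
        zygosity=call.zygosity,
        consequence_class=variant.consequence_class,
        reference_maf=maf,
    )


@dataclass
class FilterTally:
    """Dropout accounting across the cascade."""

    n_calls: int = 0
    dropped_gq: int = 0
    dropped_missing_gq: int = 0
    dropped_non_panel_gene: int = 0
    dropped_consequence: int = 0
    dropped_not_rare: int = 0
    dropped_no_rule: int = 0
    splice_no_context: int = 0
    splice_rejected: int = 0
    splice_retained: int = 0
    n_mutations: int = 0

    def summary(self) -> str:
        parts = [f"{k}={v}" for k, v in vars(self).items()]
        return ", ".join(parts)


def classify_cohort(
    variants: list[AnnotatedVariant],
    calls: list[GenotypeCall],
    probands: list[Proband],
    panel: list[GenePanelEntry],
    populations: dict[str, str | Sequence[str]],
    gq_min: float = GQ_MIN,
    maf_threshold: float = MAF_THRESHOLD,
    splice_contexts: dict[str, SpliceSiteContext] | None = None,
    scorer: PWMScorer | None = None,
    splice_delta_threshold: float = 0.20,
) -> tuple[list[MutationCall], FilterTally]:
    """Run the whole cascade over a cohort and return its mutation calls.

    ``populations`` maps group labels (e.g. ``"KS"``) to the matched
    reference population key(s) used for the rarity test; every group in
    the manifest must be covered or a :class:`ConfigurationError` is raised.
    ``splice_contexts`` maps variant_id to a :class:`SpliceSiteContext` for
    intronic candidates.
    """
    group_of = {p.proband_id: p.group.value for p in probands}
    for group in sorted({g for g in group_of.values()}):
        if group not in populations:
            raise ConfigurationError(
                f"no reference population configured for group {group}"
            )
    panel_genes = {e.gene_symbol for e in panel}
    by_id: dict[str, AnnotatedVariant] = {}
    tally = FilterTally()
    splice_contexts = splice_contexts or {}

    for variant in variants:
        if variant.gene_symbol not in panel_genes:
            continue
        if is_intronic(variant.raw_consequence):
            context = splice_contexts.get(variant.variant_id)
            if context is None:
                tally.splice_no_context += 1
                variant.consequence_class = ConsequenceClass.OTHER
            elif scorer is None:
                raise ConfigurationError(
                    "splice contexts supplied but no scorer configured"
                )
            else:
                retained = passes_splice_filter(
                    variant, context, scorer, delta_threshold=splice_delta_threshold
                )
                if retained:
                    tally.splice_retained += 1
                else:
                    tally.splice_rejected += 1
                    variant.consequence_class = ConsequenceClass.OTHER
        else:
            variant.consequence_class = consequence_class(variant.raw_consequence)
        by_id[variant.variant_id] = variant

    mutations: list[MutationCall] = []
    for call in calls:
        tally.n_calls += 1
        variant = by_id.get(call.variant_id)
        if variant is None:
            tally.dropped_non_panel_gene += 1
            continue
        if call.proband_id not in group_of:
            raise ConfigurationError(
                f"proband {call.proband_id} has genotypes but is absent "
                "from the manifest"
            )
        if call.genotype_quality is None:
            tally.dropped_missing_gq += 1
            continue
        if not quality_filter(call, gq_min):
            tally.dropped_gq += 1
            continue
        if variant.consequence_class is ConsequenceClass.OTHER:
            tally.dropped_consequence += 1
            continue
        population = populations[group_of[call.proband_id]]
        mutation = classify_mutation(variant, call, population, maf_threshold)
        if mutation is None:
            if _matched_maf(variant, population) >= maf_threshold:
                tally.dropped_not_rare += 1
            else:
                tally.dropped_no_rule += 1
            continue
        mutations.append(mutation)
    tally.n_mutations = len(mutations)
    logger.info("classification cascade: %s", tally.summary())
    return mutations, tally


_MUTATION_COLUMNS = [
    "proband_id",
    "gene",
    "variant_id",
    "consequence_class",
    "rule_fired",
    "zygosity",
    "reference_maf",
    "is_ptv",
]


def write_mutations(mutations: Sequence[MutationCall], path: str) -> None:
    """Write classified mutation calls to mutations.tsv."""
    import pandas as pd

    rows = [
        {
            "proband_id": m.proband_id,
            "gene": m.gene_symbol,
            "variant_id": m.variant_id,
            "consequence_class": m.consequence_class.value,
            "rule_fired": m.rule_fired.value,
            "zygosity": m.zygosity.value,
            "reference_maf": repr(m.reference_maf),
            "is_ptv": str(m.is_ptv).lower(),
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=_MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutations(path: str) -> list[MutationCall]:
    import pandas as pd

    from .model import Zygosity

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        MutationCall(
            proband_id=str(row.proband_id),
            variant_id=str(row.variant_id),
            gene_symbol=str(row.gene),
            rule_fired=MutationRule(str(row.rule_fired)),
            is_ptv=str(row.is_ptv).lower() == "true",
            zygosity=Zygosity(str(row.zygosity)),
            consequence_class=ConsequenceClass(str(row.consequence_class)),
            reference_maf=float(row.reference_maf),
        )
        for row in df.itertuples(index=False)
    ]


def private_fraction(
    mutations: Sequence[MutationCall],
    reference: ReferenceCountTable,
    population: str,
) -> float:
    """Fraction of distinct mutated variants absent from the reference.

    Deduplicates by variant id (a variant carried by several probands
    counts once); a variant with zero reference alternate alleles in
    ``population`` is private.
    """
    variant_ids = sorted({m.variant_id for m in mutations})
    if not variant_ids:
        raise ValueError("private fraction undefined for an empty mutation set")
    n_private = sum(
        1 for vid in variant_ids if reference.lookup(vid, population)[0] == 0
    )
    return n_private / len(variant_ids)
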