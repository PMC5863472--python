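"""Shared data model for gene-panel rare-variant cohort analysis.

The central objects mirror the stages of the analysis: annotated variants
and genotype calls come in, mutation calls (variants surviving the rarity /
consequence / prediction cascade) come out of classification, and per-gene
allelic states plus per-proband architectures summarise them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class ChromosomeClass(str, enum.Enum):
    AUTOSOMAL = "autosomal"
    X = "X"


class InheritanceMode(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    X_LINKED = "x_linked"
    UNKNOWN = "unknown"


class PhenotypeAssociation(str, enum.Enum):
    KS = "KS"
    NCHH = "nCHH"
    BOTH = "both"
    CDGP_CANDIDATE = "CDGP_candidate"


class Group(str, enum.Enum):
    KS = "KS"
    NCHH = "nCHH"
    CDGP = "CDGP"
    CONTROL = "CONTROL"


#: Groups pooled into the combined hypogonadotropic-hypogonadism case set.
CHH_GROUPS = (Group.KS, Group.NCHH)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class ConsequenceClass(str, enum.Enum):
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    SPLICE_CANDIDATE = "splice_candidate"
    OTHER = "other"


class Verdict(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class MutationRule(str, enum.Enum):
    """Which clause of the three-part mutation definition fired."""

    RARE_PTV = "rare_ptv"
    RARE_DAMAGING_MISSENSE = "rare_damaging_missense"
    INVITRO_LOF = "invitro_lof"


class GeneStateClass(str, enum.Enum):
    NONE = "none"
    MONOALLELIC = "monoallelic"
    BIALLELIC = "biallelic"


class Architecture(str, enum.Enum):
    NONE = "none"
    MONOGENIC = "monogenic"
    OLIGOGENIC = "oligogenic"


class ValidationError(ValueError):
    """An input table violated a data-model invariant."""


class FormatError(ValueError):
    """An input file was structurally malformed (missing columns etc.)."""


@dataclass(frozen=True)
class GenePanelEntry:
    gene_symbol: str
    chromosome_class: ChromosomeClass
    inheritance_mode: InheritanceMode
    phenotype_association: PhenotypeAssociation
    pli: float | None = None

    def __post_init__(self) -> None:
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValidationError(
                f"pLI for {self.gene_symbol} must be in [0,1], got {self.pli}"
            )


@dataclass
class AnnotatedVariant:
    """One alternate allele at a site, with its annotations.

    ``reference_maf`` / ``reference_alt_count`` map population labels (e.g.
    ``NFE``, ``FIN``) to frequencies / counts; a population absent from the
    map is treated as zero observed alleles (the variant is private there).
    """

    variant_id: str
    gene_symbol: str
    raw_consequence: str
    consequence_class: ConsequenceClass = ConsequenceClass.OTHER
    reference_maf: dict[str, float] = field(default_factory=dict)
    reference_alt_count: dict[str, int] = field(default_factory=dict)
    predictor_a: Verdict = Verdict.MISSING
    predictor_b: Verdict = Verdict.MISSING
    invitro_lof: bool = False
    exon_boundary_distance: int | None = None
    splice_delta: float | None = None

    def __post_init__(self) -> None:
        for pop, maf in self.reference_maf.items():
            if not (0.0 <= maf <= 1.0):
                raise ValidationError(
                    f"{self.variant_id}: MAF for {pop} out of [0,1]: {maf}"
                )
        for pop, count in self.reference_alt_count.items():
            if count < 0:
                raise ValidationError(
                    f"{self.variant_id}: negative alt count for {pop}"
                )

    def maf(self, population: str) -> float:
        """Reference MAF in ``population``; absent means unobserved (0)."""
        return self.reference_maf.get(population, 0.0)


@dataclass(frozen=True)
class GenotypeCall:
    proband_id: str
    variant_id: str
    zygosity: Zygosity
    genotype_quality: float | None = None

    def __post_init__(self) -> None:
        if self.genotype_quality is not None and self.genotype_quality < 0:
            raise ValidationError(
                f"{self.proband_id}/{self.variant_id}: negative GQ"
            )


@dataclass(frozen=True)
class Proband:
    proband_id: str
    group: Group
    sex: Sex

    @property
    def is_chh(self) -> bool:
        return self.group in CHH_GROUPS


@dataclass(frozen=True)
class ReferenceCountRecord:
    """Alt-allele tally for one key (gene or variant) in one population.

    ``alleles_inspected`` may be fractional: aggregated references report
    the average number of alleles genotyped across the sites of a gene.
    """

    key: str
    population: str
    alt_allele_count: int
    alleles_inspected: float

    def __post_init__(self) -> None:
        if self.alt_allele_count < 0:
            raise ValidationError(f"{self.key}: negative alt allele count")
        if self.alleles_inspected <= 0:
            raise ValidationError(f"{self.key}: alleles_inspected must be > 0")
        if self.alt_allele_count > self.alleles_inspected:
            raise ValidationError(
                f"{self.key}/{self.population}: alt count "
                f"{self.alt_allele_count} exceeds alleles inspected "
                f"{self.alleles_inspected}"
            )


@dataclass(frozen=True)
class MutationCall:
    """A variant-proband pair that passed the mutation definition."""

    proband_id: str
    variant_id: str
    gene_symbol: str
    rule_fired: MutationRule
    is_ptv: bool
    zygosity: Zygosity
    consequence_class: ConsequenceClass = ConsequenceClass.OTHER
    reference_maf: float = 0.0

    def __post_init__(self) -> None:
        if self.rule_fired is MutationRule.RARE_PTV and not self.is_ptv:
            raise ValidationError(
                f"{self.variant_id}: rare_ptv rule requires a PTV consequence"
            )

    @property
    def allele_count(self) -> int:
        """Mutated alleles this call contributes (hom counts twice)."""
        return 2 if self.zygosity is Zygosity.HOM else 1


@dataclass(frozen=True)
class GeneState:
    proband_id: str
    gene_symbol: str
    state: GeneStateClass
    n_mutations: int

    def __post_init__(self) -> None:
        if (self.state is GeneStateClass.NONE) != (self.n_mutations == 0):
            raise ValidationError(
                f"{self.proband_id}/{self.gene_symbol}: state "
                f"{self.state.value} inconsistent with {self.n_mutations} calls"
            )


@dataclass(frozen=True)
class ProbandArchitecture:
    proband_id: str
    group: Group
    mutated_genes: frozenset[str]
    architecture: Architecture

    def __post_init__(self) -> None:
        n = len(self.mutated_genes)
        expected = (
            Architecture.NONE
            if n == 0
            else Architecture.MONOGENIC
            if n == 1
            else Architecture.OLIGOGENIC
        )
        if self.architecture is not expected:
            raise ValidationError(
                f"{self.proband_id}: {n} mutated genes cannot be "
                f"{self.architecture.value}"
            )
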