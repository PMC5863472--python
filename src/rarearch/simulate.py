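"""Synthetic cohort generator with truth labels for parameter recovery.

The generator emulates a gene-panel rare-variant study: per proband, each
panel gene mutates with a configurable carrier frequency; once one gene is
mutated, further genes mutate with probability ``min(1, rho * f_g)``
(``rho = 1`` recovers independence, larger values couple genes and raise
the oligogenic fraction). Recessive genes emit biallelic genotypes
(homozygous, or two heterozygous variants presumed compound het), dominant
genes emit a single het, X-linked genes emit a hemizygous call in males.
Every emitted causal variant receives a consequence (protein-truncating
with probability ``fraction_ptv``, else missense), a reference MAF drawn
from a rare spectrum, predictor verdicts, and a genotype quality; benign
background variants exercise the rarity and predictor filters.

The probability that a proband carries no mutated gene is
``prod_g (1 - f_g)`` regardless of ``rho`` (the coupling only applies
after a first event), so carrier prevalence and oligogenic fraction are
separately tunable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from statsmodels.stats.proportion import proportion_confint

from .model import (
    AnnotatedVariant,
    Architecture,
    ChromosomeClass,
    GenePanelEntry,
    GenotypeCall,
    Group,
    InheritanceMode,
    MutationCall,
    MutationRule,
    Proband,
    Sex,
    Verdict,
    Zygosity,
)
from .panel_io import ReferenceCountRecord, ReferenceCountTable, default_panel


@dataclass
class MafSpectrum:
    """Reference-MAF distribution: a point mass at 0 (private variants)
    plus a Beta tail scaled below ``max_maf``, so a 1% rarity filter sees
    variants on both sides."""

    private_mass: float = 0.5
    beta_a: float = 0.5
    beta_b: float = 3.0
    max_maf: float = 0.025

    def draw(self, rng: np.random.Generator) -> float:
        if rng.random() < self.private_mass:
            return 0.0
        return float(rng.beta(self.beta_a, self.beta_b) * self.max_maf)

    def draw_rare(self, rng: np.random.Generator, threshold: float = 0.01) -> float:
        """Draw from the spectrum conditioned on MAF < ``threshold``."""
        for _ in range(1000):
            maf = self.draw(rng)
            if maf < threshold:
                return maf
        return 0.0


@dataclass
class GeneSimConfig:
    symbol: str
    chromosome_class: ChromosomeClass = ChromosomeClass.AUTOSOMAL
    inheritance_mode: InheritanceMode = InheritanceMode.DOMINANT
    #: Carrier frequency per group label, or one value for all groups.
    carrier_frequency: float | dict[str, float] = 0.0
    fraction_ptv: float = 0.3
    #: Reference-population mutated-allele frequency (for simulate_reference).
    control_allele_frequency: float | None = None

    def f_of(self, group: str) -> float:
        if isinstance(self.carrier_frequency, dict):
            return self.carrier_frequency.get(group, 0.0)
        return self.carrier_frequency


@dataclass
class SimulationConfig:
    seed: int
    n_probands: dict[str, int]
    genes: list[GeneSimConfig]
    oligogenic_coupling: float = 1.0
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    #: P(damaging verdict) per predictor for causal missense variants.
    predictor_damaging_rate: float = 1.0
    #: P(damaging verdict) per predictor for benign background variants.
    benign_damaging_rate: float = 0.05
    #: Expected benign background variants per proband (Poisson).
    background_rate: float = 0.0
    gq_mean: float = 90.0
    gq_sd: float = 8.0
    #: Male fraction per group (2:1 male:female typical of CHH cohorts).
    male_fraction: dict[str, float] = field(default_factory=dict)
    reference_population: str = "NFE"
    reference_alleles: float = 66740.0
    maf_threshold: float = 0.01

    def __post_init__(self) -> None:
        for gene in self.genes:
            for group in self.n_probands:
                f = gene.f_of(group)
                if not (0.0 <= f <= 1.0):
                    raise ValueError(f"{gene.symbol}: carrier frequency {f} not in [0,1]")
                if self.oligogenic_coupling * f > 1.0 + 1e-12:
                    raise ValueError(
                        f"{gene.symbol}: rho * f = "
                        f"{self.oligogenic_coupling * f:.3f} exceeds 1"
                    )
        if self.oligogenic_coupling < 1.0:
            raise ValueError("oligogenic coupling rho must be >= 1")

    def male_fraction_of(self, group: str) -> float:
        return self.male_fraction.get(group, 0.5)

    def panel(self) -> list[GenePanelEntry]:
        from .model import PhenotypeAssociation

        return [
            GenePanelEntry(
                gene_symbol=g.symbol,
                chromosome_class=g.chromosome_class,
                inheritance_mode=g.inheritance_mode,
                phenotype_association=PhenotypeAssociation.BOTH,
            )
            for g in self.genes
        ]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_config_to_plain(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["genes"] = [
            GeneSimConfig(
                symbol=g["symbol"],
                chromosome_class=ChromosomeClass(g.get("chromosome_class", "autosomal")),
                inheritance_mode=InheritanceMode(g.get("inheritance_mode", "dominant")),
                carrier_frequency=g.get("carrier_frequency", 0.0),
                fraction_ptv=g.get("fraction_ptv", 0.3),
                control_allele_frequency=g.get("control_allele_frequency"),
            )
            for g in raw["genes"]
        ]
        if "maf_spectrum" in raw:
            raw["maf_spectrum"] = MafSpectrum(**raw["maf_spectrum"])
        return cls(**raw)


def _config_to_plain(config: SimulationConfig) -> dict:
    plain = asdict(config)
    for gene in plain["genes"]:
        gene["chromosome_class"] = gene["chromosome_class"].value
        gene["inheritance_mode"] = gene["inheritance_mode"].value
    return plain


@dataclass
class TruthRecord:
    """Generating truth for one simulated cohort."""

    mutations: list[MutationCall]
    architectures: dict[str, Architecture]
    carrier_frequency: dict[tuple[str, str], float]  # (group, gene) -> f
    carriers: dict[tuple[str, str], int]  # (group, gene) -> carrier count


@dataclass
class SimulatedCohort:
    variants: list[AnnotatedVariant]
    genotypes: list[GenotypeCall]
    probands: list[Proband]
    truth: TruthRecord
    panel: list[GenePanelEntry]


_BENIGN_CONSEQUENCES = ("missense_variant", "synonymous_variant")


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    pop = config.reference_population
    variants: list[AnnotatedVariant] = []
    genotypes: list[GenotypeCall] = []
    probands: list[Proband] = []
    truth_mutations: list[MutationCall] = []
    architectures: dict[str, Architecture] = {}
    carrier_frequency: dict[tuple[str, str], float] = {}
    carriers: dict[tuple[str, str], int] = {
        (group, g.symbol): 0 for group in config.n_probands for g in config.genes
    }
    for group in config.n_probands:
        for g in config.genes:
            carrier_frequency[(group, g.symbol)] = g.f_of(group)

    counter = 0

    def new_variant_id() -> str:
        nonlocal counter
        counter += 1
        return f"chrS:{counter}:A:G"

    def draw_gq() -> float:
        return float(np.clip(rng.normal(config.gq_mean, config.gq_sd), 0.0, 99.0))

    for group, n in config.n_probands.items():
        male_frac = config.male_fraction_of(group)
        for i in range(n):
            pid = f"{group}_{i:04d}"
            sex = Sex.MALE if rng.random() < male_frac else Sex.FEMALE
            probands.append(Proband(pid, Group(group), sex))
            mutated_genes: list[GeneSimConfig] = []
            for g in config.genes:
                f = g.f_of(group)
                p = f if not mutated_genes else min(1.0, config.oligogenic_coupling * f)
                if rng.random() < p:
                    mutated_genes.append(g)
            n_mut = len(mutated_genes)
            architectures[pid] = (
                Architecture.NONE
                if n_mut == 0
                else Architecture.MONOGENIC
                if n_mut == 1
                else Architecture.OLIGOGENIC
            )
            for g in mutated_genes:
                carriers[(group, g.symbol)] += 1
                _emit_causal(
                    config, rng, g, pid, sex, pop,
                    variants, genotypes, truth_mutations,
                    new_variant_id, draw_gq,
                )
            if config.background_rate > 0:
                for _ in range(rng.poisson(config.background_rate)):
                    _emit_background(
                        config, rng, pid, pop,
                        variants, genotypes, new_variant_id, draw_gq,
                    )
    truth = TruthRecord(
        mutations=truth_mutations,
        architectures=architectures,
        carrier_frequency=carrier_frequency,
        carriers=carriers,
    )
    return SimulatedCohort(variants, genotypes, probands, truth, config.panel())


def _draw_consequence(
    config: SimulationConfig, rng: np.random.Generator, g: GeneSimConfig
) -> tuple[str, bool]:
    if rng.random() < g.fraction_ptv:
        raw = "stop_gained" if rng.random() < 0.5 else "frameshift_variant"
        return raw, True
    return "missense_variant", False


def _make_causal_variant(
    config: SimulationConfig,
    rng: np.random.Generator,
    g: GeneSimConfig,
    pop: str,
    new_variant_id,
) -> tuple[AnnotatedVariant, bool]:
    raw, ptv = _draw_consequence(config, rng, g)
    maf = config.maf_spectrum.draw_rare(rng, config.maf_threshold)
    if ptv:
        pred_a = pred_b = Verdict.MISSING
    else:
        pred_a = (
            Verdict.DAMAGING
            if rng.random() < config.predictor_damaging_rate
            else Verdict.TOLERATED
        )
        pred_b = (
            Verdict.DAMAGING
            if rng.random() < config.predictor_damaging_rate
            else Verdict.TOLERATED
        )
    variant = AnnotatedVariant(
        variant_id=new_variant_id(),
        gene_symbol=g.symbol,
        raw_consequence=raw,
        reference_maf={pop: maf},
        reference_alt_count={pop: int(round(maf * config.reference_alleles))},
    )
    variant.predictor_a = pred_a
    variant.predictor_b = pred_b
    return variant, ptv


def _emit_causal(
    config, rng, g, pid, sex, pop,
    variants, genotypes, truth_mutations, new_variant_id, draw_gq,
) -> None:
    if g.inheritance_mode is InheritanceMode.RECESSIVE:
        if rng.random() < 0.5:
            zygosities = [Zygosity.HOM]
        else:
            zygosities = [Zygosity.HET, Zygosity.HET]
    elif g.inheritance_mode is InheritanceMode.X_LINKED:
        zygosities = [Zygosity.HEMI if sex is Sex.MALE else Zygosity.HET]
    else:
        zygosities = [Zygosity.HET]
    for zygosity in zygosities:
        variant, ptv = _make_causal_variant(config, rng, g, pop, new_variant_id)
        variants.append(variant)
        genotypes.append(
            GenotypeCall(
                proband_id=pid,
                variant_id=variant.variant_id,
                zygosity=zygosity,
                genotype_quality=draw_gq(),
            )
        )
        truth_mutations.append(
            MutationCall(
                proband_id=pid,
                variant_id=variant.variant_id,
                gene_symbol=g.symbol,
                rule_fired=(
                    MutationRule.RARE_PTV if ptv else MutationRule.RARE_DAMAGING_MISSENSE
                ),
                is_ptv=ptv,
                zygosity=zygosity,
                reference_maf=variant.maf(pop),
            )
        )


def _emit_background(
    config, rng, pid, pop, variants, genotypes, new_variant_id, draw_gq
) -> None:
    g = config.genes[rng.integers(len(config.genes))]
    raw = _BENIGN_CONSEQUENCES[0] if rng.random() < 0.7 else _BENIGN_CONSEQUENCES[1]
    maf = config.maf_spectrum.draw(rng)
    variant = AnnotatedVariant(
        variant_id=new_variant_id(),
        gene_symbol=g.symbol,
        raw_consequence=raw,
        reference_maf={pop: maf},
        reference_alt_count={pop: int(round(maf * config.reference_alleles))},
    )
    variant.predictor_a = (
        Verdict.DAMAGING if rng.random() < config.benign_damaging_rate else Verdict.TOLERATED
    )
    variant.predictor_b = (
        Verdict.DAMAGING if rng.random() < config.benign_damaging_rate else Verdict.TOLERATED
    )
    variants.append(variant)
    genotypes.append(
        GenotypeCall(
            proband_id=pid,
            variant_id=variant.variant_id,
            zygosity=Zygosity.HET,
            genotype_quality=draw_gq(),
        )
    )


def simulate_reference(config: SimulationConfig) -> ReferenceCountTable:
    """Binomial reference-population allele counts, one row per gene.

    Uses each gene's ``control_allele_frequency`` (default: half the
    CONTROL-group carrier frequency, i.e. heterozygous carriers).
    """
    rng = np.random.default_rng(config.seed + 1)
    table = ReferenceCountTable()
    alleles = config.reference_alleles
    for g in config.genes:
        freq = g.control_allele_frequency
        if freq is None:
            freq = g.f_of("CONTROL") / 2.0
        count = int(rng.binomial(int(round(alleles)), freq))
        table.add(
            ReferenceCountRecord(
                key=g.symbol,
                population=config.reference_population,
                alt_allele_count=count,
                alleles_inspected=alleles,
            )
        )
    table.finalize_defaults()
    return table


def expected_architecture_fractions(
    frequencies: list[float], rho: float = 1.0
) -> tuple[float, float, float]:
    """Exact (none, monogenic, oligogenic) probabilities under the
    sequential coupling model, for one group."""
    p_none = math.prod(1.0 - f for f in frequencies)
    p_mono = 0.0
    for i, f in enumerate(frequencies):
        before = math.prod(1.0 - frequencies[j] for j in range(i))
        after = math.prod(
            1.0 - min(1.0, rho * frequencies[j])
            for j in range(i + 1, len(frequencies))
        )
        p_mono += before * f * after
    return p_none, p_mono, 1.0 - p_none - p_mono


def scale_frequencies(weights: list[float], target_carrier_rate: float) -> list[float]:
    """Scale a weight vector so ``1 - prod(1 - s*w_g)`` hits the target."""
    from scipy.optimize import brentq

    if not (0.0 <= target_carrier_rate < 1.0):
        raise ValueError("target carrier rate must be in [0,1)")
    if target_carrier_rate == 0.0 or all(w == 0 for w in weights):
        return [0.0 for _ in weights]

    def gap(s: float) -> float:
        return 1.0 - math.prod(1.0 - min(1.0, s * w) for w in weights) - target_carrier_rate

    upper = 1.0 / max(weights)
    s = brentq(gap, 0.0, upper)
    return [min(1.0, s * w) for w in weights]


# Per-gene weights for the default study emulation: approximate relative
# carrier frequencies in GnRH-deficiency cases (major genes FGFR1 / CHD7 /
# IGSF10 dominate; five panel genes unmutated in cases).
_CASE_GENE_WEIGHTS: dict[str, float] = {
    "ANOS1": 1.5, "SEMA3A": 2.6, "FGF8": 1.8, "FGF17": 0.8, "SOX10": 4.4,
    "IL17RD": 2.6, "AXL": 3.4, "FGFR1": 15.6, "CHD7": 13.8, "HS6ST1": 1.8,
    "PCSK1": 0.0, "LEP": 0.0, "LEPR": 0.0, "FEZF1": 0.0, "NSMF": 0.0,
    "PROKR2": 3.0, "WDR11": 1.8, "PROK2": 0.9, "GNRH1": 1.3, "GNRHR": 3.0,
    "KISS1": 0.9, "KISS1R": 0.4, "TAC3": 0.4, "TACR3": 2.2, "IGSF10": 16.4,
}

#: Cohort-level carrier prevalences the default configuration targets.
STUDY_CARRIER_RATES = {"KS": 0.51, "nCHH": 0.51, "CDGP": 5 / 72, "CONTROL": 72 / 405}
STUDY_GROUP_SIZES = {"KS": 61, "nCHH": 55, "CDGP": 72, "CONTROL": 405}


def study_config(seed: int) -> SimulationConfig:
    """Default configuration emulating the study cohorts.

    Group sizes 61 KS / 55 nCHH / 72 delayed-puberty / 405 population
    controls; 2:1 male:female in the case groups; per-gene carrier
    frequencies scaled so the expected cohort carrier prevalences match
    the observed 51% / 7% / 18%; independence between genes (rho = 1),
    under which the expected oligogenic fraction in cases is already ~15%.
    """
    panel = default_panel()
    weights = [_CASE_GENE_WEIGHTS[e.gene_symbol] for e in panel]
    uniform = [1.0] * len(panel)
    per_group: dict[str, list[float]] = {}
    for group, rate in STUDY_CARRIER_RATES.items():
        w = weights if group in ("KS", "nCHH") else uniform
        per_group[group] = scale_frequencies(w, rate)
    genes = []
    for i, entry in enumerate(panel):
        genes.append(
            GeneSimConfig(
                symbol=entry.gene_symbol,
                chromosome_class=entry.chromosome_class,
                inheritance_mode=entry.inheritance_mode,
                carrier_frequency={
                    group: per_group[group][i] for group in STUDY_CARRIER_RATES
                },
                fraction_ptv=0.29,
            )
        )
    return SimulationConfig(
        seed=seed,
        n_probands=dict(STUDY_GROUP_SIZES),
        genes=genes,
        oligogenic_coupling=1.0,
        male_fraction={"KS": 2 / 3, "nCHH": 2 / 3, "CDGP": 0.5, "CONTROL": 0.5},
        # Background variants exercise the rarity/consequence filters; their
        # predictor verdicts stay clean so the expected classified-carrier
        # prevalence equals the configured per-gene rates.
        background_rate=0.5,
        benign_damaging_rate=0.0,
    )


@dataclass
class GeneRecovery:
    group: str
    gene_symbol: str
    f_true: float
    n: int
    carriers: int
    f_hat: float
    ci_low: float
    ci_high: float
    covered: bool


@dataclass
class RecoveryReport:
    per_gene: list[GeneRecovery]
    coverage: float
    concordance: float

    def __str__(self) -> str:
        return (
            f"RecoveryReport(coverage={self.coverage:.3f}, "
            f"concordance={self.concordance:.3f}, "
            f"n_cells={len(self.per_gene)})"
        )


def recover_parameters(
    truth: TruthRecord,
    observed_mutations: list[MutationCall],
    probands: list[Proband],
    ci_alpha: float = 0.05,
) -> RecoveryReport:
    """Compare classifier output against the generating truth.

    Per (group, gene): the estimated carrier frequency (observed carriers
    over group size) with a Clopper-Pearson ``1 - ci_alpha`` interval, and
    whether it covers the generating frequency. ``concordance`` is the
    Jaccard agreement between the truth and observed (proband, variant)
    mutation sets.
    """
    observed_pids = {m.proband_id for m in observed_mutations}
    truth_pids = {m.proband_id for m in truth.mutations}
    known = {p.proband_id for p in probands}
    stray = (observed_pids | truth_pids) - known
    if stray:
        raise ValueError(f"mutations for unknown probands: {sorted(stray)}")

    group_of = {p.proband_id: p.group.value for p in probands}
    group_sizes: dict[str, int] = {}
    for p in probands:
        group_sizes[p.group.value] = group_sizes.get(p.group.value, 0) + 1
    observed_carriers: dict[tuple[str, str], set[str]] = {}
    for m in observed_mutations:
        key = (group_of[m.proband_id], m.gene_symbol)
        observed_carriers.setdefault(key, set()).add(m.proband_id)

    per_gene: list[GeneRecovery] = []
    for (group, gene), f_true in sorted(truth.carrier_frequency.items()):
        n = group_sizes.get(group, 0)
        if n == 0:
            continue
        k = len(observed_carriers.get((group, gene), set()))
        low, high = proportion_confint(k, n, alpha=ci_alpha, method="beta")
        per_gene.append(
            GeneRecovery(
                group=group,
                gene_symbol=gene,
                f_true=f_true,
                n=n,
                carriers=k,
                f_hat=k / n,
                ci_low=float(low),
                ci_high=float(high),
                covered=bool(low <= f_true <= high),
            )
        )
    coverage = (
        sum(r.covered for r in per_gene) / len(per_gene) if per_gene else float("nan")
    )
    truth_pairs = {(m.proband_id, m.variant_id) for m in truth.mutations}
    observed_pairs = {(m.proband_id, m.variant_id) for m in observed_mutations}
    union = truth_pairs | observed_pairs
    concordance = len(truth_pairs & observed_pairs) / len(union) if union else 1.0
    return RecoveryReport(per_gene=per_gene, coverage=coverage, concordance=concordance)
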