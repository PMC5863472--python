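"""Readers and writers for panel, manifest, variant and reference tables.

All flat files are UTF-8, tab-delimited TSV with a header row. VCF ingestion
(4.2, via pysam) maps onto the same in-memory model as the flat dialect.
Coordinates are 1-based VCF-style; variant keys are ``chrom:pos:ref:alt``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .model import (
    AnnotatedVariant,
    ChromosomeClass,
    ConsequenceClass,
    FormatError,
    GenePanelEntry,
    GenotypeCall,
    Group,
    InheritanceMode,
    PhenotypeAssociation,
    Proband,
    ReferenceCountRecord,
    Sex,
    ValidationError,
    Verdict,
    Zygosity,
)

logger = logging.getLogger(__name__)

_PANEL_COLUMNS = ["gene", "chromosome_class", "inheritance_mode", "association"]
_MANIFEST_COLUMNS = ["proband_id", "group", "sex"]
_REFERENCE_COLUMNS = ["key", "population", "alt_allele_count", "alleles_inspected"]

# The default screening panel: genes with published loss-of-function
# evidence in GnRH deficiency, plus the IGSF10 delayed-puberty candidate.
# (symbol, chromosome class, inheritance mode, phenotype association)
_DEFAULT_PANEL: list[tuple[str, str, str, str]] = [
    ("ANOS1", "X", "x_linked", "KS"),
    ("SEMA3A", "autosomal", "dominant", "KS"),
    ("FGF8", "autosomal", "dominant", "both"),
    ("FGF17", "autosomal", "dominant", "both"),
    ("SOX10", "autosomal", "dominant", "KS"),
    ("IL17RD", "autosomal", "dominant", "KS"),
    ("AXL", "autosomal", "dominant", "both"),
    ("FGFR1", "autosomal", "dominant", "both"),
    ("CHD7", "autosomal", "dominant", "both"),
    ("HS6ST1", "autosomal", "dominant", "both"),
    ("PCSK1", "autosomal", "recessive", "nCHH"),
    ("LEP", "autosomal", "recessive", "nCHH"),
    ("LEPR", "autosomal", "recessive", "nCHH"),
    ("FEZF1", "autosomal", "recessive", "KS"),
    ("NSMF", "autosomal", "dominant", "KS"),
    ("PROKR2", "autosomal", "recessive", "both"),
    ("WDR11", "autosomal", "dominant", "both"),
    ("PROK2", "autosomal", "recessive", "both"),
    ("GNRH1", "autosomal", "recessive", "nCHH"),
    ("GNRHR", "autosomal", "recessive", "nCHH"),
    ("KISS1", "autosomal", "recessive", "nCHH"),
    ("KISS1R", "autosomal", "recessive", "nCHH"),
    ("TAC3", "autosomal", "recessive", "nCHH"),
    ("TACR3", "autosomal", "recessive", "nCHH"),
    ("IGSF10", "autosomal", "unknown", "CDGP_candidate"),
]


def default_panel() -> list[GenePanelEntry]:
    """The built-in 25-gene screening panel (24 GnRH-deficiency genes + IGSF10)."""
    return [
        GenePanelEntry(
            gene_symbol=g,
            chromosome_class=ChromosomeClass(c),
            inheritance_mode=InheritanceMode(m),
            phenotype_association=PhenotypeAssociation(a),
        )
        for g, c, m, a in _DEFAULT_PANEL
    ]


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_gene_panel(path: str) -> list[GenePanelEntry]:
    """Read a gene-panel TSV.

    Required columns: ``gene``, ``chromosome_class``, ``inheritance_mode``,
    ``association``; optional ``pli`` (blank = missing).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _PANEL_COLUMNS, str(path))
    entries: list[GenePanelEntry] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        gene = str(row.gene)
        if gene in seen:
            raise ValidationError(f"{path}: duplicate gene symbol {gene}")
        seen.add(gene)
        pli = None
        if "pli" in df.columns:
            raw = getattr(row, "pli")
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                text = str(raw).strip()
                if text:
                    pli = float(text)
        entries.append(
            GenePanelEntry(
                gene_symbol=gene,
                chromosome_class=ChromosomeClass(str(row.chromosome_class)),
                inheritance_mode=InheritanceMode(str(row.inheritance_mode)),
                phenotype_association=PhenotypeAssociation(str(row.association)),
                pli=pli,
            )
        )
    return entries


def write_gene_panel(entries: list[GenePanelEntry], path: str) -> None:
    df = pd.DataFrame(
        {
            "gene": [e.gene_symbol for e in entries],
            "chromosome_class": [e.chromosome_class.value for e in entries],
            "inheritance_mode": [e.inheritance_mode.value for e in entries],
            "association": [e.phenotype_association.value for e in entries],
            "pli": ["" if e.pli is None else repr(e.pli) for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> list[Proband]:
    """Read the cohort manifest TSV (proband_id, group, sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _MANIFEST_COLUMNS, str(path))
    probands: list[Proband] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        pid = str(row.proband_id)
        if pid in seen:
            raise ValidationError(f"{path}: duplicate proband id {pid}")
        seen.add(pid)
        probands.append(Proband(pid, Group(str(row.group)), Sex(str(row.sex))))
    return probands


def write_manifest(probands: list[Proband], path: str) -> None:
    pd.DataFrame(
        {
            "proband_id": [p.proband_id for p in probands],
            "group": [p.group.value for p in probands],
            "sex": [p.sex.value for p in probands],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ReferenceCountTable:
    """Keyed lookup of reference-population alt-allele tallies.

    A key absent from the table is treated as unobserved: zero alternate
    alleles out of the population's default number of alleles inspected
    (the mean over the table's rows for that population, unless overridden).
    """

    records: dict[tuple[str, str], ReferenceCountRecord] = field(default_factory=dict)
    default_alleles: dict[str, float] = field(default_factory=dict)

    def add(self, record: ReferenceCountRecord) -> None:
        self.records[(record.key, record.population)] = record

    def lookup(self, key: str, population: str) -> tuple[int, float]:
        """Return ``(alt_allele_count, alleles_inspected)`` for a key."""
        rec = self.records.get((key, population))
        if rec is not None:
            return rec.alt_allele_count, rec.alleles_inspected
        if population not in self.default_alleles:
            raise ValidationError(
                f"no reference rows or default alleles for population {population}"
            )
        return 0, self.default_alleles[population]

    def populations(self) -> set[str]:
        return {pop for _, pop in self.records} | set(self.default_alleles)

    def finalize_defaults(self) -> None:
        """Set each population's default alleles to its mean over rows."""
        sums: dict[str, list[float]] = {}
        for (_, pop), rec in self.records.items():
            sums.setdefault(pop, []).append(rec.alleles_inspected)
        for pop, values in sums.items():
            self.default_alleles.setdefault(pop, sum(values) / len(values))


def read_reference_counts(path: str) -> ReferenceCountTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _REFERENCE_COLUMNS, str(path))
    table = ReferenceCountTable()
    for row in df.itertuples(index=False):
        count = int(row.alt_allele_count)
        if count < 0:
            raise ValidationError(
                f"{path}: negative alt_allele_count for {row.key}/{row.population}"
            )
        table.add(
            ReferenceCountRecord(
                key=str(row.key),
                population=str(row.population),
                alt_allele_count=count,
                alleles_inspected=float(row.alleles_inspected),
            )
        )
    table.finalize_defaults()
    return table


def write_reference_counts(table: ReferenceCountTable, path: str) -> None:
    rows = [
        {
            "key": rec.key,
            "population": rec.population,
            "alt_allele_count": rec.alt_allele_count,
            "alleles_inspected": repr(rec.alleles_inspected),
        }
        for rec in table.records.values()
    ]
    pd.DataFrame(rows, columns=_REFERENCE_COLUMNS).to_csv(path, sep="\t", index=False)


_VARIANT_COLUMNS = [
    "proband_id",
    "variant_id",
    "gene_symbol",
    "raw_consequence",
    "zygosity",
    "genotype_quality",
]


def _parse_verdict(value: object) -> Verdict:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return Verdict.MISSING
    text = str(value).strip()
    return Verdict(text) if text else Verdict.MISSING


def _parse_optional_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return float(text) if text else None


def read_variant_table(
    path: str, dialect: str = "tsv"
) -> tuple[list[AnnotatedVariant], list[GenotypeCall], int]:
    """Read an annotated variant table.

    ``dialect='tsv'``: one row per (proband, alt allele). Required columns
    as in :data:`_VARIANT_COLUMNS`; optional ``predictor_a``, ``predictor_b``,
    ``invitro_lof``, ``exon_boundary_distance``, ``splice_delta`` and any
    number of ``maf_<POP>`` / ``ac_<POP>`` reference columns.

    ``dialect='vcf'``: a VCF 4.2 file whose INFO carries ``GENE``, ``CONS``
    and optionally ``PRED_A``, ``PRED_B``, ``INVITRO``, ``EXDIST``,
    ``MAF_<POP>``, ``AC_<POP>``; genotypes come from the sample columns.

    Returns ``(variants, genotype_calls, n_skipped)`` where ``n_skipped``
    counts malformed genotype records that were dropped with a warning.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown variant-table dialect: {dialect!r}")


def _read_variant_tsv(
    path: str,
) -> tuple[list[AnnotatedVariant], list[GenotypeCall], int]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _VARIANT_COLUMNS, str(path))
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    ac_cols = [c for c in df.columns if c.startswith("ac_")]

    variants: dict[str, AnnotatedVariant] = {}
    calls: list[GenotypeCall] = []
    seen_pairs: set[tuple[str, str]] = set()
    n_skipped = 0
    for row in df.itertuples(index=False):
        vid = str(row.variant_id)
        if vid not in variants:
            reference_maf = {}
            for col in maf_cols:
                value = _parse_optional_float(getattr(row, col))
                if value is not None:
                    reference_maf[col[4:]] = value
            reference_ac = {}
            for col in ac_cols:
                value = _parse_optional_float(getattr(row, col))
                if value is not None:
                    reference_ac[col[3:]] = int(value)
            dist = getattr(row, "exon_boundary_distance", None)
            dist_value = _parse_optional_float(dist)
            variants[vid] = AnnotatedVariant(
                variant_id=vid,
                gene_symbol=str(row.gene_symbol),
                raw_consequence=str(row.raw_consequence),
                reference_maf=reference_maf,
                reference_alt_count=reference_ac,
                predictor_a=_parse_verdict(getattr(row, "predictor_a", None)),
                predictor_b=_parse_verdict(getattr(row, "predictor_b", None)),
                invitro_lof=str(getattr(row, "invitro_lof", "")).strip().lower()
                in {"true", "1", "yes"},
                exon_boundary_distance=(
                    None if dist_value is None else int(dist_value)
                ),
                splice_delta=_parse_optional_float(getattr(row, "splice_delta", None)),
            )
        try:
            zygosity = Zygosity(str(row.zygosity))
        except ValueError:
            logger.warning("%s: bad zygosity %r, record skipped", path, row.zygosity)
            n_skipped += 1
            continue
        pid = str(row.proband_id)
        if (pid, vid) in seen_pairs:
            raise ValidationError(f"{path}: duplicate genotype for ({pid}, {vid})")
        seen_pairs.add((pid, vid))
        calls.append(
            GenotypeCall(
                proband_id=pid,
                variant_id=vid,
                zygosity=zygosity,
                genotype_quality=_parse_optional_float(row.genotype_quality),
            )
        )
    return list(variants.values()), calls, n_skipped


def _read_variant_vcf(
    path: str,
) -> tuple[list[AnnotatedVariant], list[GenotypeCall], int]:
    import pysam

    variants: list[AnnotatedVariant] = []
    calls: list[GenotypeCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = dict(rec.info)
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                vid = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                reference_maf = {
                    key[4:]: float(_scalar(value, alt_index))
                    for key, value in info.items()
                    if key.startswith("MAF_")
                }
                reference_ac = {
                    key[3:]: int(_scalar(value, alt_index))
                    for key, value in info.items()
                    if key.startswith("AC_")
                }
                exdist = info.get("EXDIST")
                variants.append(
                    AnnotatedVariant(
                        variant_id=vid,
                        gene_symbol=str(_scalar(info.get("GENE", ""), alt_index)),
                        raw_consequence=str(_scalar(info.get("CONS", ""), alt_index)),
                        reference_maf=reference_maf,
                        reference_alt_count=reference_ac,
                        predictor_a=_parse_verdict(_scalar(info.get("PRED_A"), alt_index)),
                        predictor_b=_parse_verdict(_scalar(info.get("PRED_B"), alt_index)),
                        invitro_lof=bool(info.get("INVITRO", False)),
                        exon_boundary_distance=(
                            None if exdist is None else int(_scalar(exdist, alt_index))
                        ),
                    )
                )
                allele_index = alt_index + 1
                for sample in samples:
                    data = rec.samples[sample]
                    gt = data.get("GT")
                    if gt is None or all(a is None for a in gt):
                        continue
                    observed = [a for a in gt if a is not None]
                    n_alt = sum(1 for a in observed if a == allele_index)
                    if n_alt == 0:
                        continue
                    if len(observed) == 1:
                        zygosity = Zygosity.HEMI
                    elif n_alt == len(observed):
                        zygosity = Zygosity.HOM
                    else:
                        zygosity = Zygosity.HET
                    gq = data.get("GQ")
                    try:
                        calls.append(
                            GenotypeCall(
                                proband_id=sample,
                                variant_id=vid,
                                zygosity=zygosity,
                                genotype_quality=None if gq is None else float(gq),
                            )
                        )
                    except ValidationError:
                        logger.warning(
                            "%s: malformed genotype for %s at %s, skipped",
                            path,
                            sample,
                            vid,
                        )
                        n_skipped += 1
    return variants, calls, n_skipped


def _scalar(value: object, alt_index: int) -> object:
    if isinstance(value, tuple):
        return value[alt_index] if alt_index < len(value) else value[0]
    return value


def write_variant_table(
    variants: list[AnnotatedVariant],
    calls: list[GenotypeCall],
    path: str,
) -> None:
    """Write the flat TSV dialect (one row per proband x alt allele)."""
    by_id = {v.variant_id: v for v in variants}
    populations = sorted({pop for v in variants for pop in v.reference_maf})
    ac_pops = sorted({pop for v in variants for pop in v.reference_alt_count})
    rows = []
    for call in calls:
        v = by_id[call.variant_id]
        row: dict[str, object] = {
            "proband_id": call.proband_id,
            "variant_id": call.variant_id,
            "gene_symbol": v.gene_symbol,
            "raw_consequence": v.raw_consequence,
            "zygosity": call.zygosity.value,
            "genotype_quality": (
                "" if call.genotype_quality is None else repr(call.genotype_quality)
            ),
            "predictor_a": v.predictor_a.value,
            "predictor_b": v.predictor_b.value,
            "invitro_lof": str(v.invitro_lof).lower(),
            "exon_boundary_distance": (
                "" if v.exon_boundary_distance is None else v.exon_boundary_distance
            ),
            "splice_delta": "" if v.splice_delta is None else repr(v.splice_delta),
        }
        for pop in populations:
            row[f"maf_{pop}"] = (
                repr(v.reference_maf[pop]) if pop in v.reference_maf else ""
            )
        for pop in ac_pops:
            row[f"ac_{pop}"] = (
                v.reference_alt_count[pop] if pop in v.reference_alt_count else ""
            )
        rows.append(row)
    columns = _VARIANT_COLUMNS + [
        "predictor_a",
        "predictor_b",
        "invitro_lof",
        "exon_boundary_distance",
        "splice_delta",
    ]
    columns += [f"maf_{p}" for p in populations] + [f"ac_{p}" for p in ac_pops]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def validate_hemizygous_calls(
    calls: list[GenotypeCall],
    variants: list[AnnotatedVariant],
    probands: list[Proband],
    panel: list[GenePanelEntry],
) -> None:
    """Assert hemizygous calls occur only for (male proband, X-linked gene)."""
    gene_of = {v.variant_id: v.gene_symbol for v in variants}
    x_genes = {
        e.gene_symbol for e in panel if e.chromosome_class is ChromosomeClass.X
    }
    sex_of = {p.proband_id: p.sex for p in probands}
    for call in calls:
        if call.zygosity is not Zygosity.HEMI:
            continue
        gene = gene_of.get(call.variant_id)
        if gene not in x_genes or sex_of.get(call.proband_id) is not Sex.MALE:
            raise ValidationError(
                f"hemizygous call for {call.proband_id} at {call.variant_id} "
                f"({gene}) is only valid for a male proband and an X-linked gene"
            )
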