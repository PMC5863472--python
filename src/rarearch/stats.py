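"""Exact statistics for cohort contrasts and gene-collapsed burden tests.

The two-sided Fisher exact test uses the minimum-likelihood convention:
the p-value sums the hypergeometric probabilities of every table with the
observed margins whose point probability does not exceed the observed
table's (within a small relative tolerance for ties). Point probabilities
are computed in log space (log-gamma), so tables with tens of thousands of
reference alleles remain numerically stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Relative tolerance when comparing point probabilities for the
#: minimum-likelihood two-sided rule.
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = event / non-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table entries must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _log_hypergeom_pmf(k: np.ndarray, n1: int, n2: int, c1: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(rows n1/n2, first-column total c1)."""
    n = n1 + n2
    return (
        gammaln(n1 + 1)
        - gammaln(k + 1)
        - gammaln(n1 - k + 1)
        + gammaln(n2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(n2 - (c1 - k) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value under the minimum-likelihood rule.

    A table with a zero margin carries no information and returns 1.0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n1, n2 = a + b, c + d
    c1 = a + c
    if n1 == 0 or n2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    support = np.arange(max(0, c1 - n2), min(n1, c1) + 1)
    log_pmf = _log_hypergeom_pmf(support, n1, n2, c1)
    log_obs = log_pmf[support.searchsorted(a)]
    # Shift by the maximum before exponentiating for stability.
    shift = log_pmf.max()
    pmf = np.exp(log_pmf - shift)
    obs = np.exp(log_obs - shift)
    p = float(pmf[pmf <= obs * (1.0 + TIE_RTOL)].sum() / pmf.sum())
    return min(p, 1.0)


def fisher_one_sided_greater(table: ContingencyTable2x2) -> float:
    """One-sided (upper-tail) Fisher exact p-value, P(X >= a)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n1, n2 = a + b, c + d
    c1 = a + c
    if n1 == 0 or n2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    support = np.arange(max(0, c1 - n2), min(n1, c1) + 1)
    log_pmf = _log_hypergeom_pmf(support, n1, n2, c1)
    shift = log_pmf.max()
    pmf = np.exp(log_pmf - shift)
    p = float(pmf[support >= a].sum() / pmf.sum())
    return min(p, 1.0)


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


@dataclass(frozen=True)
class BurdenTestResult:
    gene_symbol: str
    case_alt_alleles: int
    case_total_alleles: int
    ref_alt_alleles: int
    ref_total_alleles: int
    p_value: float
    cutoff: float

    @property
    def significant(self) -> bool:
        return self.p_value <= self.cutoff

    @property
    def case_frequency(self) -> float:
        return self.case_alt_alleles / self.case_total_alleles

    @property
    def ref_frequency(self) -> float:
        return self.ref_alt_alleles / self.ref_total_alleles


def rva_gene_test(
    gene_symbol: str,
    case_counts: tuple[int, int],
    ref_counts: tuple[float, float],
    cutoff: float,
) -> BurdenTestResult:
    """Gene-collapsed rare-variant association test.

    Compares the mutated-allele frequency in cases against the reference
    population with a two-sided Fisher exact test on
    ``[[case_alt, case_rest], [ref_alt, ref_rest]]``. Fractional reference
    totals (averages of alleles inspected across sites) are rounded to the
    nearest integer, which perturbs the table by at most half an allele.
    """
    case_alt, case_total = case_counts
    ref_alt_raw, ref_total_raw = ref_counts
    ref_alt = int(round(ref_alt_raw))
    ref_total = int(round(ref_total_raw))
    if ref_total != ref_total_raw or ref_alt != ref_alt_raw:
        logger.info(
            "%s: reference counts rounded to integers (%s/%s -> %d/%d)",
            gene_symbol,
            ref_alt_raw,
            ref_total_raw,
            ref_alt,
            ref_total,
        )
    if case_alt > case_total or ref_alt > ref_total:
        raise ValueError(f"{gene_symbol}: alt alleles exceed total alleles")
    if case_total == 0 or ref_total == 0:
        raise ValueError(f"{gene_symbol}: zero total alleles, test undefined")
    p = fisher_two_sided(
        ContingencyTable2x2(case_alt, case_total - case_alt, ref_alt, ref_total - ref_alt)
    )
    return BurdenTestResult(
        gene_symbol=gene_symbol,
        case_alt_alleles=case_alt,
        case_total_alleles=case_total,
        ref_alt_alleles=ref_alt,
        ref_total_alleles=ref_total,
        p_value=p,
        cutoff=cutoff,
    )


def carrier_test(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> float:
    """Two-sided Fisher test comparing carrier prevalence between groups.

    Each argument is ``(carriers, cohort size)``.
    """
    (ca, na), (cb, nb) = group_a, group_b
    if ca > na or cb > nb:
        raise ValueError("carriers cannot exceed cohort size")
    return fisher_two_sided(ContingencyTable2x2(ca, na - ca, cb, nb - cb))


def ptv_enrichment(
    case: tuple[int, int], control: tuple[int, int]
) -> float:
    """Two-sided Fisher test on the PTV / non-PTV mutation composition.

    Each argument is ``(n_ptv, n_mutations)``.
    """
    (pa, na), (pb, nb) = case, control
    if pa > na or pb > nb:
        raise ValueError("PTV count cannot exceed mutation count")
    if na == 0 or nb == 0:
        raise ValueError("PTV enrichment undefined for an empty mutation set")
    return fisher_two_sided(ContingencyTable2x2(pa, na - pa, pb, nb - pb))


#: pLI strata: high constraint (>= 0.9), tolerant (< 0.1), intermediate.
PLI_HIGH = 0.9
PLI_LOW = 0.1


def pli_stratum(pli: float | None) -> str | None:
    if pli is None:
        return None
    if pli >= PLI_HIGH:
        return "high"
    if pli < PLI_LOW:
        return "low"
    return "other"


def pli_stratified_test(
    case_strata: dict[str, int], control_strata: dict[str, int]
) -> float:
    """Fisher test of high-constraint vs other PTV placement.

    Arguments map stratum labels (``high`` / ``low`` / ``other``) to PTV
    counts; the test contrasts the ``high`` stratum against the rest.
    PTVs in genes without a pLI value must be excluded upstream.
    """
    case_high = case_strata.get("high", 0)
    case_rest = sum(v for k, v in case_strata.items() if k != "high")
    ctrl_high = control_strata.get("high", 0)
    ctrl_rest = sum(v for k, v in control_strata.items() if k != "high")
    if case_high + case_rest == 0 or ctrl_high + ctrl_rest == 0:
        raise ValueError("pLI-stratified test undefined for an empty stratum set")
    return fisher_two_sided(
        ContingencyTable2x2(case_high, case_rest, ctrl_high, ctrl_rest)
    )
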