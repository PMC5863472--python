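"""Reproducible validation experiments: exact-test oracle agreement,
parameter-recovery coverage, and null calibration of the carrier contrast.

These run the package end to end on simulated cohorts and are shared by
the test suite and the results-reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

from .classify import classify_cohort
from .model import InheritanceMode
from .simulate import GeneSimConfig, SimulationConfig, recover_parameters, simulate_cohort
from .stats import ContingencyTable2x2, carrier_test, fisher_two_sided


def enumerate_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Brute-force two-sided Fisher p-value in exact rational arithmetic.

    Enumerates every table with the observed margins and sums the
    hypergeometric weights of those no more probable than the observed
    table. Independent of the log-gamma implementation; used as its oracle.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    observed = comb(r1, a) * comb(r2, c)
    total = sum(
        weight
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if (weight := comb(r1, k) * comb(r2, c1 - k)) <= observed
    )
    return Fraction(total, comb(n, c1))


def fisher_oracle_agreement(
    n_tables: int = 1000, max_entry: int = 15, seed: int = 0, rtol: float = 1e-9
) -> float:
    """Fraction of random tables where the implementation matches the
    enumeration oracle (entries uniform, so totals stay <= 4 * max_entry)."""
    rng = np.random.default_rng(seed)
    n_match = 0
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(0, max_entry + 1, size=4))
        p = fisher_two_sided(ContingencyTable2x2(a, b, c, d))
        oracle = float(enumerate_fisher_two_sided(a, b, c, d))
        if math.isclose(p, oracle, rel_tol=rtol, abs_tol=1e-300):
            n_match += 1
    return n_match / n_tables


def _uniform_config(
    seed: int,
    groups: dict[str, int],
    f: float,
    n_genes: int,
    rho: float = 1.0,
) -> SimulationConfig:
    genes = [
        GeneSimConfig(
            symbol=f"GENE{i:02d}",
            inheritance_mode=InheritanceMode.DOMINANT,
            carrier_frequency=f,
            fraction_ptv=0.3,
        )
        for i in range(n_genes)
    ]
    return SimulationConfig(
        seed=seed,
        n_probands=dict(groups),
        genes=genes,
        oligogenic_coupling=rho,
        background_rate=0.0,
        predictor_damaging_rate=1.0,
    )


def _run_pipeline(config: SimulationConfig):
    cohort = simulate_cohort(config)
    mutations, _ = classify_cohort(
        cohort.variants,
        cohort.genotypes,
        cohort.probands,
        cohort.panel,
        {group: config.reference_population for group in config.n_probands},
    )
    return cohort, mutations


@dataclass
class CoverageResult:
    coverage: float
    concordance: float
    n_replicates: int
    n_cells: int


def carrier_ci_coverage(
    n_replicates: int = 200,
    n: int = 116,
    f: float = 0.1,
    n_genes: int = 25,
    rho: float = 1.0,
    seed: int = 0,
) -> CoverageResult:
    """End-to-end parameter recovery over replicate cohorts.

    Each replicate simulates a noiseless cohort (perfect predictor
    verdicts, no benign background), runs classification, and checks the
    per-gene 95% Clopper-Pearson carrier-frequency intervals against the
    generating frequency. Returns the pooled CI coverage over all
    (replicate, gene) cells and the worst truth/output concordance seen.
    """
    rng = np.random.default_rng(seed)
    n_covered = 0
    n_cells = 0
    worst_concordance = 1.0
    for _ in range(n_replicates):
        config = _uniform_config(
            seed=int(rng.integers(2**31)), groups={"KS": n}, f=f, n_genes=n_genes, rho=rho
        )
        cohort, mutations = _run_pipeline(config)
        report = recover_parameters(cohort.truth, mutations, cohort.probands)
        n_covered += sum(r.covered for r in report.per_gene)
        n_cells += len(report.per_gene)
        worst_concordance = min(worst_concordance, report.concordance)
    return CoverageResult(
        coverage=n_covered / n_cells,
        concordance=worst_concordance,
        n_replicates=n_replicates,
        n_cells=n_cells,
    )


@dataclass
class CalibrationResult:
    rejection_rate: float
    mc_sd: float
    alpha: float
    n_contrasts: int

    @property
    def bound(self) -> float:
        """Nominal level plus three Monte-Carlo standard deviations."""
        return self.alpha + 3 * self.mc_sd


def null_calibration(
    n_contrasts: int = 1000,
    n_per_group: int = 116,
    f: float = 0.02,
    n_genes: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> CalibrationResult:
    """Type-I error of the carrier contrast under a simulated null.

    Case and control groups are generated with identical per-gene carrier
    frequencies; each contrast runs the classifier on both groups and
    tests the carrier counts. The exact test is conservative, so the
    rejection rate should sit at or below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n_reject = 0
    for _ in range(n_contrasts):
        config = _uniform_config(
            seed=int(rng.integers(2**31)),
            groups={"KS": n_per_group, "CDGP": n_per_group},
            f=f,
            n_genes=n_genes,
        )
        cohort, mutations = _run_pipeline(config)
        carriers = {"KS": set(), "CDGP": set()}
        for m in mutations:
            carriers[m.proband_id.split("_")[0]].add(m.proband_id)
        p = carrier_test(
            (len(carriers["KS"]), n_per_group), (len(carriers["CDGP"]), n_per_group)
        )
        if p <= alpha:
            n_reject += 1
    mc_sd = math.sqrt(alpha * (1 - alpha) / n_contrasts)
    return CalibrationResult(
        rejection_rate=n_reject / n_contrasts,
        mc_sd=mc_sd,
        alpha=alpha,
        n_contrasts=n_contrasts,
    )
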