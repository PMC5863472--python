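"""Splice-site strength scoring and the intronic-variant retention rule.

An intronic variant is retained as a splice candidate when it lies within
±6 bp of an exon boundary and the predicted strength of the affected splice
site changes by at least 20% relative to wild type.

The scoring model is pluggable. The genuine maximum-entropy splice models
use externally distributed parameter tables; this package ships a
position-weight-matrix (PWM) log-odds baseline built from canonical
donor/acceptor consensus base frequencies, authored here as a synthetic
stand-in with the same window conventions:

* donor: 9 nt = last 3 exonic + first 6 intronic bases;
* acceptor: 23 nt = last 20 intronic + first 3 exonic bases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnnotatedVariant, ConsequenceClass

logger = logging.getLogger(__name__)

BASES = "ACGT"
DONOR_WINDOW = 9
ACCEPTOR_WINDOW = 23
#: Candidate window around exon boundaries, in bp.
MAX_BOUNDARY_DISTANCE = 6
#: Minimum |relative score change| for retention.
DELTA_THRESHOLD = 0.20

WINDOW_LENGTHS = {"donor": DONOR_WINDOW, "acceptor": ACCEPTOR_WINDOW}


@dataclass(frozen=True)
class SpliceSiteContext:
    """Wild-type and mutated sequence for one splice site near a variant."""

    site_kind: str  # "donor" or "acceptor"
    wt_sequence: str
    mut_sequence: str
    boundary_distance: int

    def __post_init__(self) -> None:
        if self.site_kind not in WINDOW_LENGTHS:
            raise ValueError(f"unknown site kind {self.site_kind!r}")
        if len(self.wt_sequence) != len(self.mut_sequence):
            raise ValueError("wild-type and mutated windows differ in length")
        expected = WINDOW_LENGTHS[self.site_kind]
        if len(self.wt_sequence) != expected:
            raise ValueError(
                f"{self.site_kind} window must be {expected} nt, "
                f"got {len(self.wt_sequence)}"
            )
        for seq in (self.wt_sequence, self.mut_sequence):
            if any(base not in BASES for base in seq.upper()):
                raise ValueError(f"non-ACGT symbol in window {seq!r}")


@dataclass(frozen=True)
class SpliceScoreDelta:
    wt_score: float
    mut_score: float
    relative_change: float | None  # None when wt_score == 0 (degenerate)

    @property
    def degenerate(self) -> bool:
        return self.relative_change is None


class PWMScorer:
    """Log-odds position-weight-matrix splice-site scorer.

    ``matrices`` maps site kind to an (L, 4) array of per-position log-odds
    (log2 of base frequency over a uniform background), column order ACGT.
    """

    def __init__(self, matrices: dict[str, np.ndarray]):
        self.matrices = {}
        for kind, matrix in matrices.items():
            matrix = np.asarray(matrix, dtype=float)
            if kind not in WINDOW_LENGTHS:
                raise ValueError(f"unknown site kind {kind!r}")
            if matrix.shape != (WINDOW_LENGTHS[kind], 4):
                raise ValueError(
                    f"{kind} matrix must have shape "
                    f"({WINDOW_LENGTHS[kind]}, 4), got {matrix.shape}"
                )
            self.matrices[kind] = matrix

    def score(self, sequence: str, site_kind: str) -> float:
        matrix = self.matrices[site_kind]
        sequence = sequence.upper()
        if len(sequence) != matrix.shape[0]:
            raise ValueError(
                f"{site_kind} window must be {matrix.shape[0]} nt, "
                f"got {len(sequence)}"
            )
        try:
            idx = [BASES.index(base) for base in sequence]
        except ValueError as exc:
            raise ValueError(f"non-ACGT symbol in {sequence!r}") from exc
        return float(matrix[np.arange(len(idx)), idx].sum())

    def consensus(self, site_kind: str) -> str:
        """The maximal-scoring sequence for ``site_kind``."""
        matrix = self.matrices[site_kind]
        return "".join(BASES[j] for j in matrix.argmax(axis=1))


def _log_odds(frequencies: list[dict[str, float]]) -> np.ndarray:
    return np.array(
        [[math.log2(pos[b] / 0.25) for b in BASES] for pos in frequencies]
    )


def _donor_frequencies() -> list[dict[str, float]]:
    # Canonical GT donor consensus (3 exonic + GTRAGT-like intronic part).
    return [
        {"A": 0.33, "C": 0.37, "G": 0.18, "T": 0.12},
        {"A": 0.60, "C": 0.13, "G": 0.14, "T": 0.13},
        {"A": 0.08, "C": 0.04, "G": 0.81, "T": 0.07},
        {"A": 0.01, "C": 0.01, "G": 0.97, "T": 0.01},
        {"A": 0.02, "C": 0.03, "G": 0.02, "T": 0.93},
        {"A": 0.58, "C": 0.03, "G": 0.36, "T": 0.03},
        {"A": 0.70, "C": 0.08, "G": 0.10, "T": 0.12},
        {"A": 0.07, "C": 0.05, "G": 0.82, "T": 0.06},
        {"A": 0.17, "C": 0.18, "G": 0.20, "T": 0.45},
    ]


def _acceptor_frequencies() -> list[dict[str, float]]:
    # Polypyrimidine tract, then the YAG acceptor, then 3 exonic bases.
    tract = {"A": 0.10, "C": 0.31, "G": 0.10, "T": 0.49}
    return (
        [dict(tract) for _ in range(16)]
        + [
            {"A": 0.24, "C": 0.30, "G": 0.21, "T": 0.25},
            {"A": 0.04, "C": 0.65, "G": 0.01, "T": 0.30},
            {"A": 0.97, "C": 0.01, "G": 0.01, "T": 0.01},
            {"A": 0.01, "C": 0.01, "G": 0.97, "T": 0.01},
            {"A": 0.24, "C": 0.14, "G": 0.50, "T": 0.12},
            {"A": 0.28, "C": 0.23, "G": 0.26, "T": 0.23},
            {"A": 0.26, "C": 0.24, "G": 0.26, "T": 0.24},
        ]
    )


def baseline_scorer() -> PWMScorer:
    """The shipped PWM log-odds baseline scorer."""
    return PWMScorer(
        {
            "donor": _log_odds(_donor_frequencies()),
            "acceptor": _log_odds(_acceptor_frequencies()),
        }
    )


def uniform_scorer() -> PWMScorer:
    """All-zero log-odds scorer: every sequence scores 0 (degenerate)."""
    return PWMScorer(
        {
            "donor": np.zeros((DONOR_WINDOW, 4)),
            "acceptor": np.zeros((ACCEPTOR_WINDOW, 4)),
        }
    )


def score_site(sequence: str, site_kind: str, scorer: PWMScorer) -> float:
    """Score one splice-site window under ``scorer``."""
    return scorer.score(sequence, site_kind)


def relative_change(wt_score: float, mut_score: float) -> float:
    """Signed relative score change, ``(mut - wt) / |wt|``.

    Raises :class:`ZeroDivisionError` for a degenerate wild-type score of 0;
    callers treat that case as "not retained".
    """
    if wt_score == 0:
        raise ZeroDivisionError("relative change undefined for wt_score == 0")
    return (mut_score - wt_score) / abs(wt_score)


def score_delta(
    context: SpliceSiteContext, scorer: PWMScorer
) -> SpliceScoreDelta:
    wt = score_site(context.wt_sequence, context.site_kind, scorer)
    mut = score_site(context.mut_sequence, context.site_kind, scorer)
    if wt == 0:
        logger.warning(
            "degenerate wild-type splice score 0 for %s site; delta undefined",
            context.site_kind,
        )
        return SpliceScoreDelta(wt, mut, None)
    return SpliceScoreDelta(wt, mut, relative_change(wt, mut))


def passes_splice_filter(
    variant: AnnotatedVariant,
    context: SpliceSiteContext | None,
    scorer: PWMScorer,
    max_distance: int = MAX_BOUNDARY_DISTANCE,
    delta_threshold: float = DELTA_THRESHOLD,
) -> bool:
    """Apply the intronic retention rule; mutates the variant on success.

    Retained iff |boundary distance| <= ``max_distance`` and the splice-site
    score changes by at least ``delta_threshold`` in either direction
    (threshold inclusive). On retention, the variant's consequence class
    becomes ``splice_candidate`` and the signed delta is stored on it.
    A degenerate wild-type score (0) never retains.
    """
    if variant.exon_boundary_distance is None:
        raise ValueError(
            f"{variant.variant_id}: intronic variant without boundary distance"
        )
    if context is None:
        logger.warning(
            "%s: no splice-site context; variant excluded", variant.variant_id
        )
        return False
    if abs(variant.exon_boundary_distance) > max_distance:
        return False
    delta = score_delta(context, scorer)
    if delta.degenerate:
        return False
    assert delta.relative_change is not None
    if abs(delta.relative_change) >= delta_threshold:
        variant.consequence_class = ConsequenceClass.SPLICE_CANDIDATE
        variant.splice_delta = delta.relative_change
        return True
    return False


def read_scorer_matrix(path: str) -> np.ndarray:
    """Read a position x nucleotide log-odds matrix from TSV (pos, A, C, G, T)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("pos", *BASES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df.sort_values("pos")
    return df[list(BASES)].to_numpy(dtype=float)


def write_scorer_matrix(matrix: np.ndarray, path: str) -> None:
    matrix = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(matrix, columns=list(BASES))
    df.insert(0, "pos", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False)


def extract_window(
    fasta_path: str,
    chrom: str,
    exon_end: int,
    site_kind: str,
    strand: str = "+",
) -> str:
    """Extract a splice-site window from a reference FASTA.

    ``exon_end`` is the 0-based half-open BED end (donor) or start
    (acceptor) of the exon on the forward strand. Reverse-strand windows
    are reverse-complemented into the site's reading orientation.
    """
    from pyfaidx import Fasta

    with Fasta(fasta_path) as fasta:
        seq_len = len(fasta[chrom])
        if site_kind == "donor":
            exonic, intronic = 3, 6
        elif site_kind == "acceptor":
            exonic, intronic = 3, 20
        else:
            raise ValueError(f"unknown site kind {site_kind!r}")
        if strand == "+":
            left = exonic if site_kind == "donor" else intronic
        else:
            left = intronic if site_kind == "donor" else exonic
        start, end = exon_end - left, exon_end + (exonic + intronic - left)
        if start < 0 or end > seq_len:
            raise ValueError(f"window [{start}, {end}) outside {chrom}")
        window = str(fasta[chrom][start:end]).upper()
    if strand == "-":
        complement = str.maketrans("ACGT", "TGCA")
        window = window.translate(complement)[::-1]
    return window
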