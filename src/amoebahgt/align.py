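"""Pairwise local protein alignment with identity, coverage and e-value.

The aligner is Smith–Waterman with affine gaps (default BLOSUM62, gap open 11,
gap extend 1; a gap of length k costs ``open + k*extend``), executed through
Biopython's C PairwiseAligner.  E-values follow Karlin–Altschul statistics,
``E = K·m·n·exp(−λ·S)``, with the published gapped-BLOSUM62 constants
(λ = 0.267, K = 0.041) and m, n the query length and effective database length
supplied by the caller — deterministic and adequate for the threshold logic of
the downstream screens, though not bit-identical to any BLAST release.

Ambiguity convention: ``X`` and the stop symbol ``*`` never count as
identities, whatever the matrix scores them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ArgumentError, ConfigError

#: residues that never count toward identity
_NON_IDENTITY = frozenset("X*")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: substitution matrix, affine gap costs, and the
    Karlin–Altschul (λ, K) pair used to convert raw scores to e-values."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    min_raw_score: int = 1

    def min_score_for_evalue(self, evalue: float, m: int, n: int) -> float:
        """Smallest raw score whose e-value at (m, n) is <= ``evalue``."""
        return math.log(self.ka_k * m * n / evalue) / self.ka_lambda


DEFAULT_SCHEME = ScoringScheme()
BLOSUM50_SCHEME = ScoringScheme(matrix_name="BLOSUM50", gap_open=10, gap_extend=1)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject protein.

    ``identity_pct`` is 100·identities/alignment columns (gap columns count in
    the denominator); ``coverage_pct`` is 100·aligned query residues/query
    length; ``subject_coverage_pct`` is reported alongside for transparency.
    Spans are 1-based inclusive residue intervals.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    identity_pct: float
    coverage_pct: float
    subject_coverage_pct: float
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    alignment_columns: int
    aligned_length: int
    #: gapless blocks of the optimal path, 0-based half-open (qs, qe, ss, se)
    blocks: tuple[tuple[int, int, int, int], ...] = ()


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except Exception:
        raise ConfigError(f"unknown substitution matrix {name!r}") from None


@lru_cache(maxsize=8)
def make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    """Build the (cached) local aligner for a scoring scheme."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(scheme.matrix_name)
    # Biopython charges open_gap_score on the first gapped position; the
    # BLAST-style cost open + k*extend therefore maps to open+extend there.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def score_pair(query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Optimal local-alignment raw score only (fast path; no traceback)."""
    if not query or not subject:
        raise ArgumentError("sequences must be non-empty")
    return int(round(make_aligner(scheme).score(query, subject)))


def evalue_from_score(raw_score: float, m: int, n: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    return scheme.ka_k * m * n * math.exp(-scheme.ka_lambda * raw_score)


def bit_score_from_score(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    return (scheme.ka_lambda * raw_score - math.log(scheme.ka_k)) / math.log(2)


def align_pair(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
    db_length: int | None = None,
) -> AlignmentHit | None:
    """Best local alignment of two proteins, or ``None`` if the optimal raw
    score falls below ``scheme.min_raw_score``.

    ``db_length`` is the effective database length n for the e-value; it
    defaults to the subject length (single-pair statistics).
    """
    if not query or not subject:
        raise ArgumentError("sequences must be non-empty")
    aligner = make_aligner(scheme)
    score = int(round(aligner.score(query, subject)))
    if score < scheme.min_raw_score:
        return None
    aln = aligner.align(query, subject)[0]
    qblocks, sblocks = aln.aligned
    identities = 0
    pairs = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        pairs += qe - qs
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b and a not in _NON_IDENTITY:
                identities += 1
    q_lo, q_hi = int(qblocks[0][0]), int(qblocks[-1][1])
    s_lo, s_hi = int(sblocks[0][0]), int(sblocks[-1][1])
    q_span_len = q_hi - q_lo
    s_span_len = s_hi - s_lo
    columns = pairs + (q_span_len - pairs) + (s_span_len - pairs)
    n = db_length if db_length is not None else len(subject)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        bit_score=bit_score_from_score(score, scheme),
        identity_pct=100.0 * identities / columns,
        coverage_pct=100.0 * q_span_len / len(query),
        subject_coverage_pct=100.0 * s_span_len / len(subject),
        evalue=evalue_from_score(score, len(query), n, scheme),
        query_span=(q_lo + 1, q_hi),
        subject_span=(s_lo + 1, s_hi),
        alignment_columns=columns,
        aligned_length=pairs,
        blocks=tuple(
            (int(qs), int(qe), int(ss), int(se))
            for (qs, qe), (ss, se) in zip(qblocks, sblocks)
        ),
    )


def with_db_length(hit: AlignmentHit, m: int, n: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> AlignmentHit:
    """Re-state a hit's e-value for an effective database length n."""
    return replace(hit, evalue=evalue_from_score(hit.raw_score, m, n, scheme))
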