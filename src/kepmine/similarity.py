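"""Local pairwise alignment with Karlin-Altschul E-values and reciprocal-hit
logic.

Smith-Waterman alignment is computed with Biopython's ``PairwiseAligner``
under BLOSUM62 with affine gaps (a gap of length g costs
``gap_open + (g - 1) * gap_extend``). E-values follow the Karlin-Altschul
formula E = K * m * n * exp(-lambda * S) with the standard gapped BLOSUM62
constants (lambda = 0.267, K = 0.041); in database mode n is the total
residue count of the database. The thresholds used downstream (1e-30,
1e-10) are extreme enough that modest constant error cannot flip decisions;
composition-based statistics and low-complexity filtering are deliberately
not emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from kepmine.io_formats import ALPHABET


@dataclass
class AlignmentParams:
    """Scoring scheme and E-value constants for local alignment."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    search_space_mode: str = "pairwise"  # "pairwise" | "database"
    db_size: int | None = None  # total residues; required in database mode

    def __post_init__(self) -> None:
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.search_space_mode not in ("pairwise", "database"):
            raise ValueError(f"unknown search_space_mode {self.search_space_mode!r}")
        if self.search_space_mode == "database" and not self.db_size:
            raise ValueError("database mode requires db_size")


@dataclass
class AlignmentHit:
    """A local-alignment result.

    ``identity`` is exact residue matches over aligned columns (gap columns
    count, X never matches); ``coverage_*`` is the aligned span over the full
    sequence length, per sequence. Intervals are 0-based half-open.
    """

    query_id: str
    subject_id: str
    score: float
    evalue: float
    identity: float
    coverage_query: float
    coverage_subject: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _check_alphabet(seq: str, name: str) -> None:
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"{name}: residues outside the alphabet: {sorted(bad)!r}")


def karlin_altschul_evalue(
    score: float, m: int, n: int, params: AlignmentParams | None = None
) -> float:
    """E = K * m * n * exp(-lambda * S); monotone decreasing in S, linear in
    the search space m * n."""
    params = params or AlignmentParams()
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.ka_k * m * n * math.exp(-params.ka_lambda * score)


def _empty_hit(query_id: str, subject_id: str, m: int, n: int) -> AlignmentHit:
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=0.0,
        evalue=math.inf,
        identity=0.0,
        coverage_query=0.0,
        coverage_subject=0.0,
        query_interval=(0, 0),
        subject_interval=(0, 0),
    )


def local_align(
    a: str,
    b: str,
    params: AlignmentParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of ``a`` (query) vs ``b``.

    Sequences whose best local score is not positive get the empty-alignment
    convention: score 0, identity 0, coverage 0, infinite E-value. The
    search-space n for the E-value is ``len(b)`` in pairwise mode and
    ``params.db_size`` in database mode.
    """
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(a, query_id)
    _check_alphabet(b, subject_id)

    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend, "local")
    score = aligner.score(a, b)
    n_space = params.db_size if params.search_space_mode == "database" else len(b)
    if score <= 0:
        return _empty_hit(query_id, subject_id, len(a), n_space)

    alignment = next(iter(aligner.align(a, b)))
    blocks_a, blocks_b = alignment.aligned
    paired = 0
    matches = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        paired += a1 - a0
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if a[i] == b[j] and a[i] != "X":
                matches += 1
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    a_span = a_end - a_start
    b_span = b_end - b_start
    columns = paired + (a_span - paired) + (b_span - paired)
    identity = matches / columns if columns else 0.0

    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        evalue=karlin_altschul_evalue(score, len(a), n_space, params),
        identity=identity,
        coverage_query=a_span / len(a),
        coverage_subject=b_span / len(b),
        query_interval=(a_start, a_end),
        subject_interval=(b_start, b_end),
    )


def reciprocal_link(
    a: str,
    b: str,
    e_threshold: float | None = None,
    coverage_threshold: float | None = None,
    identity_threshold: float | None = None,
    params: AlignmentParams | None = None,
    db_size_a: int | None = None,
    db_size_b: int | None = None,
) -> bool:
    """True iff the pair passes thresholds in BOTH search directions.

    In each direction the query's E-value must fall below ``e_threshold``
    (when set), the query's own coverage must exceed ``coverage_threshold``,
    and identity must exceed ``identity_threshold`` (when set). The
    Smith-Waterman score and identity are symmetric, so one alignment serves
    both directions; the per-direction quantities are each query's coverage
    and its E-value over its own search space (``db_size_a`` / ``db_size_b``
    override the database size per direction in database mode).
    """
    params = params or AlignmentParams()
    hit = local_align(a, b, params=params)
    if hit.score <= 0:
        return False

    if e_threshold is not None:
        n_ab = db_size_a or (params.db_size if params.search_space_mode == "database" else len(b))
        n_ba = db_size_b or (params.db_size if params.search_space_mode == "database" else len(a))
        e_ab = karlin_altschul_evalue(hit.score, len(a), n_ab, params)
        e_ba = karlin_altschul_evalue(hit.score, len(b), n_ba, params)
        if not (e_ab < e_threshold and e_ba < e_threshold):
            return False
    if coverage_threshold is not None:
        if not (
            hit.coverage_query > coverage_threshold
            and hit.coverage_subject > coverage_threshold
        ):
            return False
    if identity_threshold is not None and not hit.identity > identity_threshold:
        return False
    return True
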