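"""Pairwise alignment utilities.

Short, high-identity nucleotide comparisons throughout the package (SL exon
searches, gene-locus location, library overlap) use a BLASTn-short-like
scoring scheme: match +1, mismatch -2, linear gap -2.  Alignment itself is
delegated to :class:`Bio.Align.PairwiseAligner`; this module fixes the
scoring conventions and derives percent identity the same way everywhere.

Percent identity (PID) is identities divided by aligned columns *including*
gap columns, and ``N`` never counts as a match.
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from ._util import revcomp

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -2.0
DEFAULT_GAP = -2.0


@dataclass(frozen=True)
class LocalAlignmentResult:
    """Best local alignment of a query against a subject (either strand).

    ``strand == '-'`` means the subject interval matched the reverse
    complement of the query; ``query_interval`` is then given in original
    query coordinates.  Intervals are 0-based half-open.
    """

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    strand: str
    aligned_length: int
    identities: int
    score: float

    @property
    def pid(self) -> float:
        return self.identities / self.aligned_length if self.aligned_length else 0.0


@lru_cache(maxsize=32)
def _aligner(match: float, mismatch: float, gap: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            # N is treated conservatively: it matches nothing.
            matrix[x, y] = match if (x == y and x != "N") else mismatch
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _columns_and_identities(alignment, target: str, query: str) -> tuple[int, int]:
    """Aligned columns (incl. gap columns between blocks) and identity count."""
    tblocks, qblocks = alignment.aligned
    cols = 0
    idents = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            cols += (ts - prev_t) + (qs - prev_q)
        cols += te - ts
        for i in range(te - ts):
            a, b = target[ts + i], query[qs + i]
            if a == b and a != "N":
                idents += 1
        prev_t, prev_q = te, qe
    return cols, idents


def smith_waterman_local(query: str, subject: str,
                         match: float = DEFAULT_MATCH,
                         mismatch: float = DEFAULT_MISMATCH,
                         gap: float = DEFAULT_GAP,
                         query_id: str = "query",
                         subject_id: str = "subject") -> LocalAlignmentResult:
    """Best local alignment of ``query`` against ``subject`` on both strands.

    The plus strand wins score ties.  Raises ``ValueError`` on empty input.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if not (match > 0 > mismatch and gap < 0):
        raise ValueError("need match > 0 > mismatch, gap")
    aligner = _aligner(match, mismatch, gap, "local")
    best = None
    best_key = None
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        alignments = aligner.align(subject, q)
        if alignments.score <= 0:
            continue
        # Co-optimal tracebacks can differ in identities; choose the one
        # with the most identities (then fewest columns) so pid is
        # well defined and symmetric under query/subject swap.
        for aln in itertools.islice(alignments, 64):
            cols, idents = _columns_and_identities(aln, subject, q)
            key = (alignments.score, idents, -cols, strand == "+")
            if best_key is not None and key <= best_key:
                continue
            tblocks, qblocks = aln.aligned
            s_int = (int(tblocks[0][0]), int(tblocks[-1][1]))
            q_int = (int(qblocks[0][0]), int(qblocks[-1][1]))
            if strand == "-":
                q_int = (len(query) - q_int[1], len(query) - q_int[0])
            best_key = key
            best = (alignments.score, strand, q_int, s_int, cols, idents)
    if best is None:
        # No positive-scoring local alignment exists (e.g. disjoint alphabets).
        return LocalAlignmentResult(query_id, subject_id, (0, 0), (0, 0), "+", 0, 0, 0.0)
    score, strand, q_int, s_int, cols, idents = best
    return LocalAlignmentResult(query_id, subject_id, q_int, s_int, strand,
                                cols, idents, float(score))


def needleman_wunsch_global(a: str, b: str,
                            match: float = DEFAULT_MATCH,
                            mismatch: float = DEFAULT_MISMATCH,
                            gap: float = DEFAULT_GAP) -> tuple[str, str, float]:
    """Optimal global alignment of ``a`` and ``b``.

    Returns the two equal-length aligned strings (``-`` for gaps) and the
    optimal score; removing gaps recovers the inputs.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _aligner(match, mismatch, gap, "global")
    alignments = aligner.align(a, b)
    aln = alignments[0]
    return str(aln[0]), str(aln[1]), float(alignments.score)
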