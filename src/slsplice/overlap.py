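"""Overlap between transcript libraries under identity/length filters.

Used to compare an SL-PCR-style amplicon library against the SL and non-SL
transcript pools of an RNA-seq assembly: a transcript in set A counts as
shared with set B when some member of B gives a local alignment of at
least ``min_len`` aligned columns at percent identity >= ``min_pid``.
Each transcript counts once (best hit), mirroring deduplication by unique
sequence id.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import smith_waterman_local


@dataclass
class OverlapResult:
    """Shared/unshared counts between two sequence sets."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    shared_a: int            # members of A matched by some member of B
    shared_b: int            # members of B matched by some member of A
    best_hits: pd.DataFrame  # per-A-transcript best hit (pid, aligned length)

    @property
    def fraction_a(self) -> float:
        return self.shared_a / self.n_a

    @property
    def fraction_b(self) -> float:
        return self.shared_b / self.n_b


def overlap_sets(set_a, set_b, min_pid: float = 0.98, min_len: int = 50,
                 label_a: str = "A", label_b: str = "B") -> OverlapResult:
    """Count transcripts shared between two sets under the filters.

    Matching is symmetric in the thresholds: the same matched pairs drive
    both directions.  Raises on an empty set.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    rows = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for a in set_a:
        best = None
        for b in set_b:
            r = smith_waterman_local(a.seq, b.seq, query_id=a.id,
                                     subject_id=b.id)
            if best is None or r.score > best.score:
                best = r
            if r.aligned_length >= min_len and r.pid >= min_pid:
                matched_a.add(a.id)
                matched_b.add(b.id)
        rows.append(dict(transcript_id=a.id, best_subject=best.subject_id,
                         pid=best.pid, aligned_length=best.aligned_length,
                         matched=a.id in matched_a))
    return OverlapResult(label_a, label_b, len(set_a), len(set_b),
                         len(matched_a), len(matched_b),
                         pd.DataFrame(rows))


def venn_counts(result: OverlapResult) -> pd.DataFrame:
    """Venn-style table: only-A, shared, only-B (by unique sequence id)."""
    return pd.DataFrame([
        dict(region=f"only_{result.label_a}",
             count=result.n_a - result.shared_a),
        dict(region="shared", count=result.shared_a),
        dict(region=f"only_{result.label_b}",
             count=result.n_b - result.shared_b),
    ])
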