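"""Permutation-based term enrichment of SL transcript pools.

Each SL-defined pool (test set) is compared against the whole annotated
transcriptome (universe).  For a term with ``K`` carriers in a universe of
``M`` transcripts and a test set of size ``N``, the null distribution of
the carrier count in the test set is obtained by drawing ``n_perm``
samples of ``N`` transcripts from the universe without replacement and
counting carriers — per term this count is exactly hypergeometric
(M, K, N), which is how the sampling is realised.  The one-sided
(enrichment) p-value uses the add-one estimator
``(1 + #{null >= observed}) / (1 + n_perm)``.  When the exact tail is
cheap to evaluate the enumeration mode returns it directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnnotationMap:
    """transcript id -> set of term ids, plus the annotated universe."""

    terms_of: dict[str, set[str]]

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "AnnotationMap":
        """Build from a (transcript_id, term) long table."""
        terms_of: dict[str, set[str]] = {}
        for tx, term in zip(df["transcript_id"], df["term"]):
            terms_of.setdefault(str(tx), set()).add(str(term))
        return cls(terms_of)

    @property
    def universe(self) -> set[str]:
        return set(self.terms_of)

    def term_universe_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for terms in self.terms_of.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts


def term_counts(test_set, amap: AnnotationMap) -> pd.DataFrame:
    """Observed vs expected term counts and fold enrichment for a test set.

    ``expected = |test| * K / M`` with K the term's universe count; fold is
    observed/expected (NaN, shown as '.', when expected is 0).
    """
    test = set(test_set)
    if not test:
        raise ValueError("empty test set")
    if not test <= amap.universe:
        raise ValueError("test set must be a subset of the annotated universe")
    M = len(amap.universe)
    N = len(test)
    uni = amap.term_universe_counts()
    obs: dict[str, int] = {t: 0 for t in uni}
    for tx in test:
        for t in amap.terms_of[tx]:
            obs[t] += 1
    rows = []
    for term in sorted(uni):
        K = uni[term]
        expected = N * K / M
        fold = obs[term] / expected if expected > 0 else float("nan")
        rows.append(dict(term=term, observed=obs[term], universe_count=K,
                         expected=expected, fold_enrichment=fold))
    return pd.DataFrame(rows)


def exact_pvalue(observed: int, test_size: int, term_universe_count: int,
                 universe_size: int) -> float:
    """Exact one-sided enrichment tail P(X >= observed), hypergeometric."""
    return float(stats.hypergeom.sf(observed - 1, universe_size,
                                    term_universe_count, test_size))


def permutation_pvalue(observed: int, test_size: int,
                       term_universe_count: int, universe_size: int,
                       n_perm: int = 100_000,
                       rng: np.random.Generator | int | None = 0,
                       exhaustive: bool | None = None) -> float:
    """Empirical one-sided enrichment p-value by permutation.

    Draws ``n_perm`` test-set-sized samples from the universe without
    replacement and compares the term count to ``observed`` (realised as
    hypergeometric count draws, which is the same distribution per term).
    ``exhaustive=None`` switches to the exact enumeration automatically
    when C(universe, test) <= 1e6; the exact mode returns the
    hypergeometric tail itself.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if test_size > universe_size:
        raise ValueError("test size exceeds universe")
    if exhaustive is None:
        try:
            exhaustive = math.comb(universe_size, test_size) <= 1_000_000
        except OverflowError:
            exhaustive = False
    if exhaustive:
        return exact_pvalue(observed, test_size, term_universe_count,
                            universe_size)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    null = rng.hypergeometric(term_universe_count,
                              universe_size - term_universe_count,
                              test_size, size=n_perm)
    return float((1 + np.count_nonzero(null >= observed)) / (1 + n_perm))


@dataclass(frozen=True)
class EnrichmentResult:
    pool: str
    term: str
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float
    n_perm: int
    significant: bool


def enrich_pools(calls, amap: AnnotationMap, alpha: float = 0.05,
                 n_perm: int = 100_000, seed: int = 0,
                 bh_correct: bool = False,
                 pools: dict[str, set[str]] | None = None) -> pd.DataFrame:
    """Enrichment of every term in every SL pool against the universe.

    Pools default to the classified SL types from ``calls`` (transcripts
    present in the annotation universe).  One row per (pool, term) with
    positive expected count; deterministic under a fixed seed.  With
    ``bh_correct`` a Benjamini-Hochberg q-value column is added and drives
    the significance flag.
    """
    if pools is None:
        pools = {}
        for c in calls:
            if c.sl_type not in ("none", "incomplete"):
                pools.setdefault(c.sl_type, set()).add(c.transcript_id)
    rng = np.random.default_rng(seed)
    M = len(amap.universe)
    rows = []
    for pool in sorted(pools):
        test = pools[pool] & amap.universe
        if not test:
            continue
        counts = term_counts(test, amap)
        for rec in counts.itertuples():
            if rec.expected <= 0:
                continue
            p = permutation_pvalue(rec.observed, len(test),
                                   rec.universe_count, M, n_perm, rng)
            rows.append(dict(pool=pool, term=rec.term, observed=rec.observed,
                             expected=rec.expected,
                             fold_enrichment=rec.fold_enrichment,
                             p_value=p, n_perm=n_perm))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if bh_correct:
        df["q_value"] = _benjamini_hochberg(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q
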