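"""TPM normalisation and nonparametric comparison of SL-pool abundance.

Counts are normalised to transcripts per million (TPM):
``TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j)`` per sample, with
effective transcript lengths ``l``.  Replicate TPM columns are averaged per
transcript before testing; the lowest quartile of mean TPM is removed to
drop low-coverage transcripts whose 5' ends are likely under-sampled.
Group comparisons use the Kruskal-Wallis test across three or more SL
pools and the Mann-Whitney U test (exact by full enumeration for small
samples, tie-corrected normal approximation otherwise) between pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Raw counts, effective lengths and derived TPM values."""

    counts: pd.DataFrame          # index: transcript ids, columns: samples
    effective_lengths: pd.Series
    tpm: pd.DataFrame
    mean_tpm: pd.Series

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of one rank test over SL pools."""

    test: str                    # kruskal_wallis | mann_whitney | wilcoxon_pairwise
    statistic: float
    p_value: float
    n_obs: dict[str, int]
    medians: dict[str, float]


def tpm_normalize(counts: pd.DataFrame, effective_lengths: pd.Series
                  ) -> AbundanceMatrix:
    """Normalise a counts matrix to TPM per sample.

    ``counts`` is indexed by transcript id with one column per sample.  A
    zero-count sample yields an all-zero TPM column with a warning.
    """
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("effective length missing for some transcripts")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts < 0).to_numpy().any():
        raise ValueError("negative counts")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        log.warning("sample(s) with zero total counts: %s",
                    list(denom.index[zero]))
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return AbundanceMatrix(counts, lengths, tpm, tpm.mean(axis=1))


def quartile_filter(mean_tpm: pd.Series) -> pd.Index:
    """Drop transcripts at or below the lower quartile of mean TPM.

    Q1 uses linear interpolation.  With fewer than 4 transcripts the filter
    is undefined (ValueError); if every value equals Q1 (degenerate ties)
    all transcripts are kept with a warning.
    """
    if len(mean_tpm) < 4:
        raise ValueError("need at least 4 transcripts for a quartile filter")
    q1 = float(np.percentile(mean_tpm.to_numpy(), 25))
    keep = mean_tpm.index[mean_tpm > q1]
    if len(keep) == 0:
        log.warning("degenerate TPM distribution (all values <= Q1); "
                    "keeping all transcripts")
        return mean_tpm.index
    return keep


def _result(test, stat, p, groups: dict[str, np.ndarray]) -> GroupTestResult:
    return GroupTestResult(test, float(stat), float(p),
                           {k: len(v) for k, v in groups.items()},
                           {k: float(np.median(v)) for k, v in groups.items()})


def mann_whitney_test(a, b, labels=("A", "B"),
                      exact_max_n: int = 10) -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    Exact full enumeration when the smaller group has <= ``exact_max_n``
    observations (valid under ties); tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_arrangements = math.comb(a.size + b.size, min(a.size, b.size))
    if min(a.size, b.size) <= exact_max_n and n_arrangements <= 500_000:
        # full enumeration of group assignments; valid under ties
        method = stats.PermutationMethod(n_resamples=500_000)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return _result("mann_whitney", res.statistic, res.pvalue,
                   {labels[0]: a, labels[1]: b})


def kruskal_wallis_test(groups: dict[str, np.ndarray]) -> GroupTestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-squared null, k-1 df)."""
    if len(groups) < 3:
        raise ValueError("need >= 3 groups (use mann_whitney_test for 2)")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    res = stats.kruskal(*arrays)
    return _result("kruskal_wallis", res.statistic, res.pvalue,
                   dict(zip(groups, arrays)))


def compare_sl_pools(matrix: AbundanceMatrix, calls,
                     min_pool_size: int = 3) -> dict:
    """Quartile-filter, then compare mean TPM between SL pools.

    Pools are the classified SL types plus the non-SL pool ("none");
    incomplete calls are excluded because they cannot be assigned a type.
    Returns the overall test (Kruskal-Wallis for >= 3 pools, Mann-Whitney
    for 2), a pairwise rank-sum table, and per-pool medians.
    """
    pool_of = {c.transcript_id: c.sl_type for c in calls
               if c.sl_type not in ("incomplete",)}
    kept = quartile_filter(matrix.mean_tpm)
    groups: dict[str, np.ndarray] = {}
    for pool in sorted(set(pool_of.values())):
        ids = [t for t in kept if pool_of.get(t) == pool]
        vals = matrix.mean_tpm.loc[ids].to_numpy()
        if vals.size >= min_pool_size:
            groups[pool] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 pools with data")
    if len(groups) >= 3:
        overall = kruskal_wallis_test(groups)
    else:
        (la, va), (lb, vb) = groups.items()
        overall = mann_whitney_test(va, vb, labels=(la, lb))
    pairwise = []
    for (la, va), (lb, vb) in itertools.combinations(groups.items(), 2):
        r = mann_whitney_test(va, vb, labels=(la, lb))
        pairwise.append(dict(pool_a=la, pool_b=lb, statistic=r.statistic,
                             p_value=r.p_value, n_a=len(va), n_b=len(vb)))
    return dict(overall=overall, pairwise=pd.DataFrame(pairwise),
                medians={k: float(np.median(v)) for k, v in groups.items()},
                n_filtered=len(kept))
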