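"""Detection, classification and trimming of spliced-leader evidence.

The detector searches transcript 5' ends for the conserved 3'-terminal SLe
octamer (``GGCTCAAG``; assembled transcripts have arbitrary strand, so its
reverse complement ``CTTGAGCC`` is searched near the 3' end and antisense
hits are reverse-complement normalised before all downstream steps).  From
the motif hit it measures how much of the SLe survived 5'-end truncation,
assigns the SL type from the discriminating positions when they are
covered, trims the mature sequence, and summarises the transcriptome
partition.  Consensus strings, position frequency matrices and nucleotide
composition summaries support logo-style reporting.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import iupac_code, pct, revcomp
from .io import SequenceRecord
from .synthetic import SLSystemSpec

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SLCall:
    """Per-transcript SL detection result.

    ``observed_extent`` counts contiguous 3'-terminal SLe nucleotides found
    immediately upstream of (and including) the motif; ``residual_5prime``
    is any unconserved sequence upstream of the observed SLe start;
    ``mature_seq`` is the orientation-normalised transcript with the SLe
    and residual removed.
    """

    transcript_id: str
    orientation: str            # sense | antisense | none
    motif_start: int | None
    observed_extent: int
    sl_type: str                # type name | incomplete | none
    complete: bool
    residual_5prime: str
    mature_seq: str
    observed_suffix: str = ""   # the observed SLe portion itself


def find_sl_evidence(seq: str, motif: str, window: int = 100):
    """Locate the SLe octamer near the transcript 5' end on either strand.

    Returns ``(orientation, motif_start)`` in normalised (sense)
    coordinates, or ``None``.  Sense hits win when both strands match.
    """
    if len(seq) < len(motif):
        raise ValueError("transcript shorter than the SL motif")
    if window < len(motif):
        raise ValueError("window shorter than the motif")
    i = seq.find(motif)
    if 0 <= i < window:
        return "sense", i
    norm = revcomp(seq)
    j = norm.find(motif)
    if 0 <= j < window:
        return "antisense", j
    return None


def measure_sl_extent(norm_seq: str, motif_start: int, sle: str,
                      motif_len: int = 8) -> tuple[int, str]:
    """Observed SLe extent at a motif hit, and the 5' residual.

    Extends the match nucleotide by nucleotide upstream of the motif with
    zero mismatches.  Returns ``(observed_extent, residual_5prime)``.
    """
    if not sle.endswith(norm_seq[motif_start:motif_start + motif_len]):
        raise ValueError("SLe does not end with the motif at this hit")
    end = motif_start + motif_len
    ext = motif_len
    while ext < len(sle) and end - ext - 1 >= 0 \
            and norm_seq[end - ext - 1] == sle[len(sle) - ext - 1]:
        ext += 1
    return ext, norm_seq[:end - ext]


def classify_sl(observed_extent: int, observed_suffix: str,
                system: SLSystemSpec) -> str:
    """Assign the SL type from the observed SLe suffix.

    Multi-type systems classify by the discriminating positions: if the
    observed suffix covers them all and matches one type's alleles, that
    type is returned; otherwise ``incomplete`` (a covered-but-mismatching
    suffix is logged).  Single-type systems call any motif hit their type.
    """
    if not system.multi_type:
        return system.types[0].name
    L = system.sle_length
    positions = sorted({p for t in system.types for p in t.discriminating})
    if any(observed_extent < L - p + 1 for p in positions):
        return "incomplete"
    for t in system.types:
        ok = all(observed_suffix[observed_extent - (L - p + 1)] == b
                 for p, b in t.discriminating.items())
        if ok:
            return t.name
    log.warning("observed SLe suffix matches no type at covered "
                "discriminating positions: %r", observed_suffix)
    return "incomplete"


def trim_sl(norm_seq: str, motif_start: int, motif_len: int = 8) -> str:
    """Mature sequence: everything after the SLe terminal ``...AAG``."""
    return norm_seq[motif_start + motif_len:]


def detect_transcript(record: SequenceRecord, system: SLSystemSpec,
                      window: int = 100) -> SLCall:
    """Full per-transcript detection: orientation, extent, type, trimming."""
    motif = system.motif
    hit = find_sl_evidence(record.seq, motif, window)
    if hit is None:
        return SLCall(record.id, "none", None, 0, "none", False, "",
                      record.seq)
    orientation, start = hit
    norm = record.seq if orientation == "sense" else revcomp(record.seq)
    # Measure against every type's SLe and keep the longest extension, so a
    # type-2 transcript is not cut short at the discriminating positions.
    ext, residual = max(
        (measure_sl_extent(norm, start, t.sle, len(motif))
         for t in system.types),
        key=lambda er: er[0])
    end = start + len(motif)
    suffix = norm[end - ext:end]
    sl_type = classify_sl(ext, suffix, system)
    return SLCall(record.id, orientation, start, ext, sl_type,
                  ext == system.sle_length, residual,
                  trim_sl(norm, start, len(motif)), suffix)


def detect_all(records, system: SLSystemSpec, window: int = 100) -> list[SLCall]:
    return [detect_transcript(r, system, window) for r in records]


def calls_table(calls) -> pd.DataFrame:
    """Tabular view of SL calls (one row per transcript)."""
    return pd.DataFrame([
        dict(transcript_id=c.transcript_id, orientation=c.orientation,
             motif_start=c.motif_start if c.motif_start is not None else ".",
             observed_extent=c.observed_extent, sl_type=c.sl_type,
             complete=c.complete, residual_len=len(c.residual_5prime))
        for c in calls])


def partial_length_distribution(calls) -> tuple[dict[int, int], dict[int, float]]:
    """Histogram of observed SLe extents and fractions with extent >= k.

    Only hit-bearing calls contribute.  Returns ``(histogram, fractions)``
    with fractions for k = 10 and 15 (NaN when there are no hits).
    """
    extents = [c.observed_extent for c in calls if c.orientation != "none"]
    hist = dict(sorted(Counter(extents).items()))
    if not extents:
        return hist, {10: float("nan"), 15: float("nan")}
    n = len(extents)
    fracs = {k: sum(v for e, v in hist.items() if e >= k) / n for k in (10, 15)}
    return hist, fracs


def estimate_missed_sl_fraction(hist: dict[int, int], sle_length: int) -> float:
    """Estimate the fraction of SL transcripts whose SLe was fully truncated.

    The number of missing 5' nucleotides (SLe length - extent) is modelled
    as a rounded normal; full loss makes a transcript undetectable, so the
    observed counts are a right-truncated sample.  The normal is fitted by
    maximum likelihood on the truncated range (with a half-integer
    continuity correction: a count of L missing corresponds to an
    underlying value >= L - 0.5) and the estimate is the fitted tail mass
    of full loss.  Degenerate (single-bin) histograms yield 0 with a
    warning.
    """
    if not hist:
        raise ValueError("empty histogram")
    missing = np.repeat([sle_length - e for e in hist], list(hist.values()))
    missing = missing[missing < sle_length].astype(float)
    if missing.size == 0:
        raise ValueError("no observed (partially truncated) calls")
    if np.ptp(missing) == 0:
        log.warning("degenerate truncation histogram (single bin); "
                    "returning tail estimate 0")
        return 0.0
    m0, s0 = float(missing.mean()), max(float(missing.std()), 0.5)
    bound = sle_length - 0.5          # continuity correction for rounding

    def nll(params):
        mu, log_sig = params
        sig = math.exp(log_sig)
        z = (missing - mu) / sig
        trunc = stats.norm.logcdf((bound - mu) / sig)
        return float(np.sum(0.5 * z ** 2 + math.log(sig)) + missing.size * trunc)

    res = optimize.minimize(nll, x0=[m0, math.log(s0)], method="Nelder-Mead",
                            options=dict(xatol=1e-6, fatol=1e-9, maxiter=2000))
    mu, sig = res.x[0], math.exp(res.x[1])
    return float(np.clip(stats.norm.sf((bound - mu) / sig), 0.0, 1.0))


def build_consensus(rows, threshold: float = 0.60) -> str:
    """Column-wise consensus of equal-length aligned sequences.

    Emits the base whose frequency is >= ``threshold``; otherwise the IUPAC
    code of all bases above frequency 0.25; otherwise ``N``.  Gap
    characters are ignored in the frequencies; an all-gap column emits
    ``-``.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("sequences must have equal aligned length")
    out = []
    for j in range(len(rows[0])):
        col = [r[j] for r in rows if r[j] in "ACGT"]
        if not col:
            out.append("-")
            continue
        freqs = Counter(col)
        n = len(col)
        base, count = max(freqs.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        if count / n >= threshold:
            out.append(base)
        else:
            above = {b for b, c in freqs.items() if c / n > 0.25}
            out.append(iupac_code(above) if above else "N")
    return "".join(out)


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies over an SLe, 3'-anchored coverage.

    ``freqs`` has one row per base (A, C, G, T) and one column per SLe
    position (1-based from the 5' end in reports); ``coverage`` counts the
    observations informing each column and ``information`` is the column
    information content in bits.
    """

    freqs: pd.DataFrame
    coverage: np.ndarray
    information: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.freqs.T.reset_index(names="position")
        df["position"] = np.arange(1, len(df) + 1)
        df["information_bits"] = self.information
        df["coverage"] = self.coverage
        return df


def position_frequency_matrix(observed_suffixes, sle_length: int
                              ) -> PositionFrequencyMatrix:
    """PFM from 3'-anchored observed SLe suffixes of varying extent.

    Column j (1-based from the SLe 5' end) uses only observations whose
    extent covers j.  Zero-coverage columns are uniform and flagged by
    ``coverage == 0``.
    """
    suffixes = [s for s in observed_suffixes if s]
    counts = np.zeros((4, sle_length))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for s in suffixes:
        ext = len(s)
        for k, ch in enumerate(s):
            j = sle_length - ext + k          # 0-based column
            if ch in base_idx:
                counts[base_idx[ch], j] += 1
    coverage = counts.sum(axis=0)
    freqs = np.full((4, sle_length), 0.25)
    nz = coverage > 0
    freqs[:, nz] = counts[:, nz] / coverage[nz]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    info[~nz] = 0.0
    fdf = pd.DataFrame(freqs, index=list("ACGT"),
                       columns=[f"pos{j + 1}" for j in range(sle_length)])
    return PositionFrequencyMatrix(fdf, coverage.astype(int), info)


def nucleotide_composition(seqs) -> dict[str, float]:
    """A/C/G/T fractions over one sequence or a collection of sequences."""
    if isinstance(seqs, str):
        seqs = [seqs]
    counts = Counter()
    for s in seqs:
        counts.update(s)
    bad = sum(v for b, v in counts.items() if b not in "ACGT")
    if bad:
        log.warning("excluding %d non-ACGT characters from composition", bad)
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("no A/C/G/T characters")
    return {b: counts[b] / total for b in "ACGT"}


@dataclass(frozen=True)
class PartitionSummary:
    """Counts and percentages of the transcriptome SL partition.

    ``type_counts`` covers classified SL types; ``incomplete`` holds hits
    whose observed SLe did not cover the discriminating positions.  Counts
    computed from calls partition the retained transcriptome: no_sl +
    sum(types) + incomplete == total.  Published tallies sometimes state a
    retained total larger than the listed categories (transcripts outside
    the listed bins); such a shortfall is tolerated with a warning, but
    categories exceeding the total are rejected.  ``complete``
    (full-length SLe), isoform pairs and cross-type groups are overlay
    statistics, not partition cells.
    """

    total: int
    no_sl: int
    type_counts: dict[str, int]
    incomplete: int
    complete: int = 0
    isoform_pairs: int = 0
    cross_type: int = 0

    def __post_init__(self):
        cat_sum = self.no_sl + sum(self.type_counts.values()) + self.incomplete
        if cat_sum > self.total:
            raise ValueError("partition categories exceed the total")
        if cat_sum < self.total:
            log.warning("partition categories sum to %d of a stated total "
                        "of %d; %d transcripts unaccounted for",
                        cat_sum, self.total, self.total - cat_sum)

    @property
    def sl_bearing(self) -> int:
        return sum(self.type_counts.values()) + self.incomplete

    def percentages(self, ndigits: int = 2) -> dict[str, float]:
        """Report percentages, half-up rounded.

        Transcriptome-wide rows use the retained total as denominator; the
        within-SL rows (per type, incomplete, complete) use the SL-bearing
        count, matching the usual reporting convention.
        """
        sl = self.sl_bearing
        out = {
            "sl_bearing_pct": pct(sl, self.total, ndigits),
            "no_sl_pct": pct(self.no_sl, self.total, ndigits),
            "incomplete_pct_of_sl": pct(self.incomplete, sl, ndigits),
            "complete_pct_of_sl": pct(self.complete, sl, ndigits),
            "isoform_pairs_pct": pct(self.isoform_pairs, self.total, ndigits),
            "cross_type_pct": pct(self.cross_type, self.total, ndigits),
        }
        for name, k in self.type_counts.items():
            out[f"{name}_pct_of_sl"] = pct(k, sl, ndigits)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", self.total), ("no_sl", self.no_sl)]
        rows += [(k, v) for k, v in self.type_counts.items()]
        rows += [("incomplete", self.incomplete), ("complete", self.complete),
                 ("isoform_pairs", self.isoform_pairs),
                 ("cross_type", self.cross_type)]
        df = pd.DataFrame(rows, columns=["category", "count"])
        p = self.percentages()
        df["percent"] = [
            ".", p["no_sl_pct"],
            *[p[f"{k}_pct_of_sl"] for k in self.type_counts],
            p["incomplete_pct_of_sl"], p["complete_pct_of_sl"],
            p["isoform_pairs_pct"], p["cross_type_pct"]]
        return df


def build_isoform_map(calls) -> dict[str, list[SLCall]]:
    """Group calls by identical body (mature for hits, full for non-hits)."""
    groups: dict[str, list[SLCall]] = defaultdict(list)
    for c in calls:
        groups[c.mature_seq].append(c)
    return {k: v for k, v in groups.items() if len(v) > 1}


def partition_summary(calls, isoform_map: dict | None = None
                      ) -> PartitionSummary:
    """Summarise SL calls into the transcriptome partition.

    ``isoform_map`` groups body-identical transcripts; groups containing
    both a hit-bearing and a no-hit member count as SL+/- pairs, groups
    containing two distinct SL types as cross-type shared.
    """
    ids = [c.transcript_id for c in calls]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate calls for a transcript")
    type_counts: Counter = Counter()
    no_sl = incomplete = complete = 0
    for c in calls:
        if c.sl_type == "none":
            no_sl += 1
        elif c.sl_type == "incomplete":
            incomplete += 1
        else:
            type_counts[c.sl_type] += 1
        if c.complete:
            complete += 1
    pairs = cross = 0
    for members in (isoform_map or {}).values():
        kinds = {m.sl_type for m in members}
        if "none" in kinds and kinds - {"none"}:
            pairs += 1
        named = kinds - {"none", "incomplete"}
        if len(named) >= 2:
            cross += 1
    return PartitionSummary(len(calls), no_sl, dict(type_counts), incomplete,
                            complete, pairs, cross)
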