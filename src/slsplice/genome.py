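"""SL-RNA gene discovery in genomic contigs.

The scan finds full-coverage, high-identity copies of an SL exon on either
strand of each contig, then applies the SL-RNA validation rules: the two
nucleotides after the exon must be the GT splice donor, at least a minimum
intron length must follow, and a CT-poly-T terminator tract must occur
within a window downstream of the donor.  The exon-terminal base plus the
next three nucleotides (the conserved GGTA cleavage-site motif) are
recorded but not required.  Validated candidates are deduplicated by full
sequence, reported with tandem-array context, scanned for Sm-binding-site
variant motifs, and trans-splicing of transcripts is verified by the
genomic absence of the SLe upstream of the gene locus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp
from .align import smith_waterman_local
from .io import SequenceRecord
from .synthetic import SLSystemSpec

#: Poly-T terminator patterns: (C)(T-run)(terminal base) triples.
DEFAULT_POLYT_PATTERNS = (
    ("CT4-6_GC", re.compile(r"CT{4,6}[GC]")),      # M. nigrum / P. sinerae
    ("CT5_A", re.compile(r"CT{5}A")),              # SPI agent
    ("CT4-7_GA", re.compile(r"CT{4,7}[GA]")),      # dinoflagellate-style
)

#: Sm-binding-site variant motifs reported across SL systems.
SM_MOTIF_PATTERNS = (
    ("AT4GG", re.compile(r"AT{4}GG")),
    ("RAT4-6GR", re.compile(r"[AG]AT{4,6}G[AG]")),
    ("AT4CGG", re.compile(r"AT{4}CGG")),
    ("AGCT3GG", re.compile(r"AGCT{3}GG")),
    ("AAYTYTGA", re.compile(r"AA[CT]T[CT]TGA")),
)


@dataclass(frozen=True)
class ExonHit:
    """A full-coverage gapless SLe match on a contig (forward coords)."""

    contig_id: str
    strand: str
    start: int
    end: int
    mismatches: int
    pid: float
    sl_type: str = ""


@dataclass(frozen=True)
class SLRNACandidate:
    """A validated SLe-SLi ORF locus.

    Intervals are 0-based half-open in forward-strand contig coordinates;
    ``seq`` is in the sense (exon-bearing) orientation.  ``total_length``
    runs from the exon start through the end of the poly-T tract.
    """

    contig_id: str
    strand: str
    sl_type: str
    exon_interval: tuple[int, int]
    intron_interval: tuple[int, int]
    donor_ok: bool
    boundary_motif: str
    polyt_interval: tuple[int, int]
    polyt_pattern: str
    total_length: int
    exon_pid: float
    seq: str


def short_match_search(query: str, contigs, min_pid: float = 0.95,
                       min_query_coverage: float = 1.0,
                       sl_type: str = "") -> list[ExonHit]:
    """Find gapless full-length copies of ``query`` on both contig strands.

    Matching is substitution-only at full query coverage — at the short
    lengths and high identities used here an indel already drops identity
    below threshold, so gapless matching is equivalent and exactly
    reproducible.  Hits are sorted by contig then position.
    """
    if len(query) < 16:
        raise ValueError("query too short (< 16 nt)")
    if min_query_coverage != 1.0:
        raise ValueError("only full query coverage (1.0) is supported")
    if not contigs:
        raise ValueError("empty genome")
    L = len(query)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    max_mm = int(np.floor((1.0 - min_pid) * L + 1e-9))
    hits: list[ExonHit] = []
    for rec in contigs:
        n = len(rec.seq)
        if n < L:
            continue
        for strand, seq in (("+", rec.seq), ("-", revcomp(rec.seq))):
            s = np.frombuffer(seq.encode(), dtype=np.uint8)
            mm = np.zeros(n - L + 1, dtype=np.int32)
            for j in range(L):
                mm += s[j:j + n - L + 1] != q[j]
            for i in np.nonzero(mm <= max_mm)[0]:
                start, end = (int(i), int(i) + L) if strand == "+" \
                    else (n - int(i) - L, n - int(i))
                hits.append(ExonHit(rec.id, strand, start, end,
                                    int(mm[i]), (L - int(mm[i])) / L, sl_type))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def find_polyt_tract(seq: str, window: int = 120,
                     patterns=DEFAULT_POLYT_PATTERNS):
    """Leftmost poly-T terminator match within ``seq[:window]``.

    Returns ``(start, end, pattern_id)`` or ``None``; absence is a valid
    result.
    """
    if window < 6:
        raise ValueError("window too small")
    region = seq[:window]
    best = None
    for name, pat in patterns:
        m = pat.search(region)
        if m and (best is None or m.start() < best[0]):
            best = (m.start(), m.end(), name)
    return best


def validate_candidate(hit: ExonHit, contig: SequenceRecord,
                       min_intron: int = 40, polyt_window: int = 120,
                       patterns=DEFAULT_POLYT_PATTERNS):
    """Apply the SL-RNA validation rules to an exon hit.

    Returns ``(SLRNACandidate, None)`` on acceptance or ``(None, reason)``
    with reason in {"donor", "intron_length", "polyT"}.
    """
    n = len(contig.seq)
    if not (0 <= hit.start < hit.end <= n):
        raise ValueError("hit interval outside contig")
    oriented = contig.seq if hit.strand == "+" else revcomp(contig.seq)
    if hit.strand == "+":
        o_start, o_end = hit.start, hit.end
    else:
        o_start, o_end = n - hit.end, n - hit.start
    after = oriented[o_end:]
    if len(after) < min_intron:
        return None, "intron_length"
    if after[:2] != "GT":
        return None, "donor"
    tract = find_polyt_tract(after, polyt_window, patterns)
    if tract is None:
        return None, "polyT"
    t_start, t_end, pattern = tract
    exon_len = hit.end - hit.start
    boundary = oriented[o_end - 1:o_end + 3]
    intron_o = (o_end, o_end + t_end)
    polyt_o = (o_end + t_start, o_end + t_end)

    def fwd(iv):
        return iv if hit.strand == "+" else (n - iv[1], n - iv[0])

    cand = SLRNACandidate(
        contig_id=contig.id, strand=hit.strand, sl_type=hit.sl_type,
        exon_interval=(hit.start, hit.end), intron_interval=fwd(intron_o),
        donor_ok=True, boundary_motif=boundary, polyt_interval=fwd(polyt_o),
        polyt_pattern=pattern, total_length=exon_len + t_end,
        exon_pid=hit.pid, seq=oriented[o_start:o_end + t_end])
    return cand, None


def deduplicate_candidates(candidates) -> list[tuple[SLRNACandidate, int]]:
    """Collapse candidates with identical full sequence, keeping counts."""
    seen: dict[str, int] = {}
    reps: dict[str, SLRNACandidate] = {}
    for c in candidates:
        if c.seq in seen:
            seen[c.seq] += 1
        else:
            seen[c.seq] = 1
            reps[c.seq] = c
    return [(reps[s], k) for s, k in seen.items()]


@dataclass
class ScanResult:
    """Validated SL-RNA candidates plus bookkeeping.

    ``validated`` keeps every accepted locus with its own interval;
    ``candidates`` is the sequence-deduplicated view with multiplicities.
    """

    candidates: list[tuple[SLRNACandidate, int]]
    counts: dict[str, int]                      # validated loci per SL type
    validated: list[SLRNACandidate] = field(default_factory=list)
    rejections: list[tuple[ExonHit, str]] = field(default_factory=list)


def scan_genome(system: SLSystemSpec, contigs, min_pid: float = 0.95,
                min_intron: int = 40, polyt_window: int = 120) -> ScanResult:
    """Search, validate and deduplicate SL-RNA loci for every SLe type."""
    validated: list[SLRNACandidate] = []
    rejections = []
    counts: dict[str, int] = {}
    by_id = {c.id: c for c in contigs}
    for t in system.types:
        n_ok = 0
        for hit in short_match_search(t.sle, contigs, min_pid,
                                      sl_type=t.name):
            cand, reason = validate_candidate(hit, by_id[hit.contig_id],
                                              min_intron, polyt_window)
            if cand is not None:
                validated.append(cand)
                n_ok += 1
            else:
                rejections.append((hit, reason))
        counts[t.name] = n_ok
    return ScanResult(deduplicate_candidates(validated), counts, validated,
                      rejections)


def tandem_context_report(result: ScanResult, contigs,
                          marker: SequenceRecord | None = None,
                          marker_min_pid: float = 0.95) -> pd.DataFrame:
    """Per-contig candidate layout: ordered intervals, gaps, marker distance.

    For contigs carrying >= 2 validated loci the inter-copy gaps are
    reported; if a marker sequence (e.g. the 5S rRNA gene) is supplied and
    found, the distance from each locus to the nearest marker copy is
    added.
    """
    expanded = list(result.validated) or [c for c, _ in result.candidates]
    marker_hits: dict[str, list[tuple[int, int]]] = {}
    if marker is not None:
        for h in short_match_search(marker.seq, contigs, marker_min_pid):
            marker_hits.setdefault(h.contig_id, []).append((h.start, h.end))
    rows = []
    by_contig: dict[str, list[SLRNACandidate]] = {}
    for cand in expanded:
        by_contig.setdefault(cand.contig_id, []).append(cand)
    for contig_id in sorted(by_contig):
        cands = sorted(by_contig[contig_id], key=lambda c: c.exon_interval[0])
        for i, cand in enumerate(cands):
            gap = cands[i + 1].exon_interval[0] - (cand.exon_interval[0]
                                                   + cand.total_length) \
                if i + 1 < len(cands) else None
            mdist = None
            if contig_id in marker_hits:
                lo = cand.exon_interval[0]
                hi = lo + cand.total_length
                # nearest-edge gap (0 when the marker touches the locus)
                mdist = min(max(ms - hi, lo - me, 0)
                            for ms, me in marker_hits[contig_id])
            rows.append(dict(contig=contig_id, sl_type=cand.sl_type,
                             start=cand.exon_interval[0],
                             end=cand.exon_interval[0] + cand.total_length,
                             strand=cand.strand, n_on_contig=len(cands),
                             gap_to_next=gap, marker_distance=mdist))
    return pd.DataFrame(rows, columns=["contig", "sl_type", "start", "end",
                                       "strand", "n_on_contig", "gap_to_next",
                                       "marker_distance"])


def sm_motif_scan(candidate: SLRNACandidate,
                  patterns=SM_MOTIF_PATTERNS) -> list[tuple[str, tuple[int, int], str]]:
    """Scan a candidate's sequence for Sm-binding-site variant motifs.

    Intervals are relative to the candidate sequence (exon start = 0);
    the region label says whether the match starts in the exon or intron.
    An empty list is a valid result.
    """
    exon_len = candidate.exon_interval[1] - candidate.exon_interval[0]
    out = []
    for name, pat in patterns:
        for m in pat.finditer(candidate.seq):
            region = "exon" if m.start() < exon_len else "intron"
            out.append((name, (m.start(), m.end()), region))
    out.sort(key=lambda x: (x[1][0], x[0]))
    return out


@dataclass(frozen=True)
class TransSpliceVerification:
    """Genomic check that an SL is added post-transcriptionally.

    ``status`` is ``confirmed`` (gene locus found, SLe absent from the
    upstream window), ``cis_encoded`` (SLe genomically present upstream)
    or ``unmapped``.
    """

    transcript_id: str
    status: str
    contig_id: str = ""
    pid: float = 0.0
    locus_interval: tuple[int, int] = (0, 0)
    sle_in_genomic_5utr: bool = False
    acceptor_ag_offset: int | None = None     # relative to locus start, < 0
    start_codon_offset: int | None = None     # relative to locus start, >= 0


def verify_trans_splicing(transcript_id: str, mature_seq: str, system,
                          contigs, min_pid: float = 0.95,
                          upstream_window: int = 200) -> TransSpliceVerification:
    """Locate the gene locus of an SL-trimmed transcript and test for a
    cis-encoded SLe in its genomic 5' region.

    The mature (SL-trimmed) sequence is locally aligned against every
    contig; the best hit with pid >= ``min_pid`` defines the locus.  The
    SLe (any type, full coverage, pid >= 0.95) is then searched in the
    ``upstream_window`` nucleotides upstream; verification is confirmed iff
    it is absent.  The nearest upstream AG dinucleotide (candidate splice
    acceptor) and the first downstream ATG are reported.
    """
    best = None
    for contig in contigs:
        res = smith_waterman_local(mature_seq, contig.seq,
                                   query_id=transcript_id,
                                   subject_id=contig.id)
        if res.aligned_length == 0:
            continue
        if best is None or res.score > best[0].score:
            best = (res, contig)
    if best is None or best[0].pid < min_pid \
            or best[0].aligned_length < min(len(mature_seq), 50):
        return TransSpliceVerification(transcript_id, "unmapped")
    res, contig = best
    n = len(contig.seq)
    oriented = contig.seq if res.strand == "+" else revcomp(contig.seq)
    if res.strand == "+":
        s_start, s_end = res.subject_interval
    else:
        s_start, s_end = n - res.subject_interval[1], n - res.subject_interval[0]
    up = oriented[max(0, s_start - upstream_window):s_start]
    sle_upstream = False
    if len(up) >= system.sle_length:
        fake = [SequenceRecord("up", up)]
        for t in system.types:
            if short_match_search(t.sle, fake, 0.95):
                sle_upstream = True
                break
    ag = up.rfind("AG")
    acceptor = ag - len(up) if ag >= 0 else None
    atg = oriented.find("ATG", s_start)
    start_codon = atg - s_start if atg >= 0 else None
    status = "cis_encoded" if sle_upstream else "confirmed"
    return TransSpliceVerification(
        transcript_id, status, contig.id, res.pid, res.subject_interval,
        sle_upstream, acceptor, start_codon)


def candidates_table(result: ScanResult) -> pd.DataFrame:
    rows = []
    for cand, mult in result.candidates:
        rows.append(dict(contig=cand.contig_id, strand=cand.strand,
                         sl_type=cand.sl_type,
                         exon_start=cand.exon_interval[0],
                         exon_end=cand.exon_interval[1],
                         intron_start=cand.intron_interval[0],
                         intron_end=cand.intron_interval[1],
                         polyt_start=cand.polyt_interval[0],
                         polyt_end=cand.polyt_interval[1],
                         polyt_pattern=cand.polyt_pattern,
                         boundary_motif=cand.boundary_motif,
                         total_length=cand.total_length,
                         exon_pid=cand.exon_pid, multiplicity=mult,
                         seq=cand.seq))
    return pd.DataFrame(rows)


def candidates_to_gff3(result: ScanResult) -> str:
    """GFF3 rendering of validated candidates (1-based inclusive coords)."""
    lines = ["##gff-version 3"]
    for i, (cand, mult) in enumerate(result.candidates, 1):
        feats = [("SL_exon", cand.exon_interval),
                 ("SL_intron", cand.intron_interval),
                 ("polyT_tract", cand.polyt_interval)]
        for ftype, (s, e) in feats:
            attrs = f"ID=slrna{i}_{ftype};sl_type={cand.sl_type};multiplicity={mult}"
            lines.append("\t".join([cand.contig_id, "slsplice", ftype,
                                    str(s + 1), str(e), ".", cand.strand,
                                    ".", attrs]))
    return "\n".join(lines) + "\n"
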