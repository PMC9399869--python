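"""Synthetic genomes, transcriptomes, counts and GO annotations with truth.

The generator emulates the statistical structure the analysis assumes for
Perkinsozoa-like spliced-leader (SL) trans-splicing systems:

* transcripts carrying one of the system's SL exon (SLe) types at the 5'
  end, with 5'-truncation noise removing a normally distributed number of
  leading nucleotides (the dominant artefact of RNA-seq transcript-end
  sampling);
* non-SL transcripts and rare SL+/- isoform pairs sharing a body sequence;
* genomic SL-RNA loci laid out as SLe + GT splice donor + intron +
  CT-poly-T terminator, optionally in tandem arrays, plus decoy loci with a
  broken donor or missing terminator;
* gene loci whose genomic 5'UTR lacks the SLe but carries an acceptor AG
  (and cis-encoded decoys that carry the SLe genomically);
* per-transcript abundance with a multiplicative shift for the first SL
  type, and GO annotations with planted per-pool enriched terms.

All draws come from a single ``numpy.random.Generator`` seeded explicitly,
so every bundle is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import revcomp
from .io import SequenceRecord, write_fasta, write_tsv

#: Shared SLe 5' decamer and 3' octamer across Perkinsozoa-like systems.
SLE_PREFIX = "ACCGTAGCCA"
SLE_SUFFIX = "GGCTCAAG"          # ends with the AAG terminal triplet
SL_MOTIF = SLE_SUFFIX            # conserved 3'-terminal octamer searched for

#: Published reference SL exons usable as phylogeny outgroups/companions.
REFERENCE_SLES = {
    "P_marinus_22nt": "ACCGTAGCCATCTTGGCTCAAG",
    "P_marinus_21nt": "ACCGTAGCCATCTGGCTCAAG",
    "dinoflagellate": "ACCGTAGCCATTTTGGCTCAAG",
}


@dataclass(frozen=True)
class SLType:
    """One SL exon type: its full sequence and discriminating positions.

    ``discriminating`` maps 1-based positions (from the SLe 5' end) to the
    type-specific nucleotide at that position.
    """

    name: str
    sle: str
    discriminating: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        for pos, base in self.discriminating.items():
            if not (1 <= pos <= len(self.sle)):
                raise ValueError(f"discriminating position {pos} outside SLe")
            if self.sle[pos - 1] != base:
                raise ValueError(f"SLe of {self.name} disagrees at position {pos}")


@dataclass(frozen=True)
class SLSystemSpec:
    """A species' SL system: its SLe types and SL-RNA gene layout."""

    species: str
    types: tuple[SLType, ...]
    intron_length: int            # nt from exon end through the poly-T tract
    polyt_tract: str              # terminator sequence planted in loci
    motif: str = SL_MOTIF         # conserved 3'-terminal SLe octamer

    @property
    def sle_length(self) -> int:
        return len(self.types[0].sle)

    @property
    def multi_type(self) -> bool:
        return len(self.types) > 1

    def __post_init__(self):
        for t in self.types:
            if len(t.sle) < 18:
                raise ValueError("SLe must be >= 18 nt (decamer + octamer)")
            if not t.sle.startswith(SLE_PREFIX) or not t.sle.endswith(SLE_SUFFIX):
                raise ValueError(f"SLe of {t.name} lacks the shared 5'/3' ends")


def generate_sl_system(kind: str = "psinerae", seed: int | None = None,
                       alleles: tuple[str, str] = ("TT", "CA")) -> SLSystemSpec:
    """Build a default SL system spec.

    ``psinerae``: two 28 nt SLe types identical except at positions 13-14
    (default alleles TT vs CA; the true alleles are a free parameter).
    ``maranthos``: one 25 nt type.  ``spi``: one 22 nt type.  Total SL-RNA
    locus lengths (exon + intron incl. poly-T) default to 68, 60 and 66 nt
    respectively.  ``seed`` is accepted for interface symmetry; the default
    systems are fully deterministic.
    """
    if kind == "psinerae":
        mid = "TC{}ATCAGT"
        types = tuple(
            SLType(f"type{i + 1}",
                   SLE_PREFIX + mid.format(al) + SLE_SUFFIX,
                   {13: al[0], 14: al[1]})
            for i, al in enumerate(alleles)
        )
        return SLSystemSpec("P. sinerae-like", types, intron_length=40,
                            polyt_tract="CTTTTG")
    if kind == "maranthos":
        t = SLType("single", SLE_PREFIX + "TCAATCA" + SLE_SUFFIX)
        return SLSystemSpec("M. nigrum-like", (t,), intron_length=35,
                            polyt_tract="CTTTTG")
    if kind == "spi":
        t = SLType("single", SLE_PREFIX + "TCTT" + SLE_SUFFIX)
        return SLSystemSpec("SPI-like", (t,), intron_length=44,
                            polyt_tract="CTTTTTA")
    raise ValueError(f"unknown SL system kind: {kind!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic bundle.

    Fractions refer to the transcriptome partition (per SL type, remainder
    non-SL); the truncation model is the number of missing 5' nucleotides,
    drawn normal, rounded and clipped to [0, SLe length].
    """

    n_transcripts: int = 2000
    sl_fractions: tuple[float, ...] | None = None   # per type; default below
    isoform_pair_fraction: float = 0.005
    cross_type_pairs: int = 0
    truncation_mean: float = 6.0
    truncation_sd: float = 4.0
    body_length_range: tuple[int, int] = (200, 800)
    # genome
    n_contigs: int = 4
    contig_length: int = 12000
    loci_per_type: tuple[int, ...] | None = None    # default (3, 1) / (3,)
    tandem_array_size: int = 1
    tandem_spacer: int = 100
    decoy_donor: int = 1
    decoy_polyt: int = 1
    n_gene_loci: int = 3
    n_cis_decoys: int = 1
    # abundance (log-normal on the natural-log scale)
    abundance_mu: float = 2.0
    abundance_sigma: float = 1.0
    shift_type1: float = 2.0
    n_samples: int = 3
    sample_noise_sigma: float = 0.15
    # GO model
    go_n_terms: int = 50
    go_bg_freq: float = 0.05
    go_planted_fold: float = 4.0
    go_planted_per_pool: int = 1

    def resolved_fractions(self, system: SLSystemSpec) -> tuple[float, ...]:
        if self.sl_fractions is not None:
            fr = self.sl_fractions
        else:
            fr = (0.5, 0.14)[:len(system.types)]
        if len(fr) != len(system.types):
            raise ValueError("one fraction per SL type required")
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1:
            raise ValueError("fractions must lie in [0,1] and sum <= 1")
        return tuple(fr)

    def resolved_loci(self, system: SLSystemSpec) -> tuple[int, ...]:
        loci = self.loci_per_type if self.loci_per_type is not None \
            else (3, 1)[:len(system.types)]
        if len(loci) != len(system.types):
            raise ValueError("one locus count per SL type required")
        return tuple(loci)


@dataclass
class SyntheticBundle:
    """A generated dataset plus its ground truth."""

    system: SLSystemSpec
    transcripts: list[SequenceRecord]
    contigs: list[SequenceRecord]
    counts: pd.DataFrame            # transcript_id, sample cols, effective_length
    go: pd.DataFrame                # transcript_id, term
    truth_transcripts: pd.DataFrame
    truth_loci: pd.DataFrame
    truth_terms: pd.DataFrame       # pool, term, fold


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _clean_random_seq(rng: np.random.Generator, length: int,
                      forbidden: tuple[str, ...]) -> str:
    """Random sequence free of the given substrings (rejection sampling)."""
    for _ in range(200):
        s = _random_seq(rng, length)
        if not any(f in s for f in forbidden):
            return s
    raise RuntimeError("could not generate clean random sequence")


_FORBIDDEN_TX = (SL_MOTIF, revcomp(SL_MOTIF))
# Intron filler must not create an early poly-T terminator match.
_FORBIDDEN_INTRON = _FORBIDDEN_TX + ("TTTT",)


def build_locus(system: SLSystemSpec, sl_type: SLType,
                rng: np.random.Generator,
                break_donor: bool = False,
                drop_polyt: bool = False) -> str:
    """One SL-RNA locus: SLe + GTA (donor) + filler + poly-T terminator.

    The exon-terminal G plus the intron-initial GTA form the conserved GGTA
    cleavage-site motif.  ``break_donor`` mutates the donor GT to CT and
    ``drop_polyt`` replaces the terminator with clean filler, producing
    decoys that must fail validation.
    """
    tract = system.polyt_tract
    filler_len = system.intron_length - 3 - len(tract)
    if filler_len < 0:
        raise ValueError("intron too short for donor and poly-T tract")
    donor = "CTA" if break_donor else "GTA"
    filler = _clean_random_seq(rng, filler_len, _FORBIDDEN_INTRON)
    guard = ""
    if drop_polyt:
        tract = _clean_random_seq(rng, len(tract), _FORBIDDEN_INTRON)
        # guard region keeps chance downstream T-runs out of the search window
        guard = _clean_random_seq(rng, 140, _FORBIDDEN_INTRON)
    return sl_type.sle + donor + filler + tract + guard


def generate_genome(system: SLSystemSpec, config: GeneratorConfig, seed: int,
                    gene_inserts: list[tuple[str, str, str]] | None = None
                    ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate contigs with planted SL-RNA loci, decoys and gene loci.

    ``gene_inserts`` is a list of ``(transcript_id, mature_body, kind)`` with
    kind ``gene`` (5'UTR lacks the SLe, acceptor AG planted immediately
    upstream) or ``cis_gene`` (SLe genomically encoded upstream — a decoy
    for the trans-splicing verification).  Returns the contigs and a truth
    table of all planted features (0-based half-open intervals, + strand).
    """
    rng = np.random.default_rng(seed)
    inserts: list[tuple[str, str, str, str]] = []   # (seq, kind, sl_type, tx_id)
    loci_counts = config.resolved_loci(system)
    for sl_type, n_loci in zip(system.types, loci_counts):
        for i in range(n_loci):
            if config.tandem_array_size > 1:
                copies = [build_locus(system, sl_type, rng)
                          for _ in range(config.tandem_array_size)]
                spacers = [_clean_random_seq(rng, config.tandem_spacer,
                                             _FORBIDDEN_INTRON)
                           for _ in copies[:-1]]
                seqs = [copies[0]]
                for sp, cp in zip(spacers, copies[1:]):
                    seqs += [sp, cp]
                inserts.append(("".join(seqs), "slrna_array", sl_type.name, ""))
            else:
                inserts.append((build_locus(system, sl_type, rng),
                                "slrna", sl_type.name, ""))
    first = system.types[0]
    for _ in range(config.decoy_donor):
        inserts.append((build_locus(system, first, rng, break_donor=True),
                        "decoy_donor", first.name, ""))
    for _ in range(config.decoy_polyt):
        inserts.append((build_locus(system, first, rng, drop_polyt=True),
                        "decoy_polyt", first.name, ""))
    for tx_id, body, kind in (gene_inserts or []):
        if kind == "gene":
            # Outron-like 5'UTR: acceptor AG immediately upstream of the body.
            utr = _clean_random_seq(rng, 60, _FORBIDDEN_TX) + "AG"
            inserts.append((utr + body, kind, "", tx_id))
        elif kind == "cis_gene":
            utr = _clean_random_seq(rng, 40, _FORBIDDEN_TX) + first.sle + "AG"
            inserts.append((utr + body, kind, first.name, tx_id))
        else:
            raise ValueError(f"unknown gene insert kind {kind!r}")

    total_insert = sum(len(s) for s, *_ in inserts)
    capacity = config.n_contigs * config.contig_length
    if total_insert + 200 * len(inserts) > capacity:
        raise ValueError("contigs too short to host the requested loci")

    contig_seqs = [_clean_random_seq(rng, config.contig_length, _FORBIDDEN_TX)
                   for _ in range(config.n_contigs)]
    truth_rows = []
    order = rng.permutation(len(inserts))
    cursor = [100] * config.n_contigs
    for k, idx in enumerate(order):
        seq, kind, type_name, tx_id = inserts[idx]
        c = k % config.n_contigs
        start = cursor[c]
        if start + len(seq) + 100 > config.contig_length:
            raise ValueError("contigs too short to host the requested loci")
        contig_seqs[c] = (contig_seqs[c][:start] + seq
                          + contig_seqs[c][start + len(seq):])
        gap = int(rng.integers(120, 300))
        cursor[c] = start + len(seq) + gap
        if kind == "slrna_array":
            # record every copy of the array individually
            locus_len = (len(seq) - (config.tandem_array_size - 1)
                         * config.tandem_spacer) // config.tandem_array_size
            for j in range(config.tandem_array_size):
                s = start + j * (locus_len + config.tandem_spacer)
                truth_rows.append(dict(contig=f"contig{c + 1}", start=s,
                                       end=s + locus_len, kind="slrna",
                                       sl_type=type_name, transcript_id="."))
        else:
            truth_rows.append(dict(contig=f"contig{c + 1}", start=start,
                                   end=start + len(seq), kind=kind,
                                   sl_type=type_name or ".",
                                   transcript_id=tx_id or "."))
    contigs = [SequenceRecord(f"contig{i + 1}", s)
               for i, s in enumerate(contig_seqs)]
    truth = pd.DataFrame(truth_rows,
                         columns=["contig", "start", "end", "kind", "sl_type",
                                  "transcript_id"])
    return contigs, truth.sort_values(["contig", "start"]).reset_index(drop=True)


def generate_transcriptome(system: SLSystemSpec, config: GeneratorConfig,
                           seed: int) -> SyntheticBundle:
    """Generate transcripts, counts, GO annotations and truth (no genome)."""
    rng = np.random.default_rng(seed)
    fractions = config.resolved_fractions(system)
    n = config.n_transcripts
    counts_per_type = [int(round(f * n)) for f in fractions]
    labels = []
    for t, k in zip(system.types, counts_per_type):
        labels += [t.name] * k
    labels += ["none"] * (n - len(labels))
    type_by_name = {t.name: t for t in system.types}
    L = system.sle_length

    lo, hi = config.body_length_range
    records: list[SequenceRecord] = []
    rows = []
    for i, lab in enumerate(labels):
        tx_id = f"tx{i + 1:05d}"
        body = _clean_random_seq(rng, int(rng.integers(lo, hi + 1)),
                                 _FORBIDDEN_TX)
        if lab == "none":
            seq, trunc, final = body, ".", "none"
        else:
            trunc = int(np.clip(round(rng.normal(config.truncation_mean,
                                                 config.truncation_sd)), 0, L))
            sle = type_by_name[lab].sle
            if trunc >= L:
                seq, final = body, "none_by_truncation"
            else:
                seq, final = sle[trunc:] + body, lab
        records.append(SequenceRecord(tx_id, seq))
        rows.append(dict(transcript_id=tx_id, true_type=lab, label=final,
                         truncation=trunc, isoform_group="."))

    # SL+/- isoform pairs: duplicate the body of some SL-bearing transcripts.
    sl_idx = [i for i, r in enumerate(rows) if r["true_type"] != "none"]
    n_pairs = int(round(config.isoform_pair_fraction * len(sl_idx)))
    for j, i in enumerate(rng.choice(sl_idx, size=n_pairs, replace=False)):
        donor = records[i]
        trunc = rows[i]["truncation"]
        sle_len_present = 0 if rows[i]["label"] in ("none", "none_by_truncation") \
            else L - int(trunc)
        body = donor.seq[sle_len_present:]
        tx_id = f"tx{i + 1:05d}iso"
        records.append(SequenceRecord(tx_id, body))
        group = f"grp{j + 1:03d}"
        rows.append(dict(transcript_id=tx_id, true_type="none", label="none",
                         truncation=".", isoform_group=group))
        rows[i]["isoform_group"] = group

    # Cross-type pairs: same body carrying each of two SL types (multi-type).
    if config.cross_type_pairs and system.multi_type:
        for j in range(config.cross_type_pairs):
            body = _clean_random_seq(rng, int(rng.integers(lo, hi + 1)),
                                     _FORBIDDEN_TX)
            group = f"xgrp{j + 1:03d}"
            for t in system.types[:2]:
                tx_id = f"tx_x{j + 1:03d}_{t.name}"
                records.append(SequenceRecord(tx_id, t.sle + body))
                rows.append(dict(transcript_id=tx_id, true_type=t.name,
                                 label=t.name, truncation=0,
                                 isoform_group=group))

    truth = pd.DataFrame(rows)

    # Abundance: log-normal base, multiplicative shift for the first SL type.
    shifted = system.types[0].name
    base = np.exp(rng.normal(config.abundance_mu, config.abundance_sigma,
                             len(records)))
    base[truth["true_type"].to_numpy() == shifted] *= config.shift_type1
    counts = pd.DataFrame({"transcript_id": [r.id for r in records]})
    for s in range(config.n_samples):
        noise = np.exp(rng.normal(0.0, config.sample_noise_sigma, len(records)))
        counts[f"s{s + 1}"] = np.round(base * noise, 2)
    counts["effective_length"] = [len(r) for r in records]
    truth["abundance"] = base

    # GO annotations: i.i.d. background, planted terms enriched per pool.
    terms = [f"GO:{i + 1:07d}" for i in range(config.go_n_terms)]
    planted_rows = []
    planted: dict[str, list[str]] = {}
    ti = 0
    for t in system.types:
        pool_terms = terms[ti:ti + config.go_planted_per_pool]
        ti += config.go_planted_per_pool
        planted[t.name] = pool_terms
        for term in pool_terms:
            planted_rows.append(dict(pool=t.name, term=term,
                                     fold=config.go_planted_fold))
    go_rows = []
    label_arr = truth["label"].to_numpy()
    for term in terms:
        p_bg = config.go_bg_freq
        probs = np.full(len(records), p_bg)
        for pool, pool_terms in planted.items():
            if term in pool_terms:
                probs[label_arr == pool] = min(1.0, config.go_planted_fold * p_bg)
        hits = rng.random(len(records)) < probs
        for r, h in zip(records, hits):
            if h:
                go_rows.append((r.id, term))
    go = pd.DataFrame(go_rows, columns=["transcript_id", "term"])

    return SyntheticBundle(system, records, [], counts, go, truth,
                           pd.DataFrame(columns=["contig", "start", "end",
                                                 "kind", "sl_type",
                                                 "transcript_id"]),
                           pd.DataFrame(planted_rows,
                                        columns=["pool", "term", "fold"]))


def generate_bundle(system: SLSystemSpec | None = None,
                    config: GeneratorConfig | None = None,
                    seed: int = 0, with_genome: bool = True) -> SyntheticBundle:
    """Generate a full bundle: transcriptome, counts, GO, genome and truth."""
    system = system or generate_sl_system()
    config = config or GeneratorConfig()
    bundle = generate_transcriptome(system, config, seed)
    if with_genome:
        # Plant gene loci for SL-bearing transcripts (their SL-trimmed bodies)
        # so the trans-splicing verification has genomic targets.
        classified = bundle.truth_transcripts
        rng = np.random.default_rng(seed + 1)
        sl_rows = classified[classified["label"].isin(
            [t.name for t in system.types])]
        ids = list(sl_rows["transcript_id"])[:config.n_gene_loci
                                             + config.n_cis_decoys]
        by_id = {r.id: r for r in bundle.transcripts}
        L = system.sle_length
        inserts = []
        for k, tx_id in enumerate(ids):
            row = classified[classified["transcript_id"] == tx_id].iloc[0]
            present = L - int(row["truncation"])
            body = by_id[tx_id].seq[present:]
            kind = "gene" if k < config.n_gene_loci else "cis_gene"
            inserts.append((tx_id, body, kind))
        contigs, loci = generate_genome(system, config, seed + 2, inserts)
        bundle.contigs = contigs
        bundle.truth_loci = loci
    return bundle


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write a bundle to disk: FASTA, TSV tables and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.transcripts, outdir / "transcripts.fasta")
    if bundle.contigs:
        write_fasta(bundle.contigs, outdir / "genome.fasta")
    write_tsv(bundle.counts, outdir / "counts.tsv")
    write_tsv(bundle.go, outdir / "go.tsv")
    write_tsv(bundle.truth_transcripts, outdir / "truth_transcripts.tsv")
    write_tsv(bundle.truth_loci, outdir / "truth_loci.tsv")
    write_tsv(bundle.truth_terms, outdir / "truth_terms.tsv")
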