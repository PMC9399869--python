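"""SL-RNA gene discovery: search, validation rules, context, verification."""

import numpy as np
import pytest

from slsplice import (GeneratorConfig, SequenceRecord, detect_all,
                      deduplicate_candidates, find_polyt_tract,
                      generate_bundle, generate_genome, scan_genome,
                      short_match_search, sm_motif_scan,
                      tandem_context_report, validate_candidate,
                      verify_trans_splicing)
from slsplice._util import revcomp
from slsplice.genome import ExonHit
from slsplice.synthetic import build_locus


def _contig(seq, cid="c1"):
    return SequenceRecord(cid, seq)


def _mutate(seq, pos, base):
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1:]


@pytest.fixture(scope="module")
def sle(psinerae):
    return psinerae.types[0].sle


class TestShortMatchSearch:
    def test_exact_planted_copy(self, sle, rng):
        bg = "".join(rng.choice(list("ACGT"), 500))
        contig = _contig(bg[:200] + sle + bg[200:])
        hits = short_match_search(sle, [contig])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.pid, h.strand) == (200, 228, 1.0, "+")

    def test_one_mismatch_retained_two_rejected(self, sle, rng):
        bg = "".join(rng.choice(list("ACGT"), 300))
        one = _mutate(sle, 5, {"A": "C"}.get(sle[5], "A"))
        two = _mutate(one, 20, {"A": "C"}.get(one[20], "A"))
        c_one = _contig(bg[:100] + one + bg[100:], "one")
        c_two = _contig(bg[:100] + two + bg[100:], "two")
        hits = short_match_search(sle, [c_one, c_two], min_pid=0.95)
        assert [h.contig_id for h in hits] == ["one"]
        assert hits[0].pid == pytest.approx(27 / 28)

    def test_reverse_strand_found(self, sle, rng):
        bg = "".join(rng.choice(list("ACGT"), 300))
        contig = _contig(bg[:150] + revcomp(sle) + bg[150:])
        hits = short_match_search(sle, [contig])
        assert len(hits) == 1 and hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (150, 178)

    def test_empty_genome_rejected(self, sle):
        with pytest.raises(ValueError):
            short_match_search(sle, [])


class TestPolyT:
    def test_spi_pattern(self):
        hit = find_polyt_tract("AAGGCTTTTTAGGAA")
        assert hit is not None and hit[2] == "CT5_A"

    def test_below_minimum_run_absent(self):
        assert find_polyt_tract("AAGGCTTTGAA") is None

    def test_dinoflagellate_style_long_run(self):
        hit = find_polyt_tract("AAGGCTTTTTTTGAA")
        assert hit is not None and hit[2] == "CT4-7_GA"

    def test_leftmost_match_wins(self):
        seq = "AACTTTTTAACCCTTTTGAA"      # CT5_A at 2, CT4-6_GC later
        start, end, name = find_polyt_tract(seq)
        assert start == 2 and name == "CT5_A"

    def test_window_limits_search(self):
        seq = "A" * 50 + "CTTTTG"
        assert find_polyt_tract(seq, window=20) is None


class TestValidation:
    def test_planted_locus_accepted_with_ggta_boundary(self, psinerae, rng):
        locus = build_locus(psinerae, psinerae.types[0], rng)
        bg = "".join(rng.choice(list("AC"), 200))
        contig = _contig(bg + locus + bg)
        hit = short_match_search(psinerae.types[0].sle, [contig])[0]
        cand, reason = validate_candidate(hit, contig)
        assert reason is None
        assert cand.boundary_motif == "GGTA"
        assert cand.donor_ok
        assert cand.total_length == 28 + 40
        assert cand.polyt_pattern == "CT4-6_GC"

    def test_broken_donor_rejected(self, psinerae, rng):
        locus = build_locus(psinerae, psinerae.types[0], rng,
                            break_donor=True)
        contig = _contig("".join(rng.choice(list("AC"), 100)) + locus
                         + "".join(rng.choice(list("AC"), 100)))
        hit = short_match_search(psinerae.types[0].sle, [contig])[0]
        cand, reason = validate_candidate(hit, contig)
        assert cand is None and reason == "donor"

    def test_missing_polyt_rejected(self, psinerae, rng):
        locus = build_locus(psinerae, psinerae.types[0], rng,
                            drop_polyt=True)
        contig = _contig("".join(rng.choice(list("AC"), 100)) + locus)
        hit = short_match_search(psinerae.types[0].sle, [contig])[0]
        cand, reason = validate_candidate(hit, contig)
        assert cand is None and reason == "polyT"

    def test_short_intron_rejected(self, psinerae, rng):
        sle = psinerae.types[0].sle
        contig = _contig("".join(rng.choice(list("AC"), 50)) + sle + "GTACT")
        hit = short_match_search(sle, [contig])[0]
        cand, reason = validate_candidate(hit, contig)
        assert cand is None and reason == "intron_length"

    def test_hit_outside_contig_rejected(self, psinerae):
        contig = _contig("ACGT" * 30)
        bad = ExonHit("c1", "+", 100, 140, 0, 1.0, "type1")
        with pytest.raises(ValueError):
            validate_candidate(bad, contig)


class TestDeduplication:
    def _cand(self, seq, start=0):
        from slsplice.genome import SLRNACandidate
        return SLRNACandidate("c", "+", "type1", (start, start + 28),
                              (start + 28, start + 68), True, "GGTA",
                              (start + 60, start + 68), "CT4-6_GC", 68, 1.0,
                              seq)

    def test_identical_copies_collapse(self):
        cands = [self._cand("A" * 68, s) for s in (0, 100, 200)]
        dedup = deduplicate_candidates(cands)
        assert len(dedup) == 1 and dedup[0][1] == 3

    def test_variants_kept(self):
        dedup = deduplicate_candidates([self._cand("A" * 68),
                                        self._cand("A" * 67 + "C")])
        assert len(dedup) == 2

    def test_empty_input(self):
        assert deduplicate_candidates([]) == []


class TestScanGenome:
    def test_planted_counts_match_truth(self, psinerae, small_config):
        contigs, truth = generate_genome(psinerae, small_config, seed=42)
        scan = scan_genome(psinerae, contigs)
        planted = truth[truth.kind == "slrna"]
        assert scan.counts == planted.sl_type.value_counts().to_dict()
        decoy_starts = {(r.contig, r.start) for r in
                        truth[truth.kind.str.startswith("decoy")].itertuples()}
        validated_starts = {(c.contig_id, c.exon_interval[0])
                            for c in scan.validated}
        assert not decoy_starts & validated_starts

    def test_random_sequence_yields_nothing(self, psinerae, rng):
        contigs = [_contig("".join(rng.choice(list("ACGT"), 50_000)), f"r{i}")
                   for i in range(2)]
        scan = scan_genome(psinerae, contigs)
        assert scan.counts == {"type1": 0, "type2": 0}

    def test_deterministic(self, psinerae, small_config):
        contigs, _ = generate_genome(psinerae, small_config, seed=3)
        s1 = scan_genome(psinerae, contigs)
        s2 = scan_genome(psinerae, contigs)
        assert [c.seq for c in s1.validated] == [c.seq for c in s2.validated]

    def test_strand_invariance(self, psinerae, small_config):
        contigs, _ = generate_genome(psinerae, small_config, seed=8)
        flipped = [SequenceRecord(c.id, revcomp(c.seq)) for c in contigs]
        s1 = scan_genome(psinerae, contigs)
        s2 = scan_genome(psinerae, flipped)
        assert s1.counts == s2.counts
        n = len(contigs[0].seq)
        mirrored = {(c.contig_id, n - c.exon_interval[1], n - c.exon_interval[0])
                    for c in s2.validated}
        original = {(c.contig_id, *c.exon_interval) for c in s1.validated}
        assert mirrored == original
        assert sorted(c.seq for c in s1.validated) == \
            sorted(c.seq for c in s2.validated)

    def test_soundness_recheck_by_string_ops(self, psinerae, small_config):
        contigs, _ = generate_genome(psinerae, small_config, seed=5)
        by_id = {c.id: c for c in contigs}
        scan = scan_genome(psinerae, contigs)
        sles = {t.name: t.sle for t in psinerae.types}
        assert scan.validated
        for cand in scan.validated:
            contig = by_id[cand.contig_id]
            n = len(contig.seq)
            oriented = contig.seq if cand.strand == "+" \
                else revcomp(contig.seq)
            s, e = cand.exon_interval
            if cand.strand == "-":
                s, e = n - e, n - s
            exon = oriented[s:e]
            mism = sum(a != b for a, b in zip(exon, sles[cand.sl_type]))
            assert mism / len(exon) <= 0.05
            assert oriented[e:e + 2] == "GT"
            assert len(oriented) - e >= 40
            assert find_polyt_tract(oriented[e:]) is not None


class TestTandemContext:
    def test_array_gaps_and_marker_distance(self, psinerae, rng):
        cfg = GeneratorConfig(n_contigs=1, contig_length=12000,
                              loci_per_type=(1, 0), tandem_array_size=3,
                              tandem_spacer=100, decoy_donor=0,
                              decoy_polyt=0)
        contigs, truth = generate_genome(psinerae, cfg, seed=12)
        scan = scan_genome(psinerae, contigs)
        # plant a 5S-like marker 250 nt after the array's last locus
        marker_seq = "".join(rng.choice(list("ACGT"), 120))
        last_end = int(truth.end.max())
        seq = contigs[0].seq
        seq = seq[:last_end + 250] + marker_seq \
            + seq[last_end + 250 + len(marker_seq):]
        contigs = [SequenceRecord(contigs[0].id, seq)]
        scan = scan_genome(psinerae, contigs)
        report = tandem_context_report(scan, contigs,
                                       SequenceRecord("5S", marker_seq))
        gaps = report.gap_to_next.dropna().tolist()
        assert gaps == [100, 100]
        assert report.marker_distance.min() == 250

    def test_single_candidate_no_gaps(self, psinerae, rng):
        cfg = GeneratorConfig(n_contigs=1, contig_length=6000,
                              loci_per_type=(1, 0), decoy_donor=0,
                              decoy_polyt=0)
        contigs, _ = generate_genome(psinerae, cfg, seed=13)
        report = tandem_context_report(scan_genome(psinerae, contigs),
                                       contigs)
        assert len(report) == 1
        assert report.gap_to_next.isna().all()
        assert report.marker_distance.isna().all()


class TestSmMotifs:
    def _cand(self, seq, exon_len):
        from slsplice.genome import SLRNACandidate
        return SLRNACandidate("c", "+", "t", (0, exon_len),
                              (exon_len, len(seq)), True, "GGTA",
                              (len(seq) - 6, len(seq)), "CT4-6_GC",
                              len(seq), 1.0, seq)

    def test_dinoflagellate_sm_variant_in_exon(self):
        sle = "ACCGTAGCCATTTTGGCTCAAG"       # contains ATTTTGG
        cand = self._cand(sle + "GTACCACCA", 22)
        hits = sm_motif_scan(cand)
        assert ("AT4GG", (9, 16), "exon") in hits

    def test_rotifer_motif(self):
        cand = self._cand("CCGG" + "AATTCTGA" + "CCGG", 4)
        assert any(h[0] == "AAYTYTGA" and h[2] == "intron"
                   for h in sm_motif_scan(cand))

    def test_ac_rich_sequence_empty(self):
        cand = self._cand("ACCA" * 10, 20)
        assert sm_motif_scan(cand) == []


@pytest.fixture(scope="module")
def verify_bundle(psinerae, small_config):
    return generate_bundle(psinerae, small_config, seed=77)


class TestVerifyTransSplicing:

    def test_planted_genes_confirmed_with_acceptor(self, psinerae, verify_bundle):
        calls = {c.transcript_id: c
                 for c in detect_all(verify_bundle.transcripts, psinerae)}
        genes = verify_bundle.truth_loci[verify_bundle.truth_loci.kind == "gene"]
        assert len(genes) > 0
        for row in genes.itertuples():
            call = calls[row.transcript_id]
            v = verify_trans_splicing(row.transcript_id, call.mature_seq,
                                      psinerae, verify_bundle.contigs)
            assert v.status == "confirmed"
            assert v.acceptor_ag_offset == -2
            assert not v.sle_in_genomic_5utr

    def test_cis_encoded_decoy_flagged(self, psinerae, verify_bundle):
        calls = {c.transcript_id: c
                 for c in detect_all(verify_bundle.transcripts, psinerae)}
        cis = verify_bundle.truth_loci[verify_bundle.truth_loci.kind == "cis_gene"]
        assert len(cis) > 0
        for row in cis.itertuples():
            call = calls[row.transcript_id]
            v = verify_trans_splicing(row.transcript_id, call.mature_seq,
                                      psinerae, verify_bundle.contigs)
            assert v.status == "cis_encoded" and v.sle_in_genomic_5utr

    def test_unplanted_transcript_unmapped(self, psinerae, verify_bundle, rng):
        random_seq = "".join(rng.choice(list("ACGT"), 400))
        v = verify_trans_splicing("ghost", random_seq, psinerae,
                                  verify_bundle.contigs)
        assert v.status == "unmapped"
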