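"""SL detection: motif finding, extent, classification, trimming, summaries."""

import numpy as np
import pytest
from scipy import stats

from slsplice import (GeneratorConfig, build_consensus, build_isoform_map,
                      classify_sl, detect_all, detect_transcript,
                      estimate_missed_sl_fraction, find_sl_evidence,
                      generate_transcriptome, measure_sl_extent,
                      nucleotide_composition, partial_length_distribution,
                      partition_summary, position_frequency_matrix,
                      SequenceRecord)
from slsplice._util import revcomp
from slsplice.detect import PartitionSummary

MOTIF = "GGCTCAAG"
PM_SLE = "ACCGTAGCCATCTTGGCTCAAG"          # published 22 nt SL exon


class TestFindEvidence:
    def test_sense_hit_position(self):
        seq = "AA" + PM_SLE + "ATGCCCGGGTTT"
        assert find_sl_evidence(seq, MOTIF) == ("sense", 16)

    def test_motif_beyond_window_is_missed(self):
        seq = "A" * 150 + MOTIF + "C" * 50
        assert find_sl_evidence(seq, MOTIF, window=100) is None

    def test_antisense_hit_maps_to_same_position(self):
        seq = "AA" + PM_SLE + "ATGCCCGGGTTT"
        assert find_sl_evidence(revcomp(seq), MOTIF) == ("antisense", 16)

    def test_too_short_transcript_raises(self):
        with pytest.raises(ValueError):
            find_sl_evidence("ACGT", MOTIF)


class TestExtentAndTrim:
    def test_full_sle(self, psinerae):
        sle = psinerae.types[0].sle
        seq = sle + "ATGAAACCC"
        ext, residual = measure_sl_extent(seq, 20, sle)
        assert ext == 28 and residual == ""

    def test_partial_sle_14nt_visible(self, psinerae):
        sle = psinerae.types[0].sle
        seq = sle[14:] + "ATGAAACCC"           # starts at SLe position 15
        ext, residual = measure_sl_extent(seq, 6, sle)
        assert ext == 14 and residual == ""

    def test_residual_kept_separate(self, psinerae):
        sle = psinerae.types[0].sle
        seq = "TGTCC" + sle + "ATG"
        ext, residual = measure_sl_extent(seq, 25, sle)
        assert ext == 28 and residual == "TGTCC"

    def test_trim_recovers_body_and_is_idempotent(self, psinerae):
        sle = psinerae.types[0].sle
        body = "ATGAAACCC"
        for start_offset in (0, 14):           # full and partial SLe
            seq = sle[start_offset:] + body
            call = detect_transcript(SequenceRecord("t", seq), psinerae)
            assert call.mature_seq == body
        again = detect_transcript(SequenceRecord("t", body + "A" * 20),
                                  psinerae)
        assert again.mature_seq == body + "A" * 20 and again.sl_type == "none"


class TestClassify:
    def test_full_extent_assigns_types(self, psinerae):
        for t in psinerae.types:
            assert classify_sl(28, t.sle, psinerae) == t.name

    def test_uncovered_discriminating_positions(self, psinerae):
        suffix = psinerae.types[0].sle[14:]
        assert classify_sl(14, suffix, psinerae) == "incomplete"

    def test_extent_16_covers_both_positions(self, psinerae):
        suffix = psinerae.types[1].sle[12:]    # positions 13..28
        assert classify_sl(16, suffix, psinerae) == "type2"

    def test_single_type_system_any_hit_is_single(self, maranthos):
        assert classify_sl(9, maranthos.types[0].sle[-9:], maranthos) \
            == "single"

    def test_mismatching_alleles_fall_back_to_incomplete(self, psinerae):
        suffix = list(psinerae.types[0].sle)
        suffix[12], suffix[13] = "G", "G"      # matches neither type
        assert classify_sl(28, "".join(suffix), psinerae) == "incomplete"


class TestOrientationInvariance:
    def test_calls_identical_after_reverse_complement(self, psinerae, rng):
        cfg = GeneratorConfig(n_transcripts=40)
        b = generate_transcriptome(psinerae, cfg, seed=21)
        n_hits = 0
        for rec in b.transcripts:
            fwd = detect_transcript(rec, psinerae)
            rev = detect_transcript(SequenceRecord(rec.id, revcomp(rec.seq)),
                                    psinerae)
            assert (fwd.sl_type, fwd.observed_extent) == \
                (rev.sl_type, rev.observed_extent)
            if fwd.orientation != "none":
                # a no-hit call has no orientation evidence to normalise by
                assert fwd.mature_seq == rev.mature_seq
                n_hits += 1
        assert n_hits > 10


class TestPartialDistribution:
    def test_all_full_extents(self, psinerae):
        sle = psinerae.types[0].sle
        recs = [SequenceRecord(f"t{i}", sle + "CCATGACA" * 4)
                for i in range(5)]
        hist, fracs = partial_length_distribution(detect_all(recs, psinerae))
        assert hist == {28: 5} and fracs[10] == 1.0

    def test_mixed_extents(self, psinerae):
        sle = psinerae.types[0].sle
        recs = [SequenceRecord(f"t{i}", sle[28 - e:] + "CCATGACA" * 4)
                for i, e in enumerate((8, 12, 20))]
        hist, fracs = partial_length_distribution(detect_all(recs, psinerae))
        assert fracs[10] == pytest.approx(2 / 3)

    def test_no_hits_gives_nan(self, psinerae):
        recs = [SequenceRecord("t", "CCATGACA" * 6)]
        hist, fracs = partial_length_distribution(detect_all(recs, psinerae))
        assert hist == {} and np.isnan(fracs[10])


class TestMissedFraction:
    def test_no_truncation_gives_near_zero(self):
        assert estimate_missed_sl_fraction({28: 100}, 28) == 0.0

    def test_default_regime_estimate_matches_truth(self, psinerae):
        # truncation N(6,4): the true full-loss probability is the normal
        # tail beyond 28, essentially zero; the estimate must agree +-0.05
        cfg = GeneratorConfig(n_transcripts=2000)
        b = generate_transcriptome(psinerae, cfg, seed=17)
        calls = detect_all(b.transcripts, psinerae)
        hist, _ = partial_length_distribution(calls)
        est = estimate_missed_sl_fraction(hist, 28)
        true_tail = float(stats.norm.sf(28, loc=6, scale=4))
        assert est == pytest.approx(true_tail, abs=0.05)
        assert est <= 0.10

    def test_heavy_truncation_gives_large_tail(self, rng):
        # mean missing equal to the SLe length: about half the SL pool is lost
        missing = np.clip(np.round(rng.normal(28, 6, 3000)), 0, 28)
        observed = missing[missing < 28]
        hist = {}
        for m in observed:
            e = 28 - int(m)
            hist[e] = hist.get(e, 0) + 1
        assert estimate_missed_sl_fraction(hist, 28) > 0.4


class TestConsensusAndPFM:
    def test_identical_sequences_reproduce_themselves(self):
        assert build_consensus(["ACGT"] * 3) == "ACGT"

    def test_majority_base_above_threshold(self):
        rows = ["A"] * 7 + ["C"] * 3
        assert build_consensus(rows) == "A"

    def test_even_split_emits_iupac(self):
        assert build_consensus(["A", "T"]) == "W"
        assert build_consensus(["A", "C", "G", "T"]) == "N"

    def test_pfm_identical_full_observations(self):
        pfm = position_frequency_matrix(["ACGT"] * 5, 4)
        assert np.allclose(pfm.freqs.sum(axis=0), 1.0)
        assert np.allclose(pfm.information, 2.0)

    def test_pfm_single_variable_column(self):
        pfm = position_frequency_matrix(["ACGT", "ACTT"], 4)
        assert pfm.information[2] == pytest.approx(1.0)
        assert pfm.freqs.loc["G", "pos3"] == pytest.approx(0.5)

    def test_pfm_mixed_extents_coverage(self):
        # one full observation, one covering only the last two columns
        pfm = position_frequency_matrix(["ACGT", "GT"], 4)
        assert list(pfm.coverage) == [1, 1, 2, 2]
        assert pfm.freqs.loc["A", "pos1"] == 1.0

    def test_zero_coverage_column_flagged_uniform(self):
        pfm = position_frequency_matrix(["GT"], 4)
        assert list(pfm.coverage[:2]) == [0, 0]
        assert np.allclose(pfm.freqs["pos1"], 0.25)


class TestComposition:
    def test_printed_sle_hand_counts(self):
        comp = nucleotide_composition(PM_SLE)
        assert comp == {"A": 5 / 22, "C": 7 / 22, "G": 5 / 22, "T": 5 / 22}

    def test_uniform_and_degenerate(self):
        assert nucleotide_composition("ACGT") == \
            {b: 0.25 for b in "ACGT"}
        assert nucleotide_composition("AAAA")["A"] == 1.0

    def test_non_acgt_excluded_from_denominator(self):
        comp = nucleotide_composition("AANN")
        assert comp["A"] == 1.0


class TestPartition:
    def test_published_counts_reproduce_printed_percentages(self):
        s = PartitionSummary(total=18596, no_sl=12880,
                             type_counts={"type1": 2541, "type2": 691},
                             incomplete=1703, complete=12,
                             isoform_pairs=81, cross_type=5)
        p = s.percentages()
        assert s.sl_bearing == 4935
        assert p["sl_bearing_pct"] == 26.54
        assert p["type1_pct_of_sl"] == 51.49
        assert p["type2_pct_of_sl"] == 14.00
        assert p["incomplete_pct_of_sl"] == 34.51
        assert s.percentages(1)["incomplete_pct_of_sl"] == 34.5
        assert p["complete_pct_of_sl"] == 0.24
        assert p["isoform_pairs_pct"] == 0.44
        assert p["cross_type_pct"] == 0.03

    def test_single_sl_species_printed_percentages(self):
        s = PartitionSummary(total=13016, no_sl=10364,
                             type_counts={"single": 2652}, incomplete=0,
                             complete=36, isoform_pairs=43)
        p = s.percentages()
        assert p["sl_bearing_pct"] == 20.37
        assert s.percentages(1)["sl_bearing_pct"] == 20.4
        assert p["isoform_pairs_pct"] == 0.33
        assert p["complete_pct_of_sl"] == 1.36

    def test_all_no_sl(self):
        s = PartitionSummary(total=10, no_sl=10, type_counts={}, incomplete=0)
        assert s.percentages()["sl_bearing_pct"] == 0.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            PartitionSummary(total=10, no_sl=5, type_counts={"t": 3},
                             incomplete=3)

    def test_zero_truncation_summary_matches_truth(self, psinerae):
        cfg = GeneratorConfig(n_transcripts=400, truncation_sd=0.0,
                              truncation_mean=0.0, isoform_pair_fraction=0.02)
        b = generate_transcriptome(psinerae, cfg, seed=31)
        calls = detect_all(b.transcripts, psinerae)
        summary = partition_summary(calls, build_isoform_map(calls))
        truth_counts = b.truth_transcripts["true_type"].value_counts()
        assert summary.type_counts["type1"] == truth_counts["type1"]
        assert summary.type_counts["type2"] == truth_counts["type2"]
        assert summary.no_sl == truth_counts["none"]
        n_groups = (b.truth_transcripts.isoform_group != ".").sum() // 2
        assert summary.isoform_pairs == n_groups

    def test_duplicate_calls_rejected(self, psinerae):
        recs = [SequenceRecord("t1", "ACGTAGCA" * 5)]
        calls = detect_all(recs + recs, psinerae)
        with pytest.raises(ValueError):
            partition_summary(calls)

    def test_partition_conserves_total(self, small_bundle, psinerae):
        calls = detect_all(small_bundle.transcripts, psinerae)
        s = partition_summary(calls)
        assert s.no_sl + sum(s.type_counts.values()) + s.incomplete == s.total
        assert s.total == len(small_bundle.transcripts)
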