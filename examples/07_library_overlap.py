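"""Estimate SL misclassification by comparing library overlaps.

Emulates an SL-PCR amplicon library (a draw from the true SL pool with 10%
non-SL contaminants) and measures its overlap with the RNA-seq non-SL pool
under the identity >= 98% / aligned length >= 50 nt filters.  The fraction
of SL-PCR transcripts matching the non-SL pool recovers the planted
contamination rate.
"""

from slsplice import (GeneratorConfig, generate_sl_system,
                      generate_transcriptome, overlap_sets, venn_counts)

system = generate_sl_system("psinerae")
bundle = generate_transcriptome(
    system, GeneratorConfig(n_transcripts=300, isoform_pair_fraction=0.0,
                            body_length_range=(150, 300)), seed=41)
truth = bundle.truth_transcripts
by_id = {r.id: r for r in bundle.transcripts}
sl_ids = list(truth[truth.label.isin(["type1", "type2"])].transcript_id)
non_ids = list(truth[truth.label == "none"].transcript_id)

n_pcr, contamination = 60, 0.10
n_contam = round(n_pcr * contamination)
slpcr = [by_id[t] for t in sl_ids[:n_pcr - n_contam]] \
    + [by_id[t] for t in non_ids[:n_contam]]
non_pool = [by_id[t] for t in non_ids[:150]]

res = overlap_sets(slpcr, non_pool, min_pid=0.98, min_len=50,
                   label_a="slpcr", label_b="non_sl")
print(f"SL-PCR library: {res.n_a} transcripts "
      f"({n_contam} planted contaminants)")
print(f"overlap with the non-SL pool: {res.shared_a} "
      f"({100 * res.fraction_a:.1f}%)")
print(venn_counts(res).to_string(index=False))
print(f"\nplanted contamination rate: {100 * contamination:.0f}%")
print("The measured overlap fraction estimates how many putative SL")
print("transcripts are misclassified; at desk scale it recovers the")
print("planted rate exactly because shared bodies match at 100% identity.")
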