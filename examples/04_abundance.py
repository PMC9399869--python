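"""Compare transcript abundance between SL pools.

TPM-normalises a simulated counts matrix (the generator plants a 2x
abundance shift on SL-type-1 transcripts), removes the lowest quartile,
and runs Kruskal-Wallis across the three pools plus pairwise Mann-Whitney
tests.
"""

from slsplice import (GeneratorConfig, compare_sl_pools, detect_all,
                      generate_sl_system, generate_transcriptome,
                      tpm_normalize)

system = generate_sl_system("psinerae")
bundle = generate_transcriptome(system, GeneratorConfig(n_transcripts=1500),
                                seed=8)
calls = detect_all(bundle.transcripts, system)

counts = bundle.counts.set_index("transcript_id")
lengths = counts.pop("effective_length")
matrix = tpm_normalize(counts, lengths)
print("per-sample TPM sums:", matrix.tpm.sum(axis=0).round(3).tolist())

out = compare_sl_pools(matrix, calls)
overall = out["overall"]
print(f"\n{overall.test}: statistic={overall.statistic:.2f}, "
      f"p={overall.p_value:.3g}, n={overall.n_obs}")
print("\npairwise Mann-Whitney:")
print(out["pairwise"].to_string(index=False))
print("\npool median TPM:", {k: round(v, 1) for k, v in out['medians'].items()})
print("\nA small p for type1-vs-none and a large one for type2-vs-none")
print("reproduce the planted pattern: only type-1 carries an abundance")
print("shift, so only its pool departs from the non-SL background.")
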