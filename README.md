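# slsplice

Analysis of spliced-leader (SL) *trans*-splicing in transcriptome and
genome assemblies, built for Perkinsozoa-like systems (e.g. the
dinoflagellate parasites *Parvilucifera sinerae* and *Maranthos nigrum*)
where mRNAs acquire a short common 5′ exon — the SL exon (SLe) — from a
small SL-RNA, and where several SLe variants can segregate the
transcriptome into distinct pools.

## What it does

- **SL detection and classification** — finds the conserved 3′-terminal
  SLe octamer `GGCTCAAG` within the first 100 nt of each transcript
  (either strand; `CTTGAGCC` is its reverse complement), measures how much
  of the SLe survived 5′ truncation, assigns the SL type from the
  discriminating positions (13–14 in a 28-nt two-type system), trims
  mature sequences, and summarises the transcriptome partition with
  published-style percentages.
- **Missed-SL estimation** — models the number of missing 5′ nucleotides
  as a right-truncated (rounded) normal, fits it by maximum likelihood and
  reports the tail mass of complete SLe loss, i.e. the fraction of truly
  SL-bearing transcripts misclassified as non-SL.
- **SL-RNA gene discovery** — scans genomic contigs for full-coverage SLe
  copies (PID ≥ 0.95), validates the SL-RNA gene architecture (GT splice
  donor after the exon, ≥ 40 nt intron, CT–poly-T terminator such as
  CT₄₋₆G/C or CT₅A within 120 nt of the donor), records the GGTA
  cleavage-site motif, deduplicates identical loci, reports tandem-array
  context and Sm-binding-site variant motifs, and verifies
  *trans*-splicing by the genomic absence of the SLe upstream of gene
  loci.
- **SL-pool statistics** — TPM normalisation
  (TPM_i = 10⁶·(c_i/ℓ_i)/Σ_j c_j/ℓ_j), lower-quartile filtering,
  Kruskal–Wallis across pools and exact/asymptotic Mann–Whitney U between
  pools; permutation GO-term enrichment of each pool against the whole
  annotated transcriptome (null counts from pool-sized draws without
  replacement, p = (1+k)/(1+N) one-sided).
- **SLe phylogenetics** — progressive global alignment of SLe sequences
  and exhaustive unrooted-topology search under Fitch parsimony with the
  gap treated as a fifth character state.
- **Synthetic data** — a first-class generator producing transcriptomes,
  genomes, counts and GO annotations with complete ground truth, so every
  stage is exercisable and testable without any external download.

## Worked example

```python
from slsplice import (GeneratorConfig, detect_all, generate_sl_system,
                      generate_transcriptome, partition_summary)

system = generate_sl_system("psinerae")     # two 28-nt SLe types
bundle = generate_transcriptome(system, GeneratorConfig(n_transcripts=1500),
                                seed=4)
calls = detect_all(bundle.transcripts, system)
print(partition_summary(calls).to_frame())
```

prints

```
     category  count percent
        total   1505       .
        no_sl    545   36.21
        type1    708   73.75
        type2    196   20.42
   incomplete     56    5.83
     complete     93    9.69
isoform_pairs      5    0.33
   cross_type      0     0.0
```

`no_sl` is the percentage of the whole transcriptome without SL evidence;
the `type1`, `type2`, `incomplete` and `complete` percentages are of the
SL-bearing subset (the convention used in published SL surveys).
`incomplete` transcripts carry the SLe 3′ end but lost the discriminating
positions to 5′ truncation, so their type cannot be called.  Comparing the
pools' abundance on the same bundle
(`compare_sl_pools`) gives Kruskal–Wallis p = 1.9 × 10⁻⁹ with
type-1 vs none at p = 1.2 × 10⁻⁹ and type-2 vs none at p = 0.57 — the
generator plants a 2× abundance shift only on type-1, and only that pool
departs from the background.

The `examples/` directory has one short script per capability
(simulation, detection, genome scan, abundance, enrichment, parsimony
tree, library overlap); each prints the numbers it computes and says what
they mean.  A thin CLI mirrors the stages:
`slsplice simulate|detect|scan-genome|abundance|enrich|phylo|overlap|all`.

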