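# Methods

## The system being modelled

Spliced-leader (SL) *trans*-splicing adds a short exon (the SLe) from a
small SL-RNA onto pre-mRNA 5′ ends, giving unrelated mRNAs an identical 5′
signature.  In the Perkinsozoa-like systems this package targets, the SLe
is 22–28 nt, starts with the conserved decamer `ACCGTAGCCA`, ends with the
octamer `GGCTCAAG` (terminal triplet AAG), and the SL-RNA gene continues
past the exon into a short intron: the exon-terminal G plus the
intron-initial GTA form the conserved GGTA cleavage motif, the intron
begins with the GT splice donor, and transcription terminates at a
CT–poly-T tract.  A species may carry one SLe (a 25-nt type, or a 22-nt
SPI-like type) or two co-expressed types distinguished only at positions
13–14 of a 28-nt SLe, in which case the transcriptome is segregated into
per-type pools.

## Detection model

Assembled transcripts have arbitrary strand, so the detector searches the
sense motif `GGCTCAAG` within the first `motif_window` nt (default 100)
and the antisense motif near the 3′ end, normalising antisense hits by
reverse complementation before all downstream steps; sense wins if both
match.  From the motif hit the observed SLe extent is extended upstream
nucleotide by nucleotide with **zero mismatches** against each type's SLe
(the longest extension wins, so a type-2 transcript is not cut short at
the discriminating positions).  Exact matching is deliberate: no mismatch
tolerance is reproducible and conservative for a 28-nt exon.  A type is
called only when the observed extent covers every discriminating
position; a covered-but-mismatching suffix is downgraded to `incomplete`
with a logged warning.  Single-type systems call any motif hit their type,
since partial hits carry the same evidence there.  Trimming removes
everything through the SLe terminal `...AAG` (the motif end); the mature
mRNA carries no genomic acceptor AG, which instead appears in the genomic
5′UTR and is handled by the verification step.

Percentages in partition reports are rounded half-up (2 dp, or 1 dp where
surveys print 1); within-SL categories use the SL-bearing count as
denominator and transcriptome-wide rows the retained total.  Published
tallies sometimes state a retained total exceeding the listed categories;
`PartitionSummary` accepts such a shortfall with a warning and uses the
stated total as the denominator, because that is how the corresponding
percentages were printed.  Partitions computed from calls always sum
exactly.

## Missed-SL estimate

The number of missing 5′ nucleotides (SLe length − extent) is treated as
a rounded normal; complete loss makes a transcript undetectable, so the
observed histogram is a right-truncated sample.  The likelihood uses the
truncation bound L − 0.5 (continuity correction for rounding: a count of
L corresponds to an underlying value ≥ L − 0.5); (μ, log σ) are fitted by
Nelder–Mead and the estimate is the fitted tail mass beyond the bound.
Without the half-integer correction the tail estimate is visibly biased
downward under heavy truncation.  A single-bin histogram is degenerate
and returns 0 with a warning.

## Genomic SL-RNA scan

`short_match_search` is a gapless (substitution-only) sliding comparison
at full query coverage on both strands.  At the default thresholds (28-nt
query, PID ≥ 0.95, coverage 1.0) a single indel already drops identity
below threshold, so gapless matching is equivalent to an aligner-based
search while being exactly reproducible and fast; only full coverage is
supported.  Validation accepts a hit iff (a) the exon is complete, (b)
the two nucleotides after it are GT, (c) at least `min_intron` nt (40)
remain before the contig end, and (d) a poly-T pattern — CT₄₋₆[GC],
CT₅A, or CT₄₋₇[GA], leftmost match first — occurs within `polyt_window`
nt (120) of the donor.  The window is permissive by design: observed
locus totals are ≤ 68 nt.  The GGTA boundary motif is recorded but not
required, being an observation about these loci rather than a selection
rule.  Candidates with identical full sequence collapse with a
multiplicity count; tandem context is reported from the pre-deduplication
loci so inter-copy gaps survive for identical tandem copies.
*Trans*-splicing verification locates the gene by local alignment of the
SL-trimmed transcript (PID ≥ 0.95), then requires the SLe to be absent
from the 200-nt genomic window upstream; the window size is a
configurable default since 5′UTR extents are not otherwise constrained.

## Statistics

TPM is the standard length-normalised relative abundance; replicate TPM
columns are averaged per transcript before testing (sums are retained in
output).  The lower quartile of mean TPM (linear interpolation; strictly
greater survives) is removed first, because low-coverage transcripts
under-sample 5′ ends and would blur the SL/non-SL contrast; the
degenerate all-equal case keeps everything with a warning.  Pools are the
classified types plus the non-SL pool; `incomplete` calls are excluded as
unassignable.  All tests are two-sided with average ranks and tie
correction: Kruskal–Wallis for ≥ 3 pools, Mann–Whitney otherwise and for
all pairwise comparisons.  When the smaller group has ≤ 10 observations
and the arrangement count is ≤ 5·10⁵ the Mann–Whitney p-value comes from
full enumeration of group assignments (valid under ties); otherwise from
the tie-corrected normal approximation.

GO enrichment compares each pool against the whole annotated
transcriptome.  For a term with K carriers in a universe of M and a pool
of N, the null count under "draw N transcripts without replacement" is
exactly hypergeometric(M, K, N); the permutation sampler therefore draws
null counts directly from that distribution (numpy), which is the same
Monte-Carlo experiment per term at a fraction of the cost.  p-values are
one-sided (enrichment) with the add-one estimator (1+k)/(1+N_perm), so
p ∈ (0, 1]; when C(M, N) ≤ 10⁶ the exact tail is returned instead.  No
multiple-testing correction is applied by default (pool surveys report
raw p < 0.05); Benjamini–Hochberg is available behind a flag.

## Parsimony of SL exons

SLe variants differ by substitutions and short indels, so gaps carry
signal and are treated as a fifth character state in Fitch scoring.
Sequences are aligned progressively (global alignment with a fixed
input-order guide; pre-aligned input passes through), and for the small
taxon sets involved (3–8 consensus SLes) every unrooted binary topology
is enumerated and scored; all minimum-score topologies are returned in a
deterministic canonical order.  Branch change counts come from one
most-parsimonious assignment resolved top-down with lexicographic
tie-breaks — the assignment is not unique and the counts are labelled
accordingly.  Alignment scoring is match +1, mismatch −2, gap −2
(BLASTn-short-like), the same scheme used for all short high-identity
comparisons in the package; PID is identities over aligned columns
including gaps, and N matches nothing.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:
per-type transcript fractions (defaults 0.50/0.14, remainder non-SL);
5′-truncation noise as a rounded normal (default mean 6, sd 4, clipped to
[0, L]) — under which ≥ 90% of SL transcripts keep their last 10 SLe nt
and full loss is essentially absent, matching the regime the detector is
meant for; rare SL+/− isoform pairs sharing an identical body (default
0.5% of SL transcripts); SL-RNA loci with the exact exon–donor–intron–
terminator architecture (locus totals 68/60/66 nt for the three default
systems) plus donor-broken and terminator-free decoys that must fail
validation; gene loci whose genomic 5′UTR carries an acceptor AG but no
SLe (and cis-encoded decoys that do carry it); log-normal abundance
(ln-scale μ = 2, σ = 1) with a 2× multiplicative shift on type-1; and
i.i.d. GO annotation at 5% background with one fold-4 planted term per
pool.  Bodies and intron fillers are rejection-sampled to exclude the SL
motif (and early poly-T matches) so that planted truth is exact.

It does **not** simulate reads, quality scores, assembly artefacts,
chimeras, host contamination, or biased truncation — so passing tests
show the pipeline recovers planted structure under the stated noise
model, not that it is robust to every artefact of real assemblies.

## Numerical and design choices

- Coordinates are 0-based half-open internally; reports and GFF3 are
  1-based.  SLe positions are 1-based from the 5′ end.
- Discriminating alleles default to TT (type-1) vs CA (type-2) at
  positions 13–14; they are configurable free parameters, not asserted
  species truths.
- Determinism: every stochastic step takes an explicit seed or
  `numpy.random.Generator`; pipeline runs are byte-identical given
  (inputs, seed), and the run log records thresholds without timestamps.
- Co-optimal local alignments can differ in identity count; the aligner
  picks the most-identities, fewest-columns optimum so PID is well
  defined and symmetric under query/subject swap.
- Problem sizes in tests and the acceptance script (bundles of 2000
  transcripts, 10–20 seeds per sweep, 100–400 simulation replicates for
  power/type-I rates) were chosen as the smallest sizes at which the
  measured rates are stable to within their tolerance bands.

## Known limitations

- The gapless genomic search cannot recover an SLe copy interrupted by a
  true indel; at 95% identity over ≤ 28 nt such copies are outside the
  acceptance rules anyway.
- The library-overlap comparison is all-vs-all local alignment, adequate
  at desk scale but not a substitute for an indexed aligner on full
  libraries.
- `estimate_missed_sl_fraction` assumes the truncation law is normal
  across its whole support; strongly non-normal truncation (e.g. bimodal
  degradation) will bias the tail estimate.
- Exhaustive parsimony stops at 8 taxa ((2n−5)!! growth); larger SLe
  collections need a heuristic search the package does not provide.
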