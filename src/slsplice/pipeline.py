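"""End-to-end orchestration: detection through reports.

``run_pipeline`` wires the stages together and writes every intermediate
table as TSV under the output directory.  Runs are deterministic given the
inputs and the seed; the run log records every threshold used (and no
timestamps, so repeated runs are byte-identical).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import abundance as ab
from . import detect as dt
from . import enrichment as en
from . import genome as gn
from . import phylo as ph
from .config import ConfigError, PipelineConfig
from .io import SequenceRecord, read_fasta, read_tsv, write_fasta, write_tsv
from .synthetic import (REFERENCE_SLES, GeneratorConfig, generate_bundle,
                        generate_sl_system, write_bundle)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") \
                    from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage and write a report directory.

    Stages whose inputs are absent (no genome, no counts, no annotations)
    are skipped.  Returns a dict of the main in-memory results.
    """
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    loglines = [f"{k}={v}" for k, v in asdict(thr).items()]
    loglines.append(f"seed={config.seed}")
    system = generate_sl_system(config.system)

    if config.simulate:
        gen_cfg = GeneratorConfig(**config.generator)
        bundle = generate_bundle(system, gen_cfg, seed=config.seed)
        bdir = out / "bundle"
        write_bundle(bundle, bdir)
        transcripts = bundle.transcripts
        contigs = bundle.contigs
        counts_df = bundle.counts
        go_df = bundle.go
    else:
        transcripts = read_fasta(config.transcripts)
        contigs = read_fasta(config.genome) if config.genome else []
        counts_df = read_tsv(config.counts) if config.counts else None
        go_df = read_tsv(config.go) if config.go else None

    results: dict = {}

    calls = _stage("detect")(dt.detect_all)(transcripts, system,
                                            thr.motif_window)
    write_tsv(dt.calls_table(calls), out / "calls.tsv")
    iso = dt.build_isoform_map(calls)
    summary = _stage("partition")(dt.partition_summary)(calls, iso)
    write_tsv(summary.to_frame(), out / "partition.tsv")
    results["calls"], results["partition"] = calls, summary

    hits = [c for c in calls if c.orientation != "none"]
    pairs = [(c, c.observed_suffix) for c in hits if c.observed_suffix]
    suffixes = [s for _, s in pairs]
    pfm = dt.position_frequency_matrix(suffixes, system.sle_length)
    write_tsv(pfm.to_frame(), out / "pfm.tsv")
    full = [s for s in suffixes if len(s) == system.sle_length]
    consensus_records = []
    if full:
        cons = dt.build_consensus(full, thr.consensus_threshold)
        consensus_records.append(SequenceRecord("consensus_all", cons))
    comp_rows = []
    for t in system.types:
        sub = [s for c, s in pairs
               if c.sl_type == t.name and len(s) == system.sle_length]
        if sub:
            cons = dt.build_consensus(sub, thr.consensus_threshold)
            consensus_records.append(SequenceRecord(f"consensus_{t.name}",
                                                    cons))
        comp = dt.nucleotide_composition(t.sle)
        comp_rows.append(dict(sequence=t.name,
                              **{b: round(f, 4) for b, f in comp.items()}))
    if consensus_records:
        write_fasta(consensus_records, out / "consensus.fasta")
    write_tsv(pd.DataFrame(comp_rows), out / "composition.tsv")
    hist, fracs = dt.partial_length_distribution(calls)
    results["extent_hist"] = hist
    if hist:
        missed = dt.estimate_missed_sl_fraction(hist, system.sle_length)
        results["missed_sl_fraction"] = missed
        loglines.append(f"missed_sl_fraction={missed:.6f}")

    if contigs:
        scan = _stage("scan-genome")(gn.scan_genome)(
            system, contigs, thr.scan_min_pid, thr.min_intron,
            thr.polyt_window)
        write_tsv(gn.candidates_table(scan), out / "candidates.tsv")
        (out / "candidates.gff3").write_text(gn.candidates_to_gff3(scan))
        write_tsv(gn.tandem_context_report(scan, contigs),
                  out / "tandem_context.tsv")
        results["scan"] = scan
        ver_rows = []
        for c in [c for c in hits if c.sl_type not in ("none",)][:20]:
            v = gn.verify_trans_splicing(c.transcript_id, c.mature_seq,
                                         system, contigs, thr.verify_min_pid,
                                         thr.upstream_window)
            ver_rows.append(dict(transcript_id=v.transcript_id,
                                 status=v.status, contig=v.contig_id or ".",
                                 pid=round(v.pid, 4),
                                 sle_in_5utr=v.sle_in_genomic_5utr,
                                 acceptor_offset=v.acceptor_ag_offset,
                                 start_codon_offset=v.start_codon_offset))
        write_tsv(pd.DataFrame(ver_rows), out / "verification.tsv")
        results["verification"] = ver_rows

    if counts_df is not None:
        counts = counts_df.set_index("transcript_id")
        lengths = counts.pop("effective_length")
        matrix = _stage("abundance")(ab.tpm_normalize)(counts, lengths)
        tpm_out = matrix.tpm.copy()
        tpm_out.insert(0, "transcript_id", tpm_out.index)
        tpm_out["mean_tpm"] = matrix.mean_tpm
        write_tsv(tpm_out.reset_index(drop=True), out / "tpm.tsv")
        comparison = _stage("abundance")(ab.compare_sl_pools)(matrix, calls)
        rows = [dict(test=comparison["overall"].test,
                     statistic=comparison["overall"].statistic,
                     p_value=comparison["overall"].p_value)]
        write_tsv(pd.concat([pd.DataFrame(rows),
                             comparison["pairwise"]], axis=0),
                  out / "tests.tsv")
        results["abundance"] = comparison

    if go_df is not None:
        amap = en.AnnotationMap.from_table(go_df)
        table = _stage("enrich")(en.enrich_pools)(
            calls, amap, thr.alpha, thr.n_perm, config.seed)
        write_tsv(table, out / "enrichment.tsv")
        results["enrichment"] = table

    taxa = {f"consensus_{r.id.split('_', 1)[1]}": r.seq.replace("N", "A")
            for r in consensus_records if r.id != "consensus_all"}
    taxa.update(REFERENCE_SLES)
    if len(taxa) >= 3 and len(taxa) <= 8:
        aln = _stage("phylo")(ph.align_sl_set)(taxa)
        trees = ph.exhaustive_parsimony_search(aln)
        (out / "tree.nwk").write_text(
            "\n".join(t.newick() for t in trees) + "\n")
        write_tsv(ph.branch_changes_table(trees[0]), out / "branch_changes.tsv")
        results["trees"] = trees

    (out / "run.log").write_text("\n".join(loglines) + "\n")
    return results
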