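"""End-to-end orchestration: simulate -> trim -> stitch -> verify -> scaffold.

This module wires the stage modules together the way the reference-guided
workflow runs in production, and is what the recovery benchmarks and the
command line drive.  The canonical recovery run uses a 2 Mb donor at 2%
divergence with 30x fragment coverage plus the two mate libraries at 10x
each — large enough for multi-contig scaffolding statistics, small enough
to finish on one CPU in minutes.
"""
from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

from . import asm_metrics, contig_builder, mate_verify, quality_trim, scaffolder, simdata
from .io_formats import AssemblyRecord, read_alignments


@dataclass
class RecoveryResult:
    """Everything a recovery run produces, from raw counts to truth scores."""

    config: simdata.SimConfig
    n_reads: int
    n_retained: int
    pct_reads_retained: float
    n_placements: int
    n_unmapped: int
    n_unmapped_collected: int
    contigs: List[contig_builder.Contig]
    contig_stats: asm_metrics.AssemblyStats
    coverage_summary: Dict[str, Dict[str, float]]
    n_intra: int
    n_spanning: int
    n_conflicting: int
    n_confirmed: int
    paths: List[scaffolder.ScaffoldPath]
    scaffold_records: List[AssemblyRecord]
    scaffold_stats: asm_metrics.AssemblyStats
    recovery: simdata.RecoveryReport


def run_recovery(
    seed: int,
    workdir: Optional[Path] = None,
    min_overlap: int = 50,
    min_support: int = 3,
    min_weight: int = 3,
    min_gap: int = 10,
    **config_overrides,
) -> RecoveryResult:
    """Run the full pipeline on simulated data and score it against truth.

    ``config_overrides`` adjust :class:`simdata.SimConfig` fields (e.g.
    ``genome_len`` or ``base_error_rate``).  Alignments round-trip through a
    coordinate-sorted SAM file in ``workdir`` (a temporary directory by
    default) so the ingestion boundary is exercised as in production.
    """
    cfg = simdata.SimConfig(seed=seed, **config_overrides)
    genomes = simdata.simulate_genomes(cfg)
    readset = simdata.simulate_reads(genomes, cfg)

    retained, stats_q0, stats_q = quality_trim.trim_set(readset.reads)
    retained = quality_trim.enforce_pair_integrity(retained)
    n_reads = sum(s.n_reads for s in stats_q0.values())
    n_kept = len(retained)

    with tempfile.TemporaryDirectory() as tmp:
        sam_path = (workdir or Path(tmp)) / "truth.sam"
        simdata.write_truth_sam(
            retained, genomes, readset, sam_path,
            unmappable_overlap_frac=cfg.unmappable_overlap_frac,
        )
        placements, unmapped, _rejected = read_alignments(sam_path)
    unmapped_reads = contig_builder.collect_unmapped(retained, unmapped)

    contigs, coverage_summary = contig_builder.build_contigs(
        placements,
        min_overlap=min_overlap,
        ref_lengths={"ref": len(genomes.reference)},
        reference={"ref": genomes.reference},
    )
    contig_stats = asm_metrics.assembly_stats([c.seq for c in contigs])

    lifted, _dropped = mate_verify.lift_to_contigs(placements, contigs)
    # window covers the generator's full insert support (truncated at 4 SD);
    # a narrower window would misclassify genuine long-insert pairs
    links = mate_verify.pair_links(lifted, readset.library_of, end_window_sds=4.0)
    kinds = {"intra": 0, "spanning": 0, "conflicting": 0}
    for link in links:
        kinds[link.kind] += 1
    mate_verify.confirm_contigs(contigs, links, min_support=min_support)

    edges, _discarded = scaffolder.bundle_links(links)
    paths = scaffolder.greedy_path_merge(
        [c.contig_id for c in contigs], edges, min_weight=min_weight
    )
    seqs = {c.contig_id: c.seq for c in contigs}
    scaffold_records = scaffolder.emit_scaffolds(paths, seqs, min_gap=min_gap)
    scaffold_stats = asm_metrics.assembly_stats(scaffold_records)

    recovery = simdata.truth_evaluate(contigs, paths, genomes)
    return RecoveryResult(
        config=cfg,
        n_reads=n_reads,
        n_retained=n_kept,
        pct_reads_retained=100.0 * n_kept / n_reads,
        n_placements=len(placements),
        n_unmapped=len(unmapped),
        n_unmapped_collected=len(unmapped_reads),
        contigs=contigs,
        contig_stats=contig_stats,
        coverage_summary=coverage_summary,
        n_intra=kinds["intra"],
        n_spanning=kinds["spanning"],
        n_conflicting=kinds["conflicting"],
        n_confirmed=sum(1 for c in contigs if c.status == "confirmed"),
        paths=paths,
        scaffold_records=scaffold_records,
        scaffold_stats=scaffold_stats,
        recovery=recovery,
    )
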