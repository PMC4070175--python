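"""End-to-end orchestration of the consensus assembly workflow.

Stage order is fixed: read QC -> seeded subsampling -> per-assembly
redundancy removal -> evaluation metrics (length statistics, RMBT against
the unselected reads, core-gene completeness) -> per-tool k selection ->
consensus merging -> robust filtering -> re-applied redundancy and length
rules -> final report bundle. External assemblers are integration points,
not dependencies: assemblies enter as labeled FASTA files, or the
simulation module generates them.

All randomness flows from the single top-level seed; re-running with an
identical configuration reproduces byte-identical TSV reports.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import completeness as comp_mod
from . import consensus as cons_mod
from . import metrics as metrics_mod
from . import qc as qc_mod
from . import redundancy as red_mod
from . import rmbt as rmbt_mod
from . import simulate as sim_mod
from .seqio import Contig, read_fasta, read_fastq_pairs, write_fasta, write_fastq

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("txome_consensus")


@dataclass(slots=True)
class AssemblyInput:
    path: str
    tool: str
    k: object = None


@dataclass(slots=True)
class SimBlock:
    """Simulated-dataset request embedded in a pipeline config."""

    n_transcripts: int = 500
    n_pairs: int = 50_000
    n_core_genes: int = 50
    tools: tuple[str, ...] = ("toolA", "toolB", "toolC")
    profile: sim_mod.ToolProfile = field(default_factory=sim_mod.ToolProfile)
    base_error_rate: float = 0.005


@dataclass(slots=True)
class PipelineConfig:
    output_dir: str = "txome_out"
    seed: int = 7
    reads1: str | None = None
    reads2: str | None = None
    assemblies: list[AssemblyInput] = field(default_factory=list)
    core_genes: str | None = None
    simulate: SimBlock | None = None
    subsample_n: int = 30_000
    trim: qc_mod.TrimParams = field(default_factory=qc_mod.TrimParams)
    cluster: red_mod.ClusterParams = field(default_factory=red_mod.ClusterParams)
    mapping: rmbt_mod.MappingParams = field(default_factory=rmbt_mod.MappingParams)
    merge: cons_mod.MergeParams = field(default_factory=cons_mod.MergeParams)
    selection: metrics_mod.KSelectionParams = field(
        default_factory=metrics_mod.KSelectionParams
    )
    complete_cov: float = 0.70
    partial_cov: float = 0.30
    min_identity: float = 0.95
    strict_all_assemblies: bool = False


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    simple = {
        "output_dir", "seed", "reads1", "reads2", "core_genes", "subsample_n",
        "complete_cov", "partial_cov", "min_identity", "strict_all_assemblies",
    }
    for key, value in raw.items():
        if key in simple:
            setattr(cfg, key, value)
        elif key == "assemblies":
            cfg.assemblies = [AssemblyInput(**a) for a in value]
        elif key == "simulate":
            profile = value.pop("profile", None)
            tools = tuple(value.get("tools", ("toolA", "toolB", "toolC")))
            block = SimBlock(**{**value, "tools": tools})
            if profile:
                block.profile = sim_mod.ToolProfile(**profile)
            cfg.simulate = block
        elif key == "trim":
            cfg.trim = qc_mod.TrimParams(**value)
        elif key == "cluster":
            cfg.cluster = red_mod.ClusterParams(**value)
        elif key == "mapping":
            cfg.mapping = rmbt_mod.MappingParams(**value)
        elif key == "merge":
            cfg.merge = cons_mod.MergeParams(**value)
        elif key == "selection":
            cfg.selection = metrics_mod.KSelectionParams(**value)
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return cfg


@dataclass(slots=True)
class PipelineResult:
    output_dir: Path
    qc_report: pd.DataFrame
    metrics: pd.DataFrame
    k_sweep: pd.DataFrame | None
    provenance: pd.DataFrame
    summary: dict
    robust_contigs: list


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    filehandler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fmt = logging.Formatter("%(levelname)s %(message)s")
    for h in (stream, filehandler):
        h.setFormatter(fmt)
        log.addHandler(h)


def _sub_seed(seed: int, stream: int) -> int:
    import numpy as np

    return int(np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full workflow and write the report bundle.

    Outputs under ``config.output_dir``: qc_report.tsv, metrics.tsv,
    k_sweep.tsv (when a tool has several k values), merged.fasta,
    robust.fasta, provenance.tsv, summary.tsv and pipeline.log.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)

    if not config.assemblies and config.simulate is None:
        raise ValueError("configuration error: no assemblies and no simulate block")
    for a in config.assemblies:
        if not Path(a.path).exists():
            raise ValueError(f"configuration error: missing assembly file {a.path}")
    if config.reads1 and not Path(config.reads1).exists():
        raise ValueError(f"configuration error: missing reads file {config.reads1}")

    truth: dict[str, str] | None = None
    transcripts = None
    core_genes = None

    if config.simulate is not None:
        sb = config.simulate
        log.info(
            "simulate: %d transcripts, %d pairs, tools=%s",
            sb.n_transcripts, sb.n_pairs, ",".join(sb.tools),
        )
        sim_cfg = sim_mod.SimConfig(
            n_transcripts=sb.n_transcripts,
            base_error_rate=sb.base_error_rate,
            seed=config.seed,
        )
        transcripts, weights = sim_mod.simulate_transcriptome(sim_cfg)
        pairs = sim_mod.simulate_reads(transcripts, weights, sb.n_pairs, sim_cfg)
        profiles = [(tool, sb.profile) for tool in sb.tools]
        assemblies, truth = sim_mod.simulate_tool_assemblies(
            transcripts, profiles, seed=_sub_seed(config.seed, 2)
        )
        core_genes = sim_mod.simulate_core_genes(
            transcripts, sb.n_core_genes, seed=_sub_seed(config.seed, 3)
        )
        simdir = outdir / "sim"
        simdir.mkdir(exist_ok=True)
        write_fasta(transcripts, simdir / "truth.fasta")
        write_fastq((p.r1 for p in pairs), simdir / "reads_1.fastq")
        write_fastq((p.r2 for p in pairs), simdir / "reads_2.fastq")
        for label, contigs in assemblies:
            write_fasta(contigs, simdir / f"{label}.fasta")
        write_fasta(core_genes, simdir / "core_genes.fasta")
    else:
        if not (config.reads1 and config.reads2):
            raise ValueError("configuration error: reads1/reads2 required")
        pairs = list(read_fastq_pairs(config.reads1, config.reads2))
        assemblies = []
        for a in config.assemblies:
            label = cons_mod.SourceLabel(a.tool, a.k)
            contigs = read_fasta(a.path, source=label)
            assemblies.append((label, contigs))
        if config.core_genes:
            core_genes = read_fasta(config.core_genes, source="core")

    # ---- QC -------------------------------------------------------------
    log.info("qc: %d raw pairs", len(pairs))
    qc_result = qc_mod.run_qc(pairs, params=config.trim)
    qc_result.report.to_tsv(outdir / "qc_report.tsv")
    log.info(
        "qc: %d pairs, %d orphans after filtering",
        len(qc_result.pairs), len(qc_result.orphans),
    )

    # ---- subsample ------------------------------------------------------
    n_sub = min(config.subsample_n, len(qc_result.pairs))
    if n_sub < config.subsample_n:
        log.info("subsample: clamping n to available pairs (%d)", n_sub)
    sub = qc_mod.subsample_pairs(qc_result.pairs, n_sub, _sub_seed(config.seed, 1))
    log.info(
        "subsample: %d selected, %d unselected (seed stream 1)",
        len(sub.selected), len(sub.unselected),
    )
    validation_reads = [r for p in sub.unselected for r in (p.r1, p.r2)]

    # ---- per-assembly redundancy + metrics ------------------------------
    rows: list[metrics_mod.MetricsRow] = []
    clustered: dict[cons_mod.SourceLabel, list[Contig]] = {}
    for label, contigs in assemblies:
        cres = red_mod.cluster_transcripts(contigs, config.cluster)
        clustered[label] = cres.retained
        log.info(
            "redundancy %s: %d -> %d contigs", label, len(contigs), len(cres.retained)
        )
        rows.append(
            _evaluate_assembly(
                cres.retained, str(label), validation_reads, core_genes, config
            )
        )

    # ---- per-tool k selection -------------------------------------------
    by_tool: dict[str, list[tuple[object, cons_mod.SourceLabel]]] = {}
    for (label, _), row in zip(assemblies, rows):
        by_tool.setdefault(label.tool, []).append((label.k, label))
    selected_labels: list[cons_mod.SourceLabel] = []
    sweep_frames = []
    label_rows = {str(label): row for (label, _), row in zip(assemblies, rows)}
    for tool, entries in by_tool.items():
        if len(entries) == 1:
            selected_labels.append(entries[0][1])
            continue
        candidates = []
        for idx, (k, label) in enumerate(entries):
            k_num = k if isinstance(k, int) else idx
            candidates.append((k_num, label_rows[str(label)]))
        chosen = metrics_mod.select_k(candidates, config.selection)
        chosen_label = entries[[k for k, _ in candidates].index(chosen)][1]
        selected_labels.append(chosen_label)
        sweep = metrics_mod.k_sweep_table(candidates)
        sweep.insert(0, "tool", tool)
        sweep_frames.append(sweep)
        log.info("select_k %s: chose %s", tool, chosen_label)
    k_sweep = pd.concat(sweep_frames, ignore_index=True) if sweep_frames else None
    if k_sweep is not None:
        k_sweep.to_csv(outdir / "k_sweep.tsv", sep="\t", index=False)

    # ---- consensus merge + robust filter --------------------------------
    merge_inputs = [(label, clustered[label]) for label in selected_labels]
    merged = cons_mod.merge_assemblies(merge_inputs, config.merge)
    log.info("merge: %d input contigs -> %d merged contigs",
             sum(len(c) for _, c in merge_inputs), len(merged))
    if config.strict_all_assemblies:
        robust = cons_mod.robust_filter(
            merged, require_labels=[label for label, _ in merge_inputs]
        )
    else:
        robust = cons_mod.robust_filter(merged, config.merge.min_tools)
    log.info("robust filter (min_tools=%d): %d contigs", config.merge.min_tools, len(robust))

    write_fasta(
        [Contig(m.id, m.seq, "merged") for m in merged], outdir / "merged.fasta"
    )
    robust_contigs = [Contig(m.id, m.seq, "robust") for m in robust]
    # re-apply redundancy and length rules to the robust set
    robust_clustered = red_mod.cluster_transcripts(robust_contigs, config.cluster).retained
    write_fasta(robust_clustered, outdir / "robust.fasta")
    log.info("robust set after redundancy/length rules: %d contigs", len(robust_clustered))

    if robust_clustered:
        rows.append(
            _evaluate_assembly(
                robust_clustered, "robust_merged", validation_reads, core_genes, config
            )
        )

    provenance = pd.DataFrame(
        [
            {
                "merged_id": m.id,
                "robust": m.n_tools >= config.merge.min_tools,
                "n_tools": m.n_tools,
                "constituents": ";".join(c.contig_id for c in m.constituents),
                "tools": ";".join(sorted({c.source.tool for c in m.constituents})),
            }
            for m in merged
        ]
    )
    provenance.to_csv(outdir / "provenance.tsv", sep="\t", index=False)

    metrics_df = metrics_mod.metrics_table(rows)
    metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False)

    summary = _summarize(merged, robust, truth, transcripts)
    pd.DataFrame([summary]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    log.info("summary: %s", summary)

    return PipelineResult(
        output_dir=outdir,
        qc_report=qc_result.report.to_frame(),
        metrics=metrics_df,
        k_sweep=k_sweep,
        provenance=provenance,
        summary=summary,
        robust_contigs=robust_clustered,
    )


def _evaluate_assembly(contigs, label, validation_reads, core_genes, config):
    row = metrics_mod.assembly_stats(contigs, label)
    if validation_reads:
        index = rmbt_mod.TranscriptIndex(contigs)
        result = rmbt_mod.map_reads(
            validation_reads, index, config.mapping, keep_hits=False
        )
        row.rmbt_pct = rmbt_mod.rmbt_percent(result)
    if core_genes:
        rep = comp_mod.core_gene_recovery(
            contigs,
            core_genes,
            complete_cov=config.complete_cov,
            partial_cov=config.partial_cov,
            min_identity=config.min_identity,
        )
        row.completeness = (rep.complete_pct, rep.partial_pct)
    log.info(
        "metrics %s: n=%d total=%d n50=%d rmbt=%s",
        label, row.n_transcripts, row.total_bp, row.n50,
        "n/a" if row.rmbt_pct is None else f"{row.rmbt_pct:.2f}%",
    )
    return row


def _summarize(merged, robust, truth, transcripts):
    summary = {
        "n_merged_contigs": len(merged),
        "n_robust_contigs": len(robust),
    }
    if truth is not None and transcripts is not None:
        def origin(constituent_id: str) -> str:
            # namespaced id is "<label>|<original id>"
            return truth.get(constituent_id.split("|", 1)[1], "unknown")

        robust_noise = sum(
            1
            for m in robust
            if all(origin(c.contig_id) == "noise" for c in m.constituents)
        )
        recovered = {
            origin(c.contig_id)
            for m in robust
            for c in m.constituents
            if origin(c.contig_id) != "noise"
        }
        summary["n_robust_noise_contigs"] = robust_noise
        summary["true_transcript_recovery_pct"] = round(
            100.0 * len(recovered) / len(transcripts), 2
        )
    return summary
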