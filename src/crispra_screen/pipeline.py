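"""End-to-end screen analysis: simulate -> assign -> QC -> factors ->
hits (-> enrichment), with a machine-readable run report.

Stages exchange plain-text formats (TSV / MTX / FASTQ) when an output
directory is given, so each stage can be validated independently; the
in-memory path is used otherwise. Reruns with the same configuration and
seed reproduce outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assign as assign_mod
from . import dge as dge_mod
from . import hits as hits_mod
from . import qc as qc_mod
from .config import SimulationConfig
from .factor import MultiViewFactorModel, ViewMatrix, identify_zga_factor
from .simulate import generate_amplicon_reads, generate_cells, generate_library

logger = logging.getLogger("crispra_screen")


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc_profile: str = "screen"
    n_factors: int = 5
    fdr: float = 0.10
    assignment_mode: str = "reads"  # "reads": amplicon round trip; "truth": planted singlets
    run_enrichment: bool = False
    enrichment_rank: int = 400
    outdir: str | None = None
    write_fastq: bool = False

    def validate(self) -> None:
        self.sim.validate()
        if self.qc_profile not in qc_mod.PROFILES:
            raise ValueError(f"unknown QC profile {self.qc_profile!r}")
        if self.assignment_mode not in ("reads", "truth"):
            raise ValueError("assignment_mode must be 'reads' or 'truth'")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {
                "sim": dataclasses.asdict(self.sim),
                "qc_profile": self.qc_profile,
                "n_factors": self.n_factors,
                "fdr": self.fdr,
                "assignment_mode": self.assignment_mode,
            },
            sort_keys=True,
            default_flow_style=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    library: object
    matrix: object  # QC-filtered ScreenMatrix
    normalized: object
    assignments: pd.DataFrame
    cell_guides: pd.Series  # per analysis cell: assigned guide
    model: MultiViewFactorModel | None
    zga_factor: int | None
    zga_p: float | None
    activation: pd.DataFrame
    hit_table: pd.DataFrame
    enrichment: pd.DataFrame | None
    truth: object
    report: dict


def _log_stage(report: dict, stage: str, **counts) -> None:
    report["stages"][stage] = counts
    logger.info(json.dumps({"stage": stage, **{k: _jsonable(v) for k, v in counts.items()}}))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def run_screen_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the screen pipeline in dependency order; fails fast with
    the offending stage named."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.sim.seed, "stages": {}}

    stage = "simulate"
    try:
        rng = np.random.default_rng(config.sim.seed)
        library = generate_library(config.sim, rng)
        matrix, truth = generate_cells(config.sim, library, rng)
        _log_stage(report, stage, guides=len(library), cells=matrix.n_cells, genes=matrix.n_genes)
        if outdir:
            library.to_tsv(outdir / "library.tsv")
            truth.write_tsv(outdir / "ground_truth.tsv")
            config.sim.to_yaml(outdir / "sim_config.yaml")

        stage = "assign"
        if config.assignment_mode == "reads":
            reads = generate_amplicon_reads(config.sim, truth, library, rng)
            if outdir and config.write_fastq:
                reads.to_fastq(outdir / "amplicon.fastq")
            read_table = assign_mod.match_reads(reads, library)
            assignments = assign_mod.assign_cells(read_table)
            n_reads = len(read_table)
        else:
            sing = truth.cell_guides.loc[~truth.cell_guides["is_doublet"]]
            assignments = pd.DataFrame(
                {
                    "category": "unique",
                    "assigned_guide": sing["guide_1"],
                    "support_reads": 0,
                    "total_reads": 0,
                    "support_fraction": 1.0,
                },
                index=sing.index,
            )
            n_reads = 0
        unique = assignments.loc[assignments["category"] == "unique"]
        summary = assign_mod.assignment_summary(assignments) if len(assignments) else {}
        _log_stage(report, stage, reads=n_reads, barcodes=len(assignments),
                   unique_cells=len(unique))
        report["assignment_summary"] = summary
        if outdir:
            assignments.to_csv(outdir / "cell_assignments.tsv", sep="\t")

        stage = "qc"
        profile = qc_mod.PROFILES[config.qc_profile]
        filtered = qc_mod.filter_cells(matrix, profile)
        filtered = qc_mod.filter_genes(filtered, profile=profile)
        report["qc"] = qc_mod.qc_report(matrix, filtered, profile)
        norm = qc_mod.normalize_log(filtered)
        hvg_mask = qc_mod.select_hvg(norm)
        _log_stage(report, stage, cells=filtered.n_cells, genes=filtered.n_genes,
                   hvgs=int(hvg_mask.sum()))
        if outdir:
            filtered.write_mtx(outdir / "filtered_counts")

        stage = "factor"
        matched = assign_mod.match_barcodes(unique, filtered.cells.index)
        analysis_barcodes = matched.index
        cell_pos = {b: i for i, b in enumerate(filtered.cells.index)}
        rows = np.array([cell_pos[b] for b in analysis_barcodes])
        cell_guides = matched["assigned_guide"]
        gene_view = ViewMatrix(
            "genes",
            norm.values[rows][:, hvg_mask],
            norm.genes.index[hvg_mask].tolist(),
        )
        totals = filtered.cells["total_umis"].to_numpy(dtype=float)[rows]
        rep_counts = filtered.repeats.iloc[rows].to_numpy(dtype=float)
        rep_norm = np.log1p(rep_counts / totals[:, None] * qc_mod.SCALE_FACTOR)
        repeat_view = ViewMatrix("repeats", rep_norm, list(filtered.repeats.columns))
        model = MultiViewFactorModel(n_factors=config.n_factors).fit(
            [gene_view, repeat_view], groups=cell_guides.to_numpy()
        )
        signature = truth.signature_genes
        # enrichment is referred to the full post-QC gene universe, of
        # which the fitted gene view is the highly-variable subset
        zga_k, zga_p = identify_zga_factor(model, signature,
                                           universe=norm.genes.index)
        _log_stage(report, stage, analysis_cells=len(rows),
                   zga_factor=None if zga_k is None else zga_k + 1,
                   zga_enrichment_p=zga_p,
                   zga_identified=zga_k is not None)
        if outdir:
            pd.DataFrame(model.factors_, index=analysis_barcodes,
                         columns=model.variance_explained_.columns).to_csv(
                outdir / "factors.tsv", sep="\t")
            for name, w in model.loadings_.items():
                w.to_csv(outdir / f"loadings_{name}.tsv", sep="\t")
            model.variance_explained_.to_csv(outdir / "variance_explained.tsv", sep="\t")

        stage = "hits"
        activation = hits_mod.activation_filter(
            norm.values[rows], norm.genes.index.tolist(), cell_guides, library
        )
        if zga_k is None:
            # no qualifying ZGA-like factor: a valid outcome — there is
            # nothing to regress against, so no hits are reported
            hit_table = hits_mod.call_hits(
                pd.DataFrame(columns=["target_gene", "n_cells", "delta", "pvalue"],
                             index=pd.Index([], name="sgrna_id")),
                fdr=config.fdr,
            )
        else:
            z = pd.Series(model.factors_[:, zga_k], index=analysis_barcodes)
            results = hits_mod.score_sgrnas(z, cell_guides, library, activation=activation)
            hit_table = hits_mod.call_hits(results, fdr=config.fdr)
        n_hits = int(hit_table["is_hit"].sum()) if len(hit_table) else 0
        _log_stage(report, stage, tested_sgrnas=len(hit_table),
                   activation_passing=int(activation["passes_activation"].sum()),
                   hits=n_hits)
        if outdir:
            hit_table.to_csv(outdir / "hit_table.tsv", sep="\t")

        enrichment = None
        if config.run_enrichment:
            stage = "enrich"
            enrichment = _enrichment_stage(config, filtered, rows, cell_guides,
                                           library, truth, hit_table)
            _log_stage(report, stage, curves=len(enrichment),
                       enriched=int((~enrichment["overlaps_background"]).sum()))
            if outdir:
                enrichment.to_csv(outdir / "enrichment.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report["conservation"] = {
        "barcodes_processed": len(assignments),
        "category_sum": int(sum(
            c["count"] for c in report.get("assignment_summary", {}).get("categories", {}).values()
        )) if report.get("assignment_summary") else len(assignments),
        "cells_entering_factor": len(rows),
    }
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return PipelineResult(
        library=library, matrix=filtered, normalized=norm, assignments=assignments,
        cell_guides=cell_guides, model=model, zga_factor=zga_k, zga_p=zga_p,
        activation=activation, hit_table=hit_table, enrichment=enrichment,
        truth=truth, report=report,
    )


def _enrichment_stage(config, filtered, rows, cell_guides, library, truth, hit_table):
    counts = filtered.counts[rows]
    libsizes = filtered.cells["total_umis"].to_numpy(dtype=float)[rows]
    gene_ids = filtered.genes.index.tolist()
    nt_ids = library.nontargeting_ids
    band = dge_mod.nt_background(counts, libsizes, cell_guides.to_numpy(), nt_ids,
                                 truth.signature_genes, gene_ids,
                                 max_rank=config.enrichment_rank)
    rows_out = []
    hit_ids = hit_table.index[hit_table["is_hit"]] if len(hit_table) else []
    for sg in hit_ids:
        curve = dge_mod.sgrna_enrichment_curve(
            counts, libsizes, cell_guides.to_numpy(), sg, nt_ids,
            truth.signature_genes, gene_ids, max_rank=config.enrichment_rank,
        )
        overlaps = dge_mod.enrichment_call(curve, band, rank=config.enrichment_rank)
        final = float(curve[-1]) if len(curve) else 0.0
        rows_out.append((sg, final, overlaps))
    return pd.DataFrame(
        rows_out, columns=["sgrna_id", "signature_genes_at_rank", "overlaps_background"]
    ).set_index("sgrna_id")
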