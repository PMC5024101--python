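"""End-to-end orchestration: discovery -> expression -> annotation -> miRNA.

A single :class:`PipelineConfig` carries every threshold of the workflow
with its standard default (length > 200 nt, ORF <= 300 nt, e-value <=
1e-3, CPC <= 0, flank 500 nt, TSI >= 0.9, stage on/off 3/0.1 FPKM,
co-expression percentile 0.5, propagation alpha 0.8, top rank 100,
enrichment p < 1e-10, expectation <= 3, UPE <= 25) and round-trips to
YAML.  :func:`run_all` executes the stages on a directory of inputs and
writes a machine-readable report whose counts come straight from the
discovery ledger.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import expression_analysis as ea
from . import function_annotation as fa
from . import lincrna_discovery as ld
from . import mirna_interaction as mi
from . import transcript_io as tio

logger = logging.getLogger("linctools")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds plus input/output paths (YAML round-trippable)."""

    # input files (relative to workdir unless absolute)
    transcripts_gtf: str = "transcripts.gtf"
    sequences_fasta: str = "transcripts.fa"
    genes_gff3: str = "genes.gff3"
    protein_hits_tsv: str = "protein_hits.tsv"
    domain_hits_tsv: str = "domain_hits.tsv"
    cpc_scores_tsv: str = "cpc_scores.tsv"
    fpkm_tsv: str = "fpkm.tsv"
    ppi_tsv: str = "ppi.tsv"
    go_tsv: str = "go_annotations.tsv"
    mirna_fasta: str = "mirnas.fa"
    linc_fasta_override: str = ""   # scan this FASTA instead of discovery output
    upe_tsv: str = ""               # optional target-accessibility table
    # thresholds (study defaults)
    min_length: int = 200
    max_orf: int = 300
    evalue_cutoff: float = 1e-3
    cpc_threshold: float = 0.0
    flank_window: int = 500
    tsi_threshold: float = 0.9
    stage_on_min: float = 3.0
    stage_off_max: float = 0.1
    min_expressed_fpkm: float = 1.0
    coexpr_percentile: float = 0.5
    alpha: float = 0.8
    propagation_tol: float = 1e-6
    top_rank: int = 100
    enrich_p_threshold: float = 1e-10
    max_expectation: float = 3.0
    max_upe: float = 25.0
    top_coexpressed_k: int = 10
    seed: int = 0
    schema_version: int = 1

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _resolve(workdir: Path, name: str) -> Path:
    p = Path(name)
    path = p if p.is_absolute() else workdir / p
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return path


def run_all(config: PipelineConfig, workdir: str | Path, out_dir: str | Path) -> dict:
    """Run every stage in order and return the machine-readable run report.

    Any stage failure is re-raised with the stage name attached.  The
    report echoes all parameters, the seed and the package version; its
    counts are taken from the discovery ledger (single source of truth).
    """
    workdir, out_dir = Path(workdir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }
    t0 = time.time()

    def _stage(name):
        logger.info("stage %s", name)
        return name

    stage = _stage("discovery")
    try:
        transcripts = tio.read_transcripts(_resolve(workdir, config.transcripts_gtf))
        sequences = tio.read_fasta(_resolve(workdir, config.sequences_fasta))
        genes = tio.read_genes(_resolve(workdir, config.genes_gff3))
        evidence = ld.EvidenceTable.from_files(
            _resolve(workdir, config.protein_hits_tsv),
            _resolve(workdir, config.domain_hits_tsv),
            _resolve(workdir, config.cpc_scores_tsv),
        )
        records, ledger = ld.run_discovery(
            transcripts, sequences, evidence, genes,
            ld.DiscoveryConfig(config.min_length, config.max_orf,
                               config.evalue_cutoff, config.cpc_threshold,
                               config.flank_window),
        )
        ledger.write_tsv(out_dir / "filter_ledger.tsv")
        features, summary = ld.compute_features(records, sequences)
        features.to_csv(out_dir / "lincrna_features.tsv", sep="\t", index=False)
        by_tid = {r.transcript_id: r for r in records}
        linc_models = [t for t in transcripts if t.transcript_id in by_tid]
        tio.write_bed(linc_models, out_dir / "lincrnas.bed")
        linc_seqs = {by_tid[t.transcript_id].linc_id: sequences[t.transcript_id]
                     for t in linc_models}
        tio.write_fasta(linc_seqs, out_dir / "lincrnas.fa")
        report["stages"]["discovery"] = {
            "ledger": ledger.to_frame().to_dict(orient="records"),
            "n_lincrnas": len(records),
            "mean_length": summary["mean_length"],
            "mean_exon_count": summary["mean_exon_count"],
            "fraction_single_exon": summary["fraction_single_exon"],
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = _stage("expression")
    try:
        fpkm = ea.read_fpkm(_resolve(workdir, config.fpkm_tsv))
        source_ids = {r.transcript_id for r in records}
        id_map = {r.transcript_id: r.linc_id for r in records}
        linc_rows = [i for i in fpkm.index if i in source_ids or str(i).startswith("Ca_linc")]
        mrna_rows = [i for i in fpkm.index if i not in set(linc_rows)]
        linc_fpkm = fpkm.loc[linc_rows].rename(index=id_map)
        mrna_fpkm = fpkm.loc[mrna_rows]
        tsi = ea.compute_tsi_table(linc_fpkm)
        tsi.to_csv(out_dir / "tsi.tsv", sep="\t")
        per_tissue, heat = ea.call_tissue_specific(linc_fpkm, config.tsi_threshold)
        heat.to_csv(out_dir / "tissue_specific_zscores.tsv", sep="\t")
        coexpr = ea.spearman_coexpression(linc_fpkm, mrna_fpkm)
        coexpr.to_edge_frame().to_csv(out_dir / "coexpression.tsv", sep="\t", index=False)
        classes = ea.expression_class_counts(linc_fpkm, statistic="mean")
        n_specific = sum(len(v) for v in per_tissue.values())
        report["stages"]["expression"] = {
            "n_tissue_specific": n_specific,
            "per_tissue_specific": {k: len(v) for k, v in per_tissue.items()},
            "expression_classes": classes.to_dict(),
            "expressed_per_tissue": ea.count_expressed_per_tissue(
                linc_fpkm, config.min_expressed_fpkm).to_dict(),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = _stage("annotation")
    try:
        ppi = fa.load_ppi_edges(_resolve(workdir, config.ppi_tsv))
        go = fa.load_go_annotations(_resolve(workdir, config.go_tsv))
        # candidate pair universe: lincRNA-mRNA and mRNA-mRNA
        combined = pd.concat([linc_fpkm, mrna_fpkm])
        all_rho = ea.spearman_coexpression(combined, combined).rho
        mrna_list = list(mrna_fpkm.index)
        linc_list = list(linc_fpkm.index)
        pair_rho: dict[tuple[str, str], float] = {}
        for i, a in enumerate(mrna_list):
            for b in mrna_list[i + 1:]:
                pair_rho[(a, b)] = float(all_rho.loc[a, b])
        for a in linc_list:
            for b in mrna_list:
                pair_rho[(a, b)] = float(all_rho.loc[a, b])
        edges = fa.build_coexpression_edges(pair_rho, config.coexpr_percentile)
        colors = {n: "lincRNA" for n in linc_list}
        colors.update({n: "mRNA" for n in mrna_list})
        net = fa.combine_network(edges, ppi, colors)
        net.attach_go(go)
        net.write_graphml(out_dir / "bicolor_network.graphml")
        scores = fa.propagate(net, alpha=config.alpha, tol=config.propagation_tol)
        assigned = fa.assign_annotations(scores, net, config.top_rank)
        with open(out_dir / "lincrna_annotations.tsv", "w") as fh:
            fh.write("linc_id\tgo_term\tscore\n")
            for linc in sorted(assigned):
                for term in sorted(assigned[linc]):
                    fh.write(f"{linc}\t{term}\t{scores.F.loc[linc, term]:.6g}\n")
        n_annotated = sum(1 for terms in assigned.values() if terms)
        report["stages"]["annotation"] = {
            "n_network_nodes": len(net.nodes),
            "n_coexpression_edges": len(edges),
            "propagation_converged": scores.converged,
            "n_annotated_lincrnas": n_annotated,
            "fraction_annotated": n_annotated / max(1, len(assigned)),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    stage = _stage("mirna")
    try:
        mirnas = mi.read_mirnas(_resolve(workdir, config.mirna_fasta))
        scan_seqs = dict(linc_seqs)
        if config.linc_fasta_override:
            override = tio.read_fasta(_resolve(workdir, config.linc_fasta_override))
            scan_seqs = {id_map.get(k, k): v for k, v in override.items()}
        upe = None
        if config.upe_tsv:
            upe = pd.read_csv(_resolve(workdir, config.upe_tsv), sep="\t")
        hits = mi.scan_targets(mirnas, scan_seqs, config.max_expectation,
                               upe, config.max_upe)
        network = mi.build_network(hits)
        network.write_graphml(out_dir / "mirna_network.graphml")
        network.edges_frame().to_csv(out_dir / "mirna_pairs.tsv", sep="\t", index=False)
        with open(out_dir / "mirna_hits.tsv", "w") as fh:
            fh.write("linc_id\tmirna_id\tstart\tend\texpectation\tprimary\n")
            for h in hits:
                fh.write(f"{h.linc_id}\t{h.mirna_id}\t{h.target_start}\t"
                         f"{h.target_end}\t{h.expectation:g}\t{int(h.primary)}\n")
        report["stages"]["mirna"] = network.summary()
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    report["runtime_s"] = round(time.time() - t0, 3)
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
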