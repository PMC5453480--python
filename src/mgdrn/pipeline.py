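"""End-to-end pipeline: catalog → expression → diffnet → topology → synergy.

A single :class:`RunConfig` (loadable from YAML) drives the full analysis
and writes every intermediate artifact plus a manifest and a run log that
records the parameters and the count surviving each stage, so a run on real
data can be compared against a published narrative stage by stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import catalog as catalog_mod
from . import diffnet as diffnet_mod
from . import expression as expression_mod
from . import synergy as synergy_mod
from . import topology as topology_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Input paths and analysis parameters for one pipeline run.

    Defaults are the conventional thresholds for this analysis: consensus of
    ≥2 prediction sources, |log2 FC| > 1, correlation difference > 0.2,
    top-10 centrality lists, enrichment at P < 0.05.
    """

    gene_expression: str = ""
    mirna_expression: str = ""
    conditions: str = ""
    prediction_tables: list[str] = field(default_factory=list)
    source_names: list[str] = field(default_factory=list)
    mature_map: str | None = None
    gmt: str | None = None
    output_dir: str = "mgdrn_out"

    min_sources: int = 2
    log2fc_threshold: float = 1.0
    pseudocount: float = 0.01
    delta_threshold: float = 0.2
    difference_mode: str = "signed"
    filter_mirnas: bool = False
    top_k: int = 10
    closeness_mode: str = "normalized"
    alpha: float = 0.05
    bh_correct: bool = False
    linkage: str = "complete"
    min_density: float = 0.8
    min_module_rows: int = 2
    min_module_cols: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("log2fc_threshold", "pseudocount", "delta_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return a manifest of written artifacts.

    Any stage's fatal error aborts the run with a stage-named
    :class:`PipelineError`; artifacts written by earlier stages remain on
    disk and the (partial) manifest is saved alongside them.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "counts": {}, "parameters": {}, "complete": False}
    manifest["parameters"] = {
        k: v for k, v in vars(config).items()
        if isinstance(v, (int, float, str, bool, list)) or v is None
    }
    log_lines: list[str] = []

    def _log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def _finish() -> None:
        with open(outdir / "run_log.txt", "w") as handle:
            handle.write("\n".join(log_lines) + "\n")
        manifest["artifacts"]["run_log"] = str(outdir / "run_log.txt")
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")

    try:
        # ---- catalog ----------------------------------------------------
        stage = "catalog"
        try:
            tables = catalog_mod.load_prediction_tables(
                config.prediction_tables, config.source_names
            )
            if config.mature_map:
                mmap = catalog_mod.MatureMap.from_tsv(config.mature_map)
                tables = [catalog_mod.map_to_mature(t, mmap) for t in tables]
            cat = catalog_mod.build_catalog(tables, min_sources=config.min_sources)
            raw_pairs = len({p for t in tables for p in t.pairs})
            _log(f"catalog: {raw_pairs} raw pairs across {len(tables)} sources")
            _log(
                f"catalog: {len(cat)} consensus pairs "
                f"({len(cat.mirnas)} miRNAs, {len(cat.genes)} genes) "
                f"at min_sources={config.min_sources}"
            )
            cat.write_tsv(outdir / "catalog.tsv")
            manifest["artifacts"]["catalog"] = str(outdir / "catalog.tsv")
            manifest["counts"]["consensus_pairs"] = len(cat)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- expression --------------------------------------------------
        stage = "expression"
        try:
            expr_genes = expression_mod.load_expression(
                config.gene_expression, config.conditions
            )
            expr_mirnas = expression_mod.load_expression(
                config.mirna_expression, config.conditions
            )
            de_table = expression_mod.compute_log2_fold_change(
                expr_genes, pseudocount=config.pseudocount
            )
            de_genes = expression_mod.select_differential(
                de_table, threshold=config.log2fc_threshold
            )
            mirna_de_table = expression_mod.compute_log2_fold_change(
                expr_mirnas, pseudocount=config.pseudocount
            )
            mirna_fc = mirna_de_table.log2_fc_of()
            if config.filter_mirnas:
                de_mirnas = expression_mod.select_differential(
                    mirna_de_table, threshold=config.log2fc_threshold
                )
                cat = catalog_mod.InteractionCatalog(
                    records={
                        pair: rec for pair, rec in cat.records.items()
                        if pair[0] in de_mirnas
                    }
                )
                _log(
                    f"expression: miRNA FC filter kept {len(de_mirnas)} miRNAs, "
                    f"{len(cat)} catalog pairs remain"
                )
            _log(
                f"expression: {len(de_genes)} differentially expressed genes "
                f"of {len(expr_genes.entity_ids)} at |log2FC| > "
                f"{config.log2fc_threshold}"
            )
            de_table.write_tsv(outdir / "de_table.tsv")
            manifest["artifacts"]["de_table"] = str(outdir / "de_table.tsv")
            manifest["counts"]["de_genes"] = len(de_genes)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- diffnet -----------------------------------------------------
        stage = "diffnet"
        try:
            net_normal = diffnet_mod.build_condition_network(
                expr_genes, expr_mirnas, cat, de_genes, "normal"
            )
            net_tumor = diffnet_mod.build_condition_network(
                expr_genes, expr_mirnas, cat, de_genes, "tumor"
            )
            _log(
                f"diffnet: {len(net_normal)} normal edges, "
                f"{len(net_tumor)} tumor edges (pcc < 0)"
            )
            mgdrn = diffnet_mod.build_mgdrn(
                net_normal, net_tumor, cat, de_table,
                delta_threshold=config.delta_threshold,
                mirna_log2_fc=mirna_fc,
                difference_mode=config.difference_mode,
            )
            n_up, n_down = len(mgdrn.up_edges()), len(mgdrn.down_edges())
            _log(
                f"diffnet: MGDRN has {len(mgdrn.edges)} edges between "
                f"{len(mgdrn.mirnas)} miRNAs and {len(mgdrn.genes)} genes "
                f"({n_up} up, {n_down} down) at |delta| > "
                f"{config.delta_threshold}"
            )
            net_normal.write_tsv(outdir / "network_normal.tsv")
            net_tumor.write_tsv(outdir / "network_tumor.tsv")
            mgdrn.write_tsv(outdir / "mgdrn_edges.tsv")
            mgdrn.write_graphml(outdir / "mgdrn.graphml")
            manifest["artifacts"].update(
                {
                    "network_normal": str(outdir / "network_normal.tsv"),
                    "network_tumor": str(outdir / "network_tumor.tsv"),
                    "mgdrn_edges": str(outdir / "mgdrn_edges.tsv"),
                    "mgdrn_graphml": str(outdir / "mgdrn.graphml"),
                }
            )
            manifest["counts"].update(
                {
                    "mgdrn_edges": len(mgdrn.edges),
                    "mgdrn_mirnas": len(mgdrn.mirnas),
                    "mgdrn_genes": len(mgdrn.genes),
                    "up_edges": n_up,
                    "down_edges": n_down,
                }
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- topology ----------------------------------------------------
        stage = "topology"
        try:
            graph = mgdrn.to_networkx()
            table = topology_mod.centrality_table(
                graph, closeness_mode=config.closeness_mode
            )
            table.to_csv(outdir / "centrality.tsv", sep="\t",
                         float_format="%.10g")
            report = topology_mod.key_regulator_report(
                graph, k=config.top_k, restrict_to="mirna",
                closeness_mode=config.closeness_mode,
            )
            topology_mod.write_key_regulator_report(
                report, outdir / "key_regulators.json"
            )
            _log(
                f"topology: {len(report['intersection'])} key regulators in "
                f"the top-{config.top_k} intersection"
            )
            manifest["artifacts"].update(
                {
                    "centrality": str(outdir / "centrality.tsv"),
                    "key_regulators": str(outdir / "key_regulators.json"),
                }
            )
            manifest["counts"]["key_regulators"] = len(report["intersection"])
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- synergy -----------------------------------------------------
        stage = "synergy"
        try:
            if not config.gmt:
                raise ValueError("no GMT pathway file configured")
            pathways = synergy_mod.load_gmt(config.gmt)
            universe = cat.genes & set(expr_genes.entity_ids)
            enr = synergy_mod.enrichment_table(mgdrn, pathways, universe)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.10g")
            matrix = synergy_mod.significance_matrix(
                mgdrn, pathways, universe, alpha=config.alpha,
                bh_correct=config.bh_correct,
            )
            matrix.to_csv(outdir / "significance_matrix.tsv", sep="\t",
                          float_format="%.10g")
            modules = synergy_mod.bicluster_modules(
                matrix, linkage=config.linkage,
                min_density=config.min_density,
                min_rows=config.min_module_rows,
                min_cols=config.min_module_cols,
            )
            synergy_mod.write_modules(modules, outdir / "modules.json")
            synergy_mod.plot_significance_heatmap(
                matrix, outdir / "heatmap.png", linkage=config.linkage
            )
            _log(
                f"synergy: {matrix.shape[0]}x{matrix.shape[1]} significance "
                f"matrix at alpha={config.alpha}; {len(modules)} modules"
            )
            manifest["artifacts"].update(
                {
                    "enrichment": str(outdir / "enrichment.tsv"),
                    "significance_matrix": str(outdir / "significance_matrix.tsv"),
                    "modules": str(outdir / "modules.json"),
                    "heatmap": str(outdir / "heatmap.png"),
                }
            )
            manifest["counts"]["modules"] = len(modules)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        manifest["complete"] = True
        return manifest
    finally:
        _finish()
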