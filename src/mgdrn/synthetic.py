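"""Synthetic tumor/normal datasets with planted, recoverable structure.

The generator emulates the statistical structure the pipeline assumes,
at desk scale:

* miRNA profiles are log-normal; each planted ("true") miRNA→target edge
  couples the target's log-expression linearly and negatively to its miRNA's,
  with the coupling strength β calibrated — separately per condition —
  against the exact correlation of exponentiated bivariate normals, so the
  expected Pearson correlation of the RPKM-scale profiles hits the
  configured target. Dysregulated edges use an attenuated tumor target
  (repression weakened in tumor), the paper-style rewiring signal.
* Every true-edge target (and a set of edge-free genes) receives a ±mag
  log2 fold-change mean shift in tumor, so planted edges survive the
  differential-expression gate.
* Multi-source prediction tables: true edges appear in ≥2 sources; decoys
  in exactly one source (removed by the consensus filter) plus a small
  number of multi-source decoys with no expression coupling (removed only
  by the correlation filters). A fraction of rows is written with the
  precursor (pre-miRNA) spelling to exercise mature-name mapping.
* Pathway gene sets are built so that each planted synergy module's miRNAs
  have their dysregulated targets concentrated in the module's pathways.

Randomness comes from a single ``numpy.random.default_rng`` (PCG64) seeded
from ``config.seed``; identical configs produce bit-identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .catalog import MatureMap, PredictionTable
from .expression import ExpressionMatrix
from .synergy import PathwayCollection, SynergyModule

import pandas as pd

_SOURCE_NAMES = (
    "targetscan", "rnahybrid", "rna22", "pictar5", "mirbase", "miranda",
    "diana",
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults define the reference fixture: 200 genes × 50 miRNAs over 60+60
    samples, 150 true edges of which 100 are dysregulated (PCC target −0.7
    in normal attenuated to −0.1 in tumor, a ΔPCC of 0.6 well past the 0.2
    pipeline gate), two planted synergy modules of 3×12 and 4×4.
    """

    n_genes: int = 200
    n_mirnas: int = 50
    n_normal_samples: int = 60
    n_tumor_samples: int = 60
    n_true_edges: int = 150
    n_dysregulated_edges: int = 100
    pcc_normal_target: float = -0.7
    pcc_tumor_target_dysregulated: float = -0.1
    de_log2fc_magnitude: float = 2.0
    n_sources: int = 7
    decoy_pair_count: int = 200
    multi_source_decoy_count: int = 10
    pathway_count: int = 30
    pathway_size: int = 20
    planted_modules: tuple[tuple[int, int], ...] = ((3, 12), (4, 4))
    module_targets_per_mirna: int = 8
    module_pathway_overlap: int = 5
    n_free_de_genes: int = 20
    mirna_log_sd: float = 0.4
    noise_sd: float = 0.15
    gene_log_sd: float = 0.4
    precursor_spelling_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_normal_samples, self.n_tumor_samples) < 3:
            raise ValueError("need >= 3 samples per condition")
        if self.n_true_edges > self.n_genes:
            raise ValueError(
                f"{self.n_true_edges} true edges need distinct target genes "
                f"but only {self.n_genes} genes exist"
            )
        if self.n_dysregulated_edges > self.n_true_edges:
            raise ValueError("dysregulated edges must be a subset of true edges")
        module_mirnas = sum(m for m, _ in self.planted_modules)
        if module_mirnas > self.n_mirnas:
            raise ValueError("planted modules need more miRNAs than exist")
        if module_mirnas * self.module_targets_per_mirna > self.n_dysregulated_edges:
            raise ValueError(
                "planted modules need more dysregulated edges than configured"
            )
        if sum(p for _, p in self.planted_modules) > self.pathway_count:
            raise ValueError("planted modules need more pathways than configured")
        if not -1.0 < self.pcc_normal_target < 0.0:
            raise ValueError("pcc_normal_target must lie in (-1, 0)")
        if self.n_sources < 2:
            raise ValueError("need at least 2 prediction sources")
        free = self.n_genes - self.n_true_edges
        if self.n_free_de_genes > free:
            raise ValueError("not enough edge-free genes for free DE genes")


@dataclass
class SyntheticTruth:
    """Planted ground truth for scoring pipeline output."""

    true_edges: dict[tuple[str, str], tuple[float, float]]  # pair -> (pcc_n, pcc_t)
    dysregulated_edges: set[tuple[str, str]]
    de_genes: dict[str, float]  # gene -> signed planted log2 fc
    module_truth: list[tuple[frozenset[str], frozenset[str]]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_edges": [
                {"mirna": m, "gene": g, "pcc_normal": pn, "pcc_tumor": pt}
                for (m, g), (pn, pt) in sorted(self.true_edges.items())
            ],
            "dysregulated_edges": sorted(
                [list(p) for p in self.dysregulated_edges]
            ),
            "de_genes": dict(sorted(self.de_genes.items())),
            "modules": [
                {"mirnas": sorted(ms), "pathways": sorted(ps)}
                for ms, ps in self.module_truth
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)
            handle.write("\n")


@dataclass
class SyntheticDataset:
    gene_expression: ExpressionMatrix
    mirna_expression: ExpressionMatrix
    prediction_tables: list[PredictionTable]
    mature_map: MatureMap
    pathways: PathwayCollection
    truth: SyntheticTruth
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write every artifact in the pipeline's input dialects."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        self.gene_expression.write_tsv(
            outdir / "gene_expression.tsv", outdir / "conditions.tsv"
        )
        manifest["gene_expression"] = str(outdir / "gene_expression.tsv")
        manifest["conditions"] = str(outdir / "conditions.tsv")
        self.mirna_expression.write_tsv(outdir / "mirna_expression.tsv")
        manifest["mirna_expression"] = str(outdir / "mirna_expression.tsv")
        pred_dir = outdir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        for table in self.prediction_tables:
            path = pred_dir / f"{table.source_name}.tsv"
            with open(path, "w") as handle:
                handle.write("# mirna\tgene\n")
                for mirna, gene in sorted(table.pairs):
                    handle.write(f"{mirna}\t{gene}\n")
            manifest[f"predictions/{table.source_name}"] = str(path)
        with open(outdir / "mature_map.tsv", "w") as handle:
            for pre, matures in sorted(self.mature_map.entries.items()):
                for mature in matures:
                    handle.write(f"{pre}\t{mature}\n")
        manifest["mature_map"] = str(outdir / "mature_map.tsv")
        self.pathways.write_gmt(outdir / "pathways.gmt")
        manifest["pathways"] = str(outdir / "pathways.gmt")
        self.truth.to_json(outdir / "truth.json")
        manifest["truth"] = str(outdir / "truth.json")
        return manifest


def lognormal_pcc(beta: float, sigma_m: float, noise_sd: float) -> float:
    """Exact Pearson correlation of the exponentiated coupled pair.

    With miRNA log-expression U ~ N(μ, σ_m²) and target log-expression
    V = ν − βU + ε, ε ~ N(0, τ²), the correlation of e^U and e^V is
    (exp(−βσ_m²) − 1) / sqrt((exp(σ_m²) − 1)(exp(β²σ_m² + τ²) − 1)).
    """
    s2 = sigma_m**2
    var_v = beta**2 * s2 + noise_sd**2
    num = math.exp(-beta * s2) - 1.0
    den = math.sqrt((math.exp(s2) - 1.0) * (math.exp(var_v) - 1.0))
    return num / den


def calibrate_beta(
    target_pcc: float, sigma_m: float, noise_sd: float
) -> float:
    """Coupling strength whose expected RPKM-scale PCC equals ``target_pcc``.

    The correlation is 0 at β = 0, decreases to a minimum (most negative
    attainable value for these variances) and rises back toward 0; the root
    on the decreasing branch is found by bisection. Targets beyond the
    attainable minimum are a configuration error.
    """
    if not -1.0 < target_pcc < 0.0:
        raise ValueError(f"target PCC must lie in (-1, 0), got {target_pcc}")
    res = minimize_scalar(
        lambda b: lognormal_pcc(b, sigma_m, noise_sd), bounds=(0.0, 50.0),
        method="bounded",
    )
    beta_min, pcc_min = float(res.x), float(res.fun)
    if target_pcc < pcc_min:
        raise ValueError(
            f"target PCC {target_pcc} unattainable: minimum is {pcc_min:.3f} "
            f"for mirna_log_sd={sigma_m}, noise_sd={noise_sd}"
        )
    return float(
        brentq(
            lambda b: lognormal_pcc(b, sigma_m, noise_sd) - target_pcc,
            1e-12, beta_min, xtol=1e-12,
        )
    )


def _source_names(n: int) -> list[str]:
    names = list(_SOURCE_NAMES[:n])
    names += [f"source{i + 1}" for i in range(len(names), n)]
    return names


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset plus its ground truth, reproducibly from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    mirna_pre = [f"hsa-mir-{100 + i}" for i in range(config.n_mirnas)]
    mirna_ids = [f"{pre}-3p" for pre in mirna_pre]
    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    n_n, n_t = config.n_normal_samples, config.n_tumor_samples
    sample_ids = [f"n{i:03d}" for i in range(n_n)] + [f"t{i:03d}" for i in range(n_t)]
    condition_of = {s: ("normal" if s.startswith("n") else "tumor") for s in sample_ids}
    n_samples = n_n + n_t
    normal_cols = np.arange(n_n)
    tumor_cols = np.arange(n_n, n_samples)

    # --- plant edge structure -------------------------------------------
    module_mirna_total = sum(m for m, _ in config.planted_modules)
    mirna_order = rng.permutation(config.n_mirnas)
    module_mirna_idx = mirna_order[:module_mirna_total]
    other_mirna_idx = mirna_order[module_mirna_total:]

    gene_order = rng.permutation(config.n_genes)
    edge_gene_idx = gene_order[: config.n_true_edges]
    free_gene_idx = gene_order[config.n_true_edges:]
    dys_gene_idx = edge_gene_idx[: config.n_dysregulated_edges]
    nondys_gene_idx = edge_gene_idx[config.n_dysregulated_edges:]

    edge_of_gene: dict[int, int] = {}  # gene idx -> mirna idx
    module_mirna_groups: list[list[int]] = []
    pos = 0
    for n_mod_mirnas, _ in config.planted_modules:
        module_mirna_groups.append(list(module_mirna_idx[pos:pos + n_mod_mirnas]))
        pos += n_mod_mirnas

    gene_cursor = 0
    mirna_dys_targets: dict[int, list[int]] = {}
    for group in module_mirna_groups:
        for m in group:
            take = list(dys_gene_idx[gene_cursor:gene_cursor + config.module_targets_per_mirna])
            gene_cursor += config.module_targets_per_mirna
            mirna_dys_targets[m] = take
            for g in take:
                edge_of_gene[g] = m
    spread_pool = list(other_mirna_idx) if len(other_mirna_idx) else list(module_mirna_idx)
    for j, g in enumerate(dys_gene_idx[gene_cursor:]):
        m = spread_pool[j % len(spread_pool)]
        edge_of_gene[g] = m
        mirna_dys_targets.setdefault(m, []).append(g)
    all_mirna_cycle = list(mirna_order)
    for j, g in enumerate(nondys_gene_idx):
        edge_of_gene[g] = all_mirna_cycle[j % len(all_mirna_cycle)]

    dys_gene_set = set(dys_gene_idx)
    free_de_idx = set(free_gene_idx[: config.n_free_de_genes])

    # --- expression -----------------------------------------------------
    sigma_m, tau = config.mirna_log_sd, config.noise_sd
    beta_normal = calibrate_beta(config.pcc_normal_target, sigma_m, tau)
    if config.pcc_tumor_target_dysregulated >= 0:
        raise ValueError("tumor PCC target must be negative (attenuated, not flipped)")
    beta_tumor_dys = calibrate_beta(
        config.pcc_tumor_target_dysregulated, sigma_m, tau
    )

    mirna_mu = rng.uniform(math.log(20.0), math.log(200.0), size=config.n_mirnas)
    z_mirna = rng.standard_normal((config.n_mirnas, n_samples))
    log_mirna = mirna_mu[:, None] + sigma_m * z_mirna

    gene_mu = rng.uniform(math.log(5.0), math.log(100.0), size=config.n_genes)
    de_sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    eps = rng.standard_normal((config.n_genes, n_samples))

    shift = config.de_log2fc_magnitude * math.log(2.0)
    log_gene = np.empty((config.n_genes, n_samples))
    de_truth: dict[str, float] = {}
    for gi in range(config.n_genes):
        if gi in edge_of_gene:
            mi = edge_of_gene[gi]
            b_n = beta_normal
            b_t = beta_tumor_dys if gi in dys_gene_set else beta_normal
            centered = sigma_m * z_mirna[mi]
            row = gene_mu[gi] + tau * eps[gi]
            row = row.copy()
            row[normal_cols] -= b_n * centered[normal_cols]
            row[tumor_cols] -= b_t * centered[tumor_cols]
            row[tumor_cols] += de_sign[gi] * shift
            de_truth[gene_ids[gi]] = de_sign[gi] * config.de_log2fc_magnitude
        else:
            row = gene_mu[gi] + config.gene_log_sd * eps[gi]
            if gi in free_de_idx:
                row[tumor_cols] += de_sign[gi] * shift
                de_truth[gene_ids[gi]] = de_sign[gi] * config.de_log2fc_magnitude
        log_gene[gi] = row

    gene_expr = ExpressionMatrix(
        values=pd.DataFrame(np.exp(log_gene), index=gene_ids, columns=sample_ids),
        condition_of=dict(condition_of),
    )
    mirna_expr = ExpressionMatrix(
        values=pd.DataFrame(np.exp(log_mirna), index=mirna_ids, columns=sample_ids),
        condition_of=dict(condition_of),
    )

    # --- prediction tables ----------------------------------------------
    sources = _source_names(config.n_sources)
    source_pairs: dict[str, set[tuple[str, str]]] = {s: set() for s in sources}
    true_pairs = {
        (mirna_ids[m], gene_ids[g]) for g, m in edge_of_gene.items()
    }
    for g, m in sorted(edge_of_gene.items()):
        pair = (mirna_ids[m], gene_ids[g])
        n_src = int(rng.integers(2, config.n_sources + 1))
        for si in rng.choice(config.n_sources, size=n_src, replace=False):
            source_pairs[sources[si]].add(pair)

    def _sample_decoy_pairs(count: int, taken: set[tuple[str, str]]) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        while len(out) < count:
            m = mirna_ids[int(rng.integers(config.n_mirnas))]
            g = gene_ids[int(rng.integers(config.n_genes))]
            if (m, g) in taken or (m, g) in true_pairs:
                continue
            taken.add((m, g))
            out.append((m, g))
        return out

    taken: set[tuple[str, str]] = set()
    for pair in _sample_decoy_pairs(config.decoy_pair_count, taken):
        source_pairs[sources[int(rng.integers(config.n_sources))]].add(pair)
    for pair in _sample_decoy_pairs(config.multi_source_decoy_count, taken):
        n_src = int(rng.integers(2, min(4, config.n_sources) + 1))
        for si in rng.choice(config.n_sources, size=n_src, replace=False):
            source_pairs[sources[si]].add(pair)

    # a fraction of rows is spelled with the precursor id
    pre_of = {mat: pre for pre, mat in zip(mirna_pre, mirna_ids)}
    tables: list[PredictionTable] = []
    for source in sources:
        rows: set[tuple[str, str]] = set()
        for mirna, gene in sorted(source_pairs[source]):
            if rng.random() < config.precursor_spelling_fraction:
                rows.add((pre_of[mirna], gene))
            else:
                rows.add((mirna, gene))
        tables.append(PredictionTable(source_name=source, pairs=frozenset(rows)))

    # every precursor maps to its measured -3p arm; a few also carry an
    # unmeasured -5p arm to exercise one-to-many expansion downstream
    entries = {pre: (f"{pre}-3p",) for pre in mirna_pre}
    for pre in mirna_pre[:3]:
        entries[pre] = (f"{pre}-3p", f"{pre}-5p")
    mature_map = MatureMap(entries=entries)

    # --- pathways --------------------------------------------------------
    module_truth: list[tuple[frozenset[str], frozenset[str]]] = []
    pathway_defs: dict[str, tuple[str, frozenset[str]]] = {}
    module_dys_targets = {
        g for group in module_mirna_groups for m in group for g in mirna_dys_targets[m]
    }
    filler_pool = [gene_ids[g] for g in range(config.n_genes) if g not in module_dys_targets]
    pathway_no = 0
    for group, (_, n_mod_pathways) in zip(module_mirna_groups, config.planted_modules):
        per_mirna = min(
            config.module_pathway_overlap,
            max(1, config.pathway_size // max(len(group), 1)),
        )
        module_pathway_ids = []
        for _ in range(n_mod_pathways):
            genes: set[str] = set()
            for m in group:
                picks = rng.choice(
                    mirna_dys_targets[m], size=min(per_mirna, len(mirna_dys_targets[m])),
                    replace=False,
                )
                genes.update(gene_ids[g] for g in picks)
            while len(genes) < config.pathway_size:
                genes.add(filler_pool[int(rng.integers(len(filler_pool)))])
            pid = f"path{pathway_no:03d}"
            pathway_no += 1
            pathway_defs[pid] = (f"planted module pathway {pid}", frozenset(genes))
            module_pathway_ids.append(pid)
        module_truth.append(
            (
                frozenset(mirna_ids[m] for m in group),
                frozenset(module_pathway_ids),
            )
        )
    while pathway_no < config.pathway_count:
        genes = {
            filler_pool[i]
            for i in rng.choice(len(filler_pool), size=config.pathway_size, replace=False)
        }
        pid = f"path{pathway_no:03d}"
        pathway_no += 1
        pathway_defs[pid] = (f"background pathway {pid}", frozenset(genes))
    pathways = PathwayCollection(pathways=pathway_defs)

    truth = SyntheticTruth(
        true_edges={
            (mirna_ids[m], gene_ids[g]): (
                config.pcc_normal_target,
                config.pcc_tumor_target_dysregulated
                if g in dys_gene_set else config.pcc_normal_target,
            )
            for g, m in edge_of_gene.items()
        },
        dysregulated_edges={
            (mirna_ids[edge_of_gene[g]], gene_ids[g]) for g in dys_gene_set
        },
        de_genes=de_truth,
        module_truth=module_truth,
    )
    return SyntheticDataset(
        gene_expression=gene_expr,
        mirna_expression=mirna_expr,
        prediction_tables=tables,
        mature_map=mature_map,
        pathways=pathways,
        truth=truth,
        config=config,
    )


def score_edge_recovery(
    predicted: set[tuple[str, str]], truth: SyntheticTruth
) -> tuple[float, float]:
    """Precision and recall of predicted pairs against planted dysregulated edges.

    Precision is 0 by convention when nothing is predicted.
    """
    if not predicted:
        return (0.0, 0.0)
    overlap = len(set(predicted) & truth.dysregulated_edges)
    precision = overlap / len(predicted)
    recall = (
        overlap / len(truth.dysregulated_edges) if truth.dysregulated_edges else 0.0
    )
    return (precision, recall)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def score_module_recovery(
    found: Sequence[SynergyModule], truth: SyntheticTruth
) -> list[float]:
    """Per planted module: best min(row-Jaccard, column-Jaccard) over found modules."""
    scores = []
    for true_mirnas, true_pathways in truth.module_truth:
        best = 0.0
        for module in found:
            score = min(
                _jaccard(module.mirnas, true_mirnas),
                _jaccard(module.pathways, true_pathways),
            )
            best = max(best, score)
        scores.append(best)
    return scores
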