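"""Per-condition negative-correlation networks and the differential network.

For every consensus miRNA→gene candidate whose gene is differentially
expressed, the Pearson correlation of the two expression profiles is computed
separately over normal and over tumor samples. Because miRNAs repress their
targets, only negative correlations count as regulatory evidence; an edge
whose correlation shifts by more than ``delta_threshold`` between conditions
enters the differential network (MGDRN) with a dysregulation direction:

* ``up``   — pcc_tumor > pcc_normal: the negative coupling weakens in tumor
  (repression is lost);
* ``down`` — pcc_tumor < pcc_normal: repression tightens in tumor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .catalog import InteractionCatalog
from .expression import DifferentialExpressionTable, ExpressionMatrix

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for a zero-variance vector."""


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson's correlation coefficient of two equal-length vectors.

    r = Σ(xᵢ−x̄)(yᵢ−ȳ) / sqrt(Σ(xᵢ−x̄)² · Σ(yᵢ−ȳ)²), requiring n ≥ 3 and
    nonzero variance in both vectors (otherwise r is undefined and
    :class:`UndefinedCorrelationError` is raised for the caller to handle).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    # guard round-off just outside [-1, 1]
    return max(-1.0, min(1.0, r))


@dataclass
class ConditionNetwork:
    """Negative-correlation regulatory network for one condition.

    ``edges`` holds pairs with pcc < 0; ``raw_pcc`` additionally keeps the
    unfiltered correlation of every eligible pair (used when differencing the
    two conditions, where the side failing the sign filter still contributes
    its raw value).
    """

    condition: str
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    raw_pcc: dict[tuple[str, str], float] = field(default_factory=dict)
    n_undefined: int = 0
    n_samples: int = 0

    def __len__(self) -> int:
        return len(self.edges)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("mirna\tgene\tpcc\n")
            for (mirna, gene), pcc in sorted(self.edges.items()):
                handle.write(f"{mirna}\t{gene}\t{pcc:.10g}\n")


@dataclass(frozen=True)
class DifferentialEdge:
    mirna_id: str
    gene_id: str
    pcc_normal: float
    pcc_tumor: float

    @property
    def delta(self) -> float:
        return self.pcc_tumor - self.pcc_normal

    @property
    def direction(self) -> str:
        return "up" if self.delta > 0 else "down"


@dataclass
class MGDRN:
    """Bipartite miRNA↔gene differential regulatory network."""

    edges: list[DifferentialEdge] = field(default_factory=list)
    node_log2_fc: dict[str, float] = field(default_factory=dict)

    @property
    def mirnas(self) -> set[str]:
        return {e.mirna_id for e in self.edges}

    @property
    def genes(self) -> set[str]:
        return {e.gene_id for e in self.edges}

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(e.mirna_id, e.gene_id) for e in self.edges}

    def up_edges(self) -> list[DifferentialEdge]:
        return [e for e in self.edges if e.direction == "up"]

    def down_edges(self) -> list[DifferentialEdge]:
        return [e for e in self.edges if e.direction == "down"]

    def targets_of(self, mirna_id: str) -> set[str]:
        return {e.gene_id for e in self.edges if e.mirna_id == mirna_id}

    def to_networkx(self) -> nx.Graph:
        """Undirected bipartite graph with node/edge annotations."""
        graph = nx.Graph()
        for mirna in self.mirnas:
            graph.add_node(mirna, node_type="mirna",
                           log2_fc=self.node_log2_fc.get(mirna, float("nan")))
        for gene in self.genes:
            graph.add_node(gene, node_type="gene",
                           log2_fc=self.node_log2_fc.get(gene, float("nan")))
        for e in self.edges:
            graph.add_edge(e.mirna_id, e.gene_id, pcc_normal=e.pcc_normal,
                           pcc_tumor=e.pcc_tumor, delta=e.delta,
                           direction=e.direction)
        return graph

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("mirna\tgene\tpcc_normal\tpcc_tumor\tdelta\tdirection\n")
            for e in sorted(self.edges, key=lambda e: (e.mirna_id, e.gene_id)):
                handle.write(
                    f"{e.mirna_id}\t{e.gene_id}\t{e.pcc_normal:.10g}\t"
                    f"{e.pcc_tumor:.10g}\t{e.delta:.10g}\t{e.direction}\n"
                )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def _pairwise_pcc(
    expr_genes: ExpressionMatrix,
    expr_mirnas: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    samples: Sequence[str],
) -> tuple[dict[tuple[str, str], float], int]:
    """Raw PCC per (mirna, gene) pair over the given samples, vectorized.

    Pairs whose correlation is undefined (zero variance) are dropped;
    the count of dropped pairs is returned alongside.
    """
    gmat = expr_genes.values.loc[:, list(samples)]
    mmat = expr_mirnas.values.loc[:, list(samples)]

    def _standardize(mat):
        arr = mat.to_numpy(dtype=float)
        arr = arr - arr.mean(axis=1, keepdims=True)
        norm = np.sqrt((arr * arr).sum(axis=1))
        return arr, norm

    garr, gnorm = _standardize(gmat)
    marr, mnorm = _standardize(mmat)
    gidx = {e: i for i, e in enumerate(gmat.index)}
    midx = {e: i for i, e in enumerate(mmat.index)}

    out: dict[tuple[str, str], float] = {}
    n_undefined = 0
    for mirna, gene in pairs:
        gi, mi = gidx[gene], midx[mirna]
        if gnorm[gi] == 0.0 or mnorm[mi] == 0.0:
            n_undefined += 1
            continue
        r = float(garr[gi] @ marr[mi]) / (gnorm[gi] * mnorm[mi])
        out[(mirna, gene)] = max(-1.0, min(1.0, r))
    return out, n_undefined


def build_condition_network(
    expr_genes: ExpressionMatrix,
    expr_mirnas: ExpressionMatrix,
    catalog: InteractionCatalog,
    de_genes: set[str],
    condition: str,
) -> ConditionNetwork:
    """Negative-correlation network over one condition's samples.

    For each catalog pair whose gene is differentially expressed and whose
    miRNA and gene are both measured, the PCC is computed over the samples of
    ``condition``; an edge is retained iff pcc < 0. Zero-variance pairs are
    skipped with a logged count. An empty result is a warning, not an error.
    """
    samples = expr_genes.samples_of(condition)
    if set(expr_genes.sample_ids) != set(expr_mirnas.sample_ids):
        raise ValueError("gene and miRNA matrices must share the same samples")
    if len(samples) < 3:
        raise ValueError(
            f"condition {condition!r} has {len(samples)} samples; need >= 3"
        )
    measured_genes = set(expr_genes.entity_ids)
    measured_mirnas = set(expr_mirnas.entity_ids)
    eligible = [
        (m, g) for (m, g) in catalog.pairs
        if g in de_genes and g in measured_genes and m in measured_mirnas
    ]
    raw, n_undefined = _pairwise_pcc(expr_genes, expr_mirnas, eligible, samples)
    edges = {pair: pcc for pair, pcc in raw.items() if pcc < 0}
    if n_undefined:
        logger.info("%s network: %d zero-variance pairs skipped",
                    condition, n_undefined)
    if not edges:
        logger.warning("%s network is empty", condition)
    return ConditionNetwork(condition=condition, edges=edges, raw_pcc=raw,
                            n_undefined=n_undefined, n_samples=len(samples))


def build_mgdrn(
    net_normal: ConditionNetwork,
    net_tumor: ConditionNetwork,
    catalog: InteractionCatalog,
    de_table: DifferentialExpressionTable,
    delta_threshold: float = 0.2,
    mirna_log2_fc: Mapping[str, float] | None = None,
    difference_mode: str = "signed",
) -> MGDRN:
    """Difference the two condition networks into the MGDRN.

    A pair is eligible if it passed the sign filter (pcc < 0) in at least one
    condition; the other condition contributes its raw (sign-unfiltered)
    correlation. Requiring pcc < 0 in *both* would discard exactly the
    strongest rewiring events, where a negative coupling collapses to zero or
    flips positive. The pair is kept iff the correlation difference strictly
    exceeds ``delta_threshold``; direction is up iff pcc_tumor > pcc_normal.

    ``difference_mode="signed"`` (default) thresholds |pcc_tumor − pcc_normal|,
    the only reading under which up/down directions are well defined;
    ``"magnitude"`` thresholds ||pcc_tumor| − |pcc_normal|| instead.

    Node annotations take gene log2 fold changes from ``de_table`` and miRNA
    values from ``mirna_log2_fc`` when provided. Isolated nodes never arise:
    only endpoint nodes of kept edges are part of the network.
    """
    if difference_mode not in ("signed", "magnitude"):
        raise ValueError(f"unknown difference_mode {difference_mode!r}")
    candidate_pairs = set(net_normal.edges) | set(net_tumor.edges)
    edges: list[DifferentialEdge] = []
    n_skipped = 0
    for pair in sorted(candidate_pairs):
        if pair not in net_normal.raw_pcc or pair not in net_tumor.raw_pcc:
            n_skipped += 1  # undefined correlation on the out-of-network side
            continue
        pcc_n = net_normal.raw_pcc[pair]
        pcc_t = net_tumor.raw_pcc[pair]
        if difference_mode == "signed":
            magnitude = abs(pcc_t - pcc_n)
        else:
            magnitude = abs(abs(pcc_t) - abs(pcc_n))
        if magnitude > delta_threshold:
            edges.append(DifferentialEdge(pair[0], pair[1], pcc_n, pcc_t))
    if n_skipped:
        logger.info("MGDRN: %d pairs skipped (undefined out-of-network PCC)",
                    n_skipped)
    gene_fc = de_table.log2_fc_of()
    node_fc: dict[str, float] = {}
    for e in edges:
        if e.gene_id in gene_fc:
            node_fc[e.gene_id] = float(gene_fc[e.gene_id])
        if mirna_log2_fc is not None and e.mirna_id in mirna_log2_fc:
            node_fc[e.mirna_id] = float(mirna_log2_fc[e.mirna_id])
    return MGDRN(edges=edges, node_log2_fc=node_fc)
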