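"""Pathway-level synergy analysis.

For each miRNA in the differential network, its dysregulated target genes
are tested for over-representation in each pathway gene set with the exact
upper-tail hypergeometric test (sampling targets without replacement from a
gene universe). Cells significant at ``alpha`` form a miRNA × pathway
significance matrix of −log10(p); bi-directional hierarchical clustering of
that matrix, followed by dense-block extraction, yields synergy modules —
groups of miRNAs that jointly dysregulate groups of pathways.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.stats import hypergeom

from .catalog import normalize_id
from .diffnet import MGDRN

logger = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    """Pathway id → (description, member gene set)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.pathways)

    def genes_of(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def ids(self) -> list[str]:
        return list(self.pathways)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for pid, (desc, genes) in self.pathways.items():
                handle.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class EnrichmentRecord:
    mirna_id: str
    pathway_id: str
    overlap_count: int
    target_count: int
    pathway_count_in_universe: int
    universe_size: int
    p_value: float


@dataclass(frozen=True)
class SynergyModule:
    """A set of miRNAs and the pathways they jointly dysregulate."""

    mirnas: frozenset[str]
    pathways: frozenset[str]
    density: float


def load_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: ``id<TAB>description<TAB>gene...`` per line.

    Gene ids are normalized (lower-case, stripped). A line without at least
    one gene, or a duplicated pathway id, is fatal, with the line number.
    """
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f"at least one gene"
                )
            pid = fields[0].strip()
            genes = frozenset(
                normalize_id(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            if pid in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            pathways[pid] = (fields[1].strip(), genes)
    return PathwayCollection(pathways=pathways)


def enrich(
    targets: Iterable[str],
    pathway: Iterable[str],
    universe: Iterable[str],
    ease: bool = False,
    mirna_id: str = "",
    pathway_id: str = "",
) -> EnrichmentRecord:
    """Upper-tail hypergeometric over-representation test.

    With population ``universe`` of size N, K pathway genes in the universe
    and n target genes (both intersected with the universe) sharing k genes,
    p = P(X ≥ k) for X hypergeometric(N, K, n). ``ease`` applies the
    conservative EASE-score variant, deflating the overlap by one
    (p = P(X ≥ k) computed at k−1 successes, i.e. on max(k−1, 0)).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    targets = frozenset(targets) & universe
    pathway = frozenset(pathway) & universe
    n_universe = len(universe)
    n_targets = len(targets)
    n_pathway = len(pathway)
    overlap = len(targets & pathway)
    k_eff = max(overlap - 1, 0) if ease else overlap
    # P(X >= k) == sf(k - 1)
    p = float(hypergeom.sf(k_eff - 1, n_universe, n_pathway, n_targets))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentRecord(
        mirna_id=mirna_id,
        pathway_id=pathway_id,
        overlap_count=overlap,
        target_count=n_targets,
        pathway_count_in_universe=n_pathway,
        universe_size=n_universe,
        p_value=p,
    )


def enrichment_table(
    mgdrn: MGDRN,
    pathways: PathwayCollection,
    universe: Iterable[str],
    ease: bool = False,
) -> pd.DataFrame:
    """All (miRNA, pathway) enrichment tests over the MGDRN's target sets."""
    universe = frozenset(universe)
    rows = []
    for mirna in sorted(mgdrn.mirnas):
        targets = mgdrn.targets_of(mirna)
        for pid in pathways.ids():
            rec = enrich(targets, pathways.genes_of(pid), universe,
                         ease=ease, mirna_id=mirna, pathway_id=pid)
            rows.append(
                {
                    "mirna": mirna,
                    "pathway": pid,
                    "overlap": rec.overlap_count,
                    "targets": rec.target_count,
                    "pathway_size": rec.pathway_count_in_universe,
                    "universe": rec.universe_size,
                    "p_value": rec.p_value,
                }
            )
    return pd.DataFrame(rows)


def significance_matrix(
    mgdrn: MGDRN,
    pathways: PathwayCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
    ease: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """miRNA × pathway matrix of −log10(p) where p < alpha, else 0.

    Each row uses the miRNA's dysregulated targets in the MGDRN. Raw
    p-values are thresholded by default; ``bh_correct`` applies
    Benjamini–Hochberg across all cells first. Rows and columns that end up
    all-zero are dropped (they carry no signal for the clustering step).
    """
    table = enrichment_table(mgdrn, pathways, universe, ease=ease)
    if table.empty:
        return pd.DataFrame()
    pvals = table["p_value"].to_numpy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    table = table.assign(p_eff=pvals)
    mat = table.pivot(index="mirna", columns="pathway", values="p_eff")
    with np.errstate(divide="ignore"):
        sig = np.where(mat.to_numpy() < alpha, -np.log10(mat.to_numpy()), 0.0)
    out = pd.DataFrame(sig, index=mat.index, columns=mat.columns)
    out = out.loc[out.sum(axis=1) > 0, out.sum(axis=0) > 0]
    return out


def _subtree_clusters(link: np.ndarray, n_leaves: int, min_size: int) -> list[frozenset[int]]:
    """All dendrogram-subtree leaf sets of at least ``min_size`` leaves."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n_leaves)}
    clusters: list[frozenset[int]] = []
    for i, (a, b, _, _) in enumerate(link):
        merged = members[int(a)] | members[int(b)]
        members[n_leaves + i] = merged
        if len(merged) >= min_size:
            clusters.append(merged)
    if min_size <= 1:
        clusters.extend(frozenset([i]) for i in range(n_leaves))
    # dedupe preserving determinism
    return sorted(set(clusters), key=lambda s: (len(s), sorted(s)))


def bicluster_modules(
    matrix: pd.DataFrame,
    linkage: str = "complete",
    min_density: float = 0.8,
    min_rows: int = 2,
    min_cols: int = 2,
) -> list[SynergyModule]:
    """Extract dense miRNA × pathway blocks from the significance matrix.

    Rows and columns are clustered independently (Euclidean distance, the
    chosen linkage). Every subtree of each dendrogram is a candidate row or
    column cluster; candidate blocks are their cross products. A block is a
    module iff its fraction of nonzero cells is at least ``min_density`` and
    it spans at least ``min_rows`` miRNAs and ``min_cols`` pathways.
    Qualifying blocks are accepted greedily by (density, cell count)
    descending, then by sorted member ids for determinism; a block
    overlapping an accepted module in both dimensions simultaneously is
    discarded, so reported modules never overlap in both dimensions.
    """
    if linkage not in ("complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if matrix.empty or matrix.shape[0] < min_rows or matrix.shape[1] < min_cols:
        return []
    arr = matrix.to_numpy(dtype=float)
    if not (arr > 0).any():
        return []

    def _clusters(data: np.ndarray, min_size: int) -> list[frozenset[int]]:
        n = data.shape[0]
        if n == 1:
            return [frozenset([0])] if min_size <= 1 else []
        link = scipy_linkage(data, method=linkage, metric="euclidean")
        return _subtree_clusters(link, n, min_size)

    row_clusters = _clusters(arr, min_rows)
    col_clusters = _clusters(arr.T, min_cols)

    candidates: list[tuple[float, int, frozenset[int], frozenset[int]]] = []
    nonzero = arr > 0
    for rows in row_clusters:
        ridx = sorted(rows)
        for cols in col_clusters:
            cidx = sorted(cols)
            block = nonzero[np.ix_(ridx, cidx)]
            density = float(block.mean())
            if density >= min_density:
                candidates.append((density, block.size, rows, cols))

    candidates.sort(
        key=lambda c: (-c[0], -c[1], sorted(c[2]), sorted(c[3]))
    )
    accepted: list[SynergyModule] = []
    taken: list[tuple[frozenset[int], frozenset[int]]] = []
    for density, _, rows, cols in candidates:
        if any(rows & r and cols & c for r, c in taken):
            continue
        taken.append((rows, cols))
        accepted.append(
            SynergyModule(
                mirnas=frozenset(matrix.index[i] for i in rows),
                pathways=frozenset(matrix.columns[j] for j in cols),
                density=density,
            )
        )
    return accepted


def write_modules(modules: list[SynergyModule], path: str | Path) -> None:
    payload = [
        {
            "mirnas": sorted(m.mirnas),
            "pathways": sorted(m.pathways),
            "density": m.density,
        }
        for m in modules
    ]
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")


def plot_significance_heatmap(matrix: pd.DataFrame, path: str | Path,
                              linkage: str = "complete") -> None:
    """Clustered −log10(p) heatmap (rows/columns in dendrogram leaf order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list

    if matrix.empty:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.text(0.5, 0.5, "no significant cells", ha="center", va="center")
        ax.set_axis_off()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return
    arr = matrix.to_numpy(dtype=float)
    row_order = (
        leaves_list(scipy_linkage(arr, method=linkage))
        if arr.shape[0] > 1 else [0]
    )
    col_order = (
        leaves_list(scipy_linkage(arr.T, method=linkage))
        if arr.shape[1] > 1 else [0]
    )
    ordered = matrix.iloc[row_order, col_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * ordered.shape[1]), max(3, 0.25 * ordered.shape[0]))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(ordered.shape[0]))
    ax.set_yticklabels(ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="-log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
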