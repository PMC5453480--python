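import numpy as np
import pandas as pd
import pytest

from mgdrn.diffnet import MGDRN, DifferentialEdge
from mgdrn.synergy import (
    bicluster_modules,
    enrich,
    load_gmt,
    significance_matrix,
)

from oracles import hypergeom_upper_tail


class TestLoadGmt:
    def test_two_line_gmt(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("p1\tdesc one\tG1\tg2\np2\tdesc two\tg3\n")
        coll = load_gmt(path)
        assert len(coll) == 2
        assert coll.genes_of("p1") == {"g1", "g2"}  # normalized

    def test_line_without_genes_is_fatal_with_line_number(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("p1\tdesc\tg1\npempty\tdesc\t\n")
        with pytest.raises(ValueError, match=":2"):
            load_gmt(path)

    def test_duplicate_pathway_id_is_fatal(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("p1\td\tg1\np1\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_gmt(path)


class TestEnrich:
    UNIVERSE = [f"g{i}" for i in range(20)]

    def test_perfect_overlap_closed_form(self):
        # all 5 targets inside a 5-gene pathway: p = 1/C(20,5)
        pathway = self.UNIVERSE[:5]
        rec = enrich(pathway, pathway, self.UNIVERSE)
        assert rec.p_value == pytest.approx(1.0 / 15504.0, rel=1e-12)

    def test_pathway_equal_to_universe_is_certain(self):
        rec = enrich(self.UNIVERSE[:7], self.UNIVERSE, self.UNIVERSE)
        assert rec.p_value == pytest.approx(1.0)

    def test_zero_overlap_is_certain(self):
        rec = enrich(self.UNIVERSE[:5], self.UNIVERSE[10:15], self.UNIVERSE)
        assert rec.overlap_count == 0
        assert rec.p_value == pytest.approx(1.0)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            enrich(["g1"], ["g1"], [])

    def test_ease_variant_deflates_overlap_by_one(self):
        pathway = self.UNIVERSE[:5]
        rec = enrich(pathway, pathway, self.UNIVERSE, ease=True)
        assert rec.p_value == pytest.approx(
            hypergeom_upper_tail(20, 5, 5, 4), rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exact_combinatorial_sum(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            N = int(rng.integers(5, 201))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            pathway = list(rng.choice(universe, size=K, replace=False))
            targets = list(rng.choice(universe, size=n, replace=False))
            rec = enrich(targets, pathway, universe)
            k = len(set(targets) & set(pathway))
            assert rec.overlap_count == k
            assert rec.overlap_count <= min(rec.target_count,
                                            rec.pathway_count_in_universe)
            assert rec.p_value == pytest.approx(
                hypergeom_upper_tail(N, K, n, k), abs=1e-10
            )

    def test_p_monotone_in_overlap_at_fixed_margins(self):
        pvals = [hypergeom_upper_tail(50, 10, 8, k) for k in range(9)]
        assert pvals == sorted(pvals, reverse=True)
        observed = [
            enrich(
                [f"g{i}" for i in range(k)] + [f"x{i}" for i in range(8 - k)],
                [f"g{i}" for i in range(10)],
                [f"g{i}" for i in range(10)] + [f"x{i}" for i in range(40)],
            ).p_value
            for k in range(9)
        ]
        assert observed == pytest.approx(pvals, abs=1e-10)


def _mgdrn(edges):
    return MGDRN(edges=[DifferentialEdge(m, g, -0.7, -0.1) for m, g in edges])


class TestSignificanceMatrix:
    def _collection(self, mapping):
        from mgdrn.synergy import PathwayCollection

        return PathwayCollection(
            pathways={pid: ("", frozenset(genes)) for pid, genes in mapping.items()}
        )

    def test_cells_replay_per_pair_enrichment(self):
        universe = [f"g{i}" for i in range(40)]
        mgdrn = _mgdrn([("m1", g) for g in universe[:5]])
        coll = self._collection({"hit": universe[:5], "miss": universe[20:30]})
        mat = significance_matrix(mgdrn, coll, universe, alpha=0.05)
        p_hit = enrich(universe[:5], universe[:5], universe).p_value
        assert mat.loc["m1", "hit"] == pytest.approx(-np.log10(p_hit))
        assert "miss" not in mat.columns  # all-zero column dropped

    def test_mirna_without_significant_pathway_dropped(self):
        universe = [f"g{i}" for i in range(40)]
        mgdrn = _mgdrn([("m1", g) for g in universe[:5]]
                       + [("m2", universe[30])])
        coll = self._collection({"hit": universe[:5]})
        mat = significance_matrix(mgdrn, coll, universe, alpha=0.05)
        assert list(mat.index) == ["m1"]

    def test_vacuous_alpha_keeps_every_overlapping_cell(self):
        universe = [f"g{i}" for i in range(10)]
        mgdrn = _mgdrn([("m1", universe[0])])
        coll = self._collection({"p1": universe[:3]})
        mat = significance_matrix(mgdrn, coll, universe, alpha=1.0000001)
        assert mat.loc["m1", "p1"] > 0


def _planted_matrix(rng, speckle=0.0):
    """3x12 and 4x4 dense blocks on a 12x24 background, optional speckle."""
    rows = [f"m{i:02d}" for i in range(12)]
    cols = [f"p{i:02d}" for i in range(24)]
    arr = np.zeros((12, 24))
    arr[0:3, 0:12] = rng.uniform(2.0, 6.0, size=(3, 12))
    arr[3:7, 12:16] = rng.uniform(2.0, 6.0, size=(4, 4))
    speckle_mask = (rng.random(arr.shape) < speckle) & (arr == 0)
    arr[speckle_mask] = rng.uniform(1.4, 3.0, size=int(speckle_mask.sum()))
    truth = [
        (frozenset(rows[0:3]), frozenset(cols[0:12])),
        (frozenset(rows[3:7]), frozenset(cols[12:16])),
    ]
    return pd.DataFrame(arr, index=rows, columns=cols), truth


class TestBiclusterModules:
    def test_clean_block_diagonal_recovered_exactly(self):
        mat, truth = _planted_matrix(np.random.default_rng(0))
        modules = bicluster_modules(mat)
        found = {(m.mirnas, m.pathways) for m in modules}
        assert found == set(truth)
        assert all(m.density == 1.0 for m in modules)

    def test_all_zero_matrix_has_no_modules(self):
        mat = pd.DataFrame(np.zeros((4, 4)),
                           index=list("abcd"), columns=list("wxyz"))
        assert bicluster_modules(mat) == []

    def test_degenerate_matrix_has_no_modules(self):
        assert bicluster_modules(pd.DataFrame([[1.0]])) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_speckled_blocks_recovered_with_high_jaccard(self, seed):
        mat, truth = _planted_matrix(np.random.default_rng(seed), speckle=0.1)
        modules = bicluster_modules(mat)

        def jaccard(a, b):
            return len(a & b) / len(a | b)

        for true_rows, true_cols in truth:
            best = max(
                (
                    min(jaccard(m.mirnas, true_rows), jaccard(m.pathways, true_cols))
                    for m in modules
                ),
                default=0.0,
            )
            assert best >= 0.8

    def test_reported_modules_respect_density_and_disjointness(self):
        rng = np.random.default_rng(3)
        mat, _ = _planted_matrix(rng, speckle=0.15)
        modules = bicluster_modules(mat, min_density=0.7)
        for m in modules:
            assert m.density >= 0.7
            assert len(m.mirnas) >= 2 and len(m.pathways) >= 2
        for i, a in enumerate(modules):
            for b in modules[i + 1:]:
                assert not (a.mirnas & b.mirnas and a.pathways & b.pathways)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        mat, _ = _planted_matrix(rng)
        perm_rows = rng.permutation(mat.index)
        perm_cols = rng.permutation(mat.columns)
        shuffled = mat.loc[perm_rows, perm_cols]
        base = {(m.mirnas, m.pathways) for m in bicluster_modules(mat)}
        permuted = {(m.mirnas, m.pathways) for m in bicluster_modules(shuffled)}
        assert base == permuted
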