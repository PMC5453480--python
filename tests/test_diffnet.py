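import numpy as np
import pandas as pd
import pytest

from mgdrn.catalog import PredictionTable, build_catalog
from mgdrn.diffnet import (
    ConditionNetwork,
    DifferentialEdge,
    UndefinedCorrelationError,
    build_condition_network,
    build_mgdrn,
    pearson_correlation,
)
from mgdrn.expression import (
    DifferentialExpressionTable,
    ExpressionMatrix,
    compute_log2_fold_change,
    select_differential,
)
from mgdrn.synthetic import SyntheticConfig, generate_dataset

from conftest import small_config
from oracles import brute_diffnet


class TestPearsonCorrelation:
    def test_exact_anticorrelation_and_identity(self):
        assert pearson_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # cov-sum 2, variance sums 2 and 14/3 -> 2 / sqrt(28/3)
        expected = 2.0 / np.sqrt(28.0 / 3.0)
        assert pearson_correlation([1, 2, 3], [2, 1, 4]) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.6547, abs=1e-4)

    def test_zero_variance_raises_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1.0, 1.0, 1.0], [1, 2, 3])

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([1, 2], [2, 1])

    def test_matches_textbook_implementation_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 50))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert pearson_correlation(x, y) == pytest.approx(
                float(np.corrcoef(x, y)[0, 1]), abs=1e-12
            )


def _make_exprs(gene_rows, mirna_rows, n_normal=4, n_tumor=4):
    samples = [f"n{i}" for i in range(n_normal)] + [f"t{i}" for i in range(n_tumor)]
    cond = {s: ("normal" if s.startswith("n") else "tumor") for s in samples}
    genes = ExpressionMatrix(
        values=pd.DataFrame.from_dict(gene_rows, orient="index", columns=samples),
        condition_of=cond,
    )
    mirnas = ExpressionMatrix(
        values=pd.DataFrame.from_dict(mirna_rows, orient="index", columns=samples),
        condition_of=cond,
    )
    return genes, mirnas


class TestBuildConditionNetwork:
    def test_planted_anticorrelation_is_recovered(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=8)
        y = 100.0 - 9.0 * x + rng.normal(scale=0.05, size=8)
        genes, mirnas = _make_exprs({"g1": y}, {"m1": x})
        cat = build_catalog([PredictionTable("s", frozenset({("m1", "g1")}))], 1)
        net = build_condition_network(genes, mirnas, cat, {"g1"}, "normal")
        assert net.edges[("m1", "g1")] == pytest.approx(-1.0, abs=0.05)

    def test_positive_correlation_is_filtered(self):
        x = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        genes, mirnas = _make_exprs({"g1": 2 * x}, {"m1": x})
        cat = build_catalog([PredictionTable("s", frozenset({("m1", "g1")}))], 1)
        net = build_condition_network(genes, mirnas, cat, {"g1"}, "normal")
        assert ("m1", "g1") not in net.edges
        assert net.raw_pcc[("m1", "g1")] > 0  # raw value retained for differencing

    def test_non_de_gene_is_excluded(self):
        x = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        genes, mirnas = _make_exprs({"g1": -0.5 * x + 10}, {"m1": x})
        cat = build_catalog([PredictionTable("s", frozenset({("m1", "g1")}))], 1)
        net = build_condition_network(genes, mirnas, cat, set(), "normal")
        assert len(net) == 0

    def test_zero_variance_pair_skipped_and_counted(self):
        x = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        genes, mirnas = _make_exprs({"g1": np.full(8, 5.0)}, {"m1": x})
        cat = build_catalog([PredictionTable("s", frozenset({("m1", "g1")}))], 1)
        net = build_condition_network(genes, mirnas, cat, {"g1"}, "normal")
        assert len(net) == 0 and net.n_undefined == 1

    def test_too_few_condition_samples_is_fatal(self):
        genes, mirnas = _make_exprs(
            {"g1": [1.0, 2, 3, 4]}, {"m1": [4.0, 3, 2, 1]},
            n_normal=2, n_tumor=2,
        )
        cat = build_catalog([PredictionTable("s", frozenset({("m1", "g1")}))], 1)
        with pytest.raises(ValueError, match="need >= 3"):
            build_condition_network(genes, mirnas, cat, {"g1"}, "normal")


def _mgdrn_from_pccs(pcc_normal, pcc_tumor, **kwargs):
    """Assemble an MGDRN from literal per-pair correlations."""
    pairs = sorted(pcc_normal)
    net_n = ConditionNetwork(
        "normal",
        edges={p: v for p, v in pcc_normal.items() if v < 0},
        raw_pcc=dict(pcc_normal),
    )
    net_t = ConditionNetwork(
        "tumor",
        edges={p: v for p, v in pcc_tumor.items() if v < 0},
        raw_pcc=dict(pcc_tumor),
    )
    cat = build_catalog(
        [PredictionTable("s", frozenset(pairs))], 1
    )
    de = DifferentialExpressionTable(
        table=pd.DataFrame(
            {"mean_normal": 1.0, "mean_tumor": 4.0, "log2_fc": 2.0, "selected": True},
            index=sorted({g for _, g in pairs}),
        )
    )
    return build_mgdrn(net_n, net_t, cat, de, **kwargs)


class TestBuildMgdrn:
    def test_difference_rule_and_directions(self):
        mgdrn = _mgdrn_from_pccs(
            {("m1", "g1"): -0.6, ("m2", "g2"): -0.30, ("m3", "g3"): -0.05},
            {("m1", "g1"): -0.1, ("m2", "g2"): -0.25, ("m3", "g3"): -0.60},
        )
        by_pair = {(e.mirna_id, e.gene_id): e for e in mgdrn.edges}
        assert set(by_pair) == {("m1", "g1"), ("m3", "g3")}  # |0.05| <= 0.2 dropped
        assert by_pair[("m1", "g1")].delta == pytest.approx(0.5)
        assert by_pair[("m1", "g1")].direction == "up"
        assert by_pair[("m3", "g3")].delta == pytest.approx(-0.55)
        assert by_pair[("m3", "g3")].direction == "down"

    def test_pair_negative_in_only_one_condition_still_eligible(self):
        # a collapse from -0.5 to +0.1 is the strongest rewiring signal
        mgdrn = _mgdrn_from_pccs({("m1", "g1"): -0.5}, {("m1", "g1"): 0.1})
        (edge,) = mgdrn.edges
        assert edge.direction == "up" and edge.delta == pytest.approx(0.6)

    def test_magnitude_mode_uses_absolute_correlations(self):
        pccs_n, pccs_t = {("m1", "g1"): -0.5}, {("m1", "g1"): 0.45}
        assert len(_mgdrn_from_pccs(pccs_n, pccs_t).edges) == 1
        assert (
            _mgdrn_from_pccs(pccs_n, pccs_t, difference_mode="magnitude").edges == []
        )

    def test_up_down_partition_is_exhaustive(self):
        rng = np.random.default_rng(11)
        pairs = [(f"m{i}", f"g{i}") for i in range(40)]
        pn = {p: float(rng.uniform(-1, 0.2)) for p in pairs}
        pt = {p: float(rng.uniform(-1, 0.2)) for p in pairs}
        mgdrn = _mgdrn_from_pccs(pn, pt)
        assert len(mgdrn.up_edges()) + len(mgdrn.down_edges()) == len(mgdrn.edges)
        for e in mgdrn.edges:
            assert abs(e.delta) > 0.2

    def test_swapping_conditions_flips_direction_and_negates_delta(self):
        rng = np.random.default_rng(12)
        pairs = [(f"m{i}", f"g{i}") for i in range(30)]
        pn = {p: float(rng.uniform(-1, 0.2)) for p in pairs}
        pt = {p: float(rng.uniform(-1, 0.2)) for p in pairs}
        fwd = _mgdrn_from_pccs(pn, pt)
        rev = _mgdrn_from_pccs(pt, pn)
        fwd_edges = {(e.mirna_id, e.gene_id): e for e in fwd.edges}
        rev_edges = {(e.mirna_id, e.gene_id): e for e in rev.edges}
        assert set(fwd_edges) == set(rev_edges)
        for pair, e in fwd_edges.items():
            assert rev_edges[pair].delta == pytest.approx(-e.delta)
            assert rev_edges[pair].direction != e.direction


@pytest.mark.parametrize("seed", range(5))
def test_full_stage_matches_brute_force_filter_oracle(seed):
    """catalog→MGDRN equals a literal loop applying every filter, on small
    random instances."""
    dataset = generate_dataset(
        small_config(seed, n_genes=40, n_mirnas=10, n_true_edges=25,
                     n_dysregulated_edges=15, decoy_pair_count=20,
                     planted_modules=((2, 3),), module_targets_per_mirna=5,
                     n_normal_samples=15, n_tumor_samples=15, n_free_de_genes=4)
    )
    cat = build_catalog(dataset.prediction_tables, min_sources=2)
    de_table = compute_log2_fold_change(dataset.gene_expression)
    de_genes = select_differential(de_table, 1.0)
    net_n = build_condition_network(
        dataset.gene_expression, dataset.mirna_expression, cat, de_genes, "normal"
    )
    net_t = build_condition_network(
        dataset.gene_expression, dataset.mirna_expression, cat, de_genes, "tumor"
    )
    mgdrn = build_mgdrn(net_n, net_t, cat, de_table)

    expected = brute_diffnet(
        dataset.gene_expression.values, dataset.mirna_expression.values,
        cat.pairs, de_genes, dataset.gene_expression.condition_of,
    )
    got = {
        (e.mirna_id, e.gene_id): (e.pcc_normal, e.pcc_tumor, e.direction)
        for e in mgdrn.edges
    }
    assert set(got) == set(expected)
    for pair in expected:
        assert got[pair][0] == pytest.approx(expected[pair][0], abs=1e-9)
        assert got[pair][1] == pytest.approx(expected[pair][1], abs=1e-9)
        assert got[pair][2] == expected[pair][2]


def test_mgdrn_edges_stay_within_catalog_and_de_set(default_dataset):
    cat = build_catalog(default_dataset.prediction_tables, min_sources=2)
    de_table = compute_log2_fold_change(default_dataset.gene_expression)
    de_genes = select_differential(de_table, 1.0)
    net_n = build_condition_network(
        default_dataset.gene_expression, default_dataset.mirna_expression,
        cat, de_genes, "normal",
    )
    net_t = build_condition_network(
        default_dataset.gene_expression, default_dataset.mirna_expression,
        cat, de_genes, "tumor",
    )
    mgdrn = build_mgdrn(net_n, net_t, cat, de_table)
    assert mgdrn.pairs <= cat.pairs
    assert mgdrn.genes <= de_genes
    # bipartite with no isolated nodes by construction
    graph = mgdrn.to_networkx()
    assert all(graph.degree[v] >= 1 for v in graph)
    for e in mgdrn.edges:
        assert graph.nodes[e.mirna_id]["node_type"] == "mirna"
        assert graph.nodes[e.gene_id]["node_type"] == "gene"
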