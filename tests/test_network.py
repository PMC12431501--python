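"""Pearson correlation, network thresholding, hubs, shared targets, exports."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
import networkx as nx
from lxml import etree

from seedreg.network import (
    build_network,
    degree_table,
    export_network,
    pearson_r,
    read_edge_tsv,
    shared_targets,
)
from seedreg.simulate import ExpressionSimSpec, ModuleSpec, simulate_expression

from conftest import definitional_pearson


class TestPearsonR:
    def test_perfect_positive(self):
        assert pearson_r([1, 2, 3], [2, 4, 6], min_pairs=3) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_r([1, 2, 3], [6, 4, 2], min_pairs=3) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # deviations (-1.5,-0.5,0.5,1.5) vs (-1.5,0.5,-0.5,1.5):
        # cross sum 4, each sum of squares 5 -> r = 4/5
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4], min_pairs=4) == pytest.approx(0.8)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson_r([1, 2], [1, 2, 3])

    def test_constant_vector_undefined(self):
        assert math.isnan(pearson_r([1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6]))

    def test_pairwise_complete_below_min_pairs_undefined(self):
        x = [1, 2, 3, 4, 5, np.nan]
        y = [2, 1, 4, 3, np.nan, 6]
        assert math.isnan(pearson_r(x, y, min_pairs=6))
        assert not math.isnan(pearson_r(x, y, min_pairs=4))

    @settings(derandomize=True, max_examples=60)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50), st.floats(-50, 50)
            ),
            min_size=6,
            max_size=20,
        ),
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-10, 10),
    )
    def test_symmetry_and_affine_invariance(self, data, a, b):
        x = np.array([d[0] for d in data])
        y = np.array([d[1] for d in data])
        r = pearson_r(x, y)
        if math.isnan(r):
            return
        assert pearson_r(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson_r(a * x + b, y) == pytest.approx(
            math.copysign(1, a) * r, abs=1e-6
        )


class TestBuildNetwork:
    def test_matches_definitional_oracle_on_small_random_matrices(self):
        """Edge sets equal independent recomputation via the raw sum formula,
        for dense and missing-data matrices up to 8x8."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            n_genes = rng.integers(4, 9)
            n_samples = rng.integers(6, 9)
            values = rng.normal(size=(n_genes, n_samples))
            if trial % 2:  # punch missing holes in half the trials
                mask = rng.random(values.shape) < 0.1
                values[mask] = np.nan
            genes = [f"g{i}" for i in range(n_genes)]
            m = pd.DataFrame(values, index=genes)
            k = n_genes // 2
            tf_ids, ssp_ids = genes[:k], genes[k:]
            net = build_network(m, tf_ids, ssp_ids, cutoff=0.5, min_pairs=6)
            got = {(e.tf_id, e.ssp_id): e.r for e in net.edges}
            expected = {}
            for tf in tf_ids:
                for ssp in ssp_ids:
                    x, y = m.loc[tf], m.loc[ssp]
                    ok = ~(x.isna() | y.isna())
                    if ok.sum() < 6:
                        continue
                    xs, ys = list(x[ok]), list(y[ok])
                    if len(set(xs)) == 1 or len(set(ys)) == 1:
                        continue
                    r = definitional_pearson(xs, ys)
                    if abs(r) >= 0.5:
                        expected[(tf, ssp)] = r
            assert got.keys() == expected.keys()
            for pair, r in expected.items():
                assert got[pair] == pytest.approx(r, abs=1e-10)

    def test_planted_pair_yields_single_positive_edge(self):
        spec = ExpressionSimSpec(
            modules=[
                ModuleSpec(tf_ids=["tf1"], ssp_ids=["ssp1"], noise_sd=0.1),
                ModuleSpec(tf_ids=[], ssp_ids=["ssp_noise"], loading=0.0),
            ],
            n_samples=20,
            seed=5,
        )
        m, _ = simulate_expression(spec)
        net = build_network(m, ["tf1"], ["ssp1", "ssp_noise"], cutoff=0.7)
        assert len(net.edges) == 1
        edge = net.edges[0]
        assert (edge.tf_id, edge.ssp_id, edge.sign) == ("tf1", "ssp1", "positive")

    def test_unattainable_cutoff_gives_empty_network(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"))
        net = build_network(m, ["a", "b"], ["c", "d"], cutoff=1.01)
        assert net.edges == []

    def test_constant_tf_profile_produces_no_edges(self):
        m = pd.DataFrame(
            [[1.0] * 8, list(range(8))], index=["tf_const", "ssp1"]
        )
        net = build_network(m, ["tf_const"], ["ssp1"], cutoff=0.7)
        assert net.edges == []

    def test_overlapping_id_lists_rejected(self):
        m = pd.DataFrame(np.ones((2, 8)), index=["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            build_network(m, ["a"], ["a", "b"])


def toy_network():
    """Orthogonal-design matrix whose edge set is exactly
    {(t1,s1), (t1,s2), (t2,s1)}: r(t, t+t') = 1/sqrt(2) for orthogonal
    equal-variance profiles, and orthogonality gives r = 0 elsewhere."""
    from scipy.linalg import hadamard

    h = hadamard(8).astype(float)
    m = pd.DataFrame(
        [h[1], h[2], h[1] + h[2], 2 * h[1], h[4]],
        index=["t1", "t2", "s1", "s2", "s3"],
    )
    net = build_network(m, ["t1", "t2"], ["s1", "s2", "s3"], cutoff=0.7)
    assert {(e.tf_id, e.ssp_id) for e in net.edges} == {
        ("t1", "s1"), ("t1", "s2"), ("t2", "s1")
    }
    return net


class TestDegreeAndSharedTargets:
    def test_degree_table_sorted_with_zero_degree_tfs_listed(self):
        net = toy_network()
        table = degree_table(net)
        assert list(table["tf_id"])[0] == "t1"
        assert set(table["tf_id"]) == {"t1", "t2"}
        assert table["degree"].sum() == len(net.edges)

    def test_degrees_sum_to_edge_count_on_fixture(self, fixture_dir):
        import seedreg.expression as ex

        m = ex.read_expression_matrix(fixture_dir["expression.tsv"])
        roles = ex.read_role_table(fixture_dir["roles.tsv"])
        tf, ssp = ex.partition_candidates(list(m.index), roles)
        net = build_network(m, tf, ssp)
        assert degree_table(net)["degree"].sum() == len(net.edges)

    def test_planted_degree_ranking_recovered(self):
        spec = ExpressionSimSpec(
            modules=[
                ModuleSpec(tf_ids=["tA"], ssp_ids=[f"a{i}" for i in range(5)],
                           noise_sd=1 / 3),
                ModuleSpec(tf_ids=["tB"], ssp_ids=[f"b{i}" for i in range(3)],
                           noise_sd=1 / 3),
                ModuleSpec(tf_ids=["tC"], ssp_ids=["c0"], noise_sd=1 / 3),
            ],
            n_samples=48,
            seed=11,
        )
        m, truth = simulate_expression(spec)
        ssp_ids = [g for g in m.index if not g.startswith("t")]
        net = build_network(m, ["tA", "tB", "tC"], ssp_ids)
        table = degree_table(net)
        assert list(table["tf_id"]) == ["tA", "tB", "tC"]
        assert list(table["degree"]) == [5, 3, 1]

    def test_shared_targets_is_intersection(self):
        net = toy_network()
        assert shared_targets(net, ["t1", "t2"]) == {"s1"}
        assert shared_targets(net, ["t1"]) == {"s1", "s2"}
        assert shared_targets(net, []) == set()

    def test_unknown_tf_errors(self):
        with pytest.raises(KeyError):
            shared_targets(toy_network(), ["nope"])


class TestExport:
    def test_edge_tsv_round_trip(self, tmp_path):
        net = toy_network()
        p = tmp_path / "edges.tsv"
        export_network(net, "edge-tsv", p)
        table = read_edge_tsv(p)
        assert len(table) == len(net.edges)
        got = {(r.tf_id, r.ssp_id, r.r, r.sign) for r in table.itertuples()}
        want = {(e.tf_id, e.ssp_id, e.r, e.sign) for e in net.edges}
        assert got == want

    def test_sif_lines(self, tmp_path):
        net = toy_network()
        p = tmp_path / "edges.sif"
        export_network(net, "sif", p)
        lines = p.read_text().splitlines()
        assert len(lines) == len(net.edges)
        assert all(l.split("\t")[1] in {"coexpr_pos", "coexpr_neg"}
                   for l in lines)

    def test_graphml_is_wellformed_and_attribute_preserving(self, tmp_path):
        net = toy_network()
        p = tmp_path / "edges.graphml"
        export_network(net, "graphml", p)
        etree.parse(str(p))  # well-formed XML
        g = nx.read_graphml(p)
        assert g.number_of_edges() == len(net.edges)
        e = net.edges[0]
        assert g.edges[e.tf_id, e.ssp_id]["r"] == pytest.approx(e.r)
        assert g.nodes[e.tf_id]["role"] == "TF"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(toy_network(), "xlsx", tmp_path / "x")
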