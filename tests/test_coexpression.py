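"""Phi correlation, soft-threshold adjacency and co-expression profiles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from tcemm.coexpression import (
    CoexpressionProfiler,
    CorrelationNetwork,
    build_profiles,
    export_graph,
    soft_adjacency,
    tcemm_correlation,
)
from tcemm.engine import TcEMMMatrix


def matrix_from_df(df):
    return TcEMMMatrix(
        pair_ids=[f"p{i}" for i in range(len(df))],
        tcemm_ids=list(df.columns),
        entries=sparse.csr_matrix(df.to_numpy(np.int8)),
        scores=df.to_numpy().sum(axis=1),
    )


class TestCorrelation:
    def test_duplicate_and_complement_columns(self, rng):
        a = rng.binomial(1, 0.4, 200)
        df = pd.DataFrame({"a": a, "dup": a, "comp": 1 - a})
        net = tcemm_correlation(matrix_from_df(df))
        i = {c: j for j, c in enumerate(net.tcemm_ids)}
        assert net.correlation[i["a"], i["dup"]] == pytest.approx(1.0)
        assert net.correlation[i["a"], i["comp"]] == pytest.approx(-1.0)
        assert np.allclose(np.diag(net.correlation), 1.0)

    def test_matches_contingency_phi(self, rng):
        for _ in range(20):
            x = rng.binomial(1, rng.uniform(0.2, 0.8), 300)
            y = rng.binomial(1, rng.uniform(0.2, 0.8), 300)
            if x.std() == 0 or y.std() == 0:
                continue
            df = pd.DataFrame({"x": x, "y": y})
            net = tcemm_correlation(matrix_from_df(df))
            a = np.sum((x == 1) & (y == 1))
            b = np.sum((x == 1) & (y == 0))
            c = np.sum((x == 0) & (y == 1))
            d = np.sum((x == 0) & (y == 0))
            phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
            assert net.correlation[0, 1] == pytest.approx(phi, abs=1e-12)

    def test_constant_columns_dropped_and_too_few_rejected(self, rng):
        df = pd.DataFrame({"x": rng.binomial(1, 0.5, 50), "const": np.ones(50, int)})
        with pytest.raises(ValueError, match="fewer than 2"):
            tcemm_correlation(matrix_from_df(df))


class TestAdjacency:
    def test_threshold_pair_consistency(self):
        # |r| = 0.74 at beta = 4 lands essentially on adjacency 0.30
        net = CorrelationNetwork(["a", "b"], np.array([[1.0, 0.74], [0.74, 1.0]]))
        soft_adjacency(net, beta=4.0)
        assert net.adjacency[0, 1] == pytest.approx(0.2998, abs=1e-4)
        assert 0.3 ** 0.25 == pytest.approx(0.7401, abs=1e-4)

    def test_extremes(self):
        net = CorrelationNetwork(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        soft_adjacency(net, beta=4.0)
        assert net.adjacency[0, 1] == 0.0
        net2 = CorrelationNetwork(["a", "b"], np.array([[1.0, -1.0], [-1.0, 1.0]]))
        soft_adjacency(net2, beta=4.0)
        assert net2.adjacency[0, 1] == 1.0  # unsigned

    def test_edge_criterion_equivalence(self, rng):
        n = 15
        r = rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = CorrelationNetwork([f"t{i}" for i in range(n)], r)
        soft_adjacency(net, beta=4.0)
        edges = {(u, v) for u, v, _, _ in net.edges(0.3)}
        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                if abs(r[i, j]) >= 0.3 ** 0.25:
                    expected.add((f"t{i}", f"t{j}"))
        assert edges == expected


class TestProfiles:
    def _net_from_edges(self, nodes, strong_pairs):
        n = len(nodes)
        r = np.eye(n)
        idx = {v: k for k, v in enumerate(nodes)}
        for u, v in strong_pairs:
            r[idx[u], idx[v]] = r[idx[v], idx[u]] = 0.9
        net = CorrelationNetwork(nodes, r)
        return soft_adjacency(net, beta=4.0)

    def test_chain_component(self):
        net = self._net_from_edges(list("ABCDE"), [("A", "B"), ("B", "C")])
        profiles, singles = build_profiles(net, 0.3)
        assert len(profiles) == 1 and profiles[0].members == {"A", "B", "C"}
        assert singles == ["D", "E"]

    def test_planted_blocks_recovered(self, rng):
        n = 2000
        blocks = {}
        for b in range(3):
            base = rng.binomial(1, 0.4, n)
            for j in range(4):
                blocks[f"B{b}_{j}"] = base
        for j in range(6):
            blocks[f"N{j}"] = rng.binomial(1, 0.4, n)
        df = pd.DataFrame(blocks)
        prof = CoexpressionProfiler(beta=4.0, adjacency_threshold=0.3).fit(df)
        assert len(prof.profiles_) == 3
        members = sorted(tuple(sorted(p.members)) for p in prof.profiles_)
        assert members == [
            tuple(sorted(f"B{b}_{j}" for j in range(4))) for b in range(3)
        ]
        assert set(prof.singletons_) == {f"N{j}" for j in range(6)}

    def test_partition_invariant_and_threshold_monotonicity(self, rng):
        n = 400
        df = pd.DataFrame(
            {f"t{j}": rng.binomial(1, rng.uniform(0.2, 0.6), n) for j in range(12)}
        )
        net = soft_adjacency(tcemm_correlation(matrix_from_df(df)), beta=4.0)
        prev_components = None
        for thr in (0.05, 0.3, 0.7, 1.0):
            profiles, singles = build_profiles(net, thr)
            all_nodes = sorted(
                [m for p in profiles for m in p.members] + list(singles)
            )
            assert all_nodes == sorted(net.tcemm_ids)
            comp = sorted(
                [tuple(sorted(p.members)) for p in profiles] + [(s,) for s in singles]
            )
            if prev_components is not None:
                # raising the threshold only refines (never merges) components
                prev_map = {m: k for k, c in enumerate(prev_components) for m in c}
                for c in comp:
                    assert len({prev_map[m] for m in c}) == 1
            prev_components = comp

    def test_perfect_threshold_all_singletons(self, rng):
        df = pd.DataFrame(
            {f"t{j}": rng.binomial(1, 0.5, 300) for j in range(6)}
        )
        net = soft_adjacency(tcemm_correlation(matrix_from_df(df)), beta=4.0)
        profiles, singles = build_profiles(net, 1.0)
        assert profiles == [] and len(singles) == 6


class TestExport:
    def test_round_trip_and_annotations(self, tmp_path, rng):
        a = rng.binomial(1, 0.5, 200)
        df = pd.DataFrame({"a": a, "b": a, "c": rng.binomial(1, 0.5, 200)})
        net = soft_adjacency(tcemm_correlation(matrix_from_df(df)), beta=4.0)
        profiles, _ = build_profiles(net, 0.3)
        path = tmp_path / "g.graphml"
        g = export_graph(
            net, profiles,
            {"lasso_selected": {"a": True}},
            adjacency_threshold=0.3, path=path,
        )
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()
        assert g.nodes["a"]["lasso_selected"] is True
        assert g.nodes["c"]["lasso_selected"] is False

    def test_unknown_annotation_key_rejected(self, rng):
        df = pd.DataFrame({"a": rng.binomial(1, 0.5, 50), "b": rng.binomial(1, 0.5, 50)})
        net = soft_adjacency(tcemm_correlation(matrix_from_df(df)), beta=4.0)
        with pytest.raises(KeyError, match="unknown annotation"):
            export_graph(net, [], {"bogus": {}})

    def test_empty_edge_set_node_only_graph(self):
        net = CorrelationNetwork(["a", "b"], np.array([[1.0, 0.1], [0.1, 1.0]]))
        soft_adjacency(net, beta=4.0)
        g = export_graph(net, [], {}, adjacency_threshold=0.3)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0
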