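"""Thresholded networks: construction oracle, annotation, concordance, export."""

import numpy as np
import pandas as pd
import pytest

from enznet.networks import (
    SimilarityMatrix,
    annotate_network,
    build_network,
    cluster_purity,
    concordance,
    connected_components,
    edge_homophily,
    export_network,
    import_edge_tsv,
    import_sif,
    import_xgmml,
    load_score_table,
)

from .oracles import brute_force_edges


def _random_matrix(n, seed):
    rng = np.random.default_rng(seed)
    ids = [f"e{i:03d}" for i in range(n)]
    m = SimilarityMatrix(entity_ids=list(ids), metric_name="random")
    for i in range(n):
        for j in range(i + 1, n):
            m.set(ids[i], ids[j], float(rng.random()))
    return m


class TestScoreTable:
    def test_load_three_rows(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("id1\tid2\tscore\na\tb\t0.9\na\tc\t0.5\nb\tc\t0.2\n")
        m = load_score_table(path)
        assert sorted(m.entity_ids) == ["a", "b", "c"]
        assert m.get("c", "a") == 0.5  # symmetric access

    def test_conflicting_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("id1\tid2\tscore\na\tb\t0.9\nb\ta\t0.8\n")
        with pytest.raises(ValueError, match="conflicting"):
            load_score_table(path)

    def test_non_numeric_score_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("id1\tid2\tscore\na\tb\thigh\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_score_table(path)

    def test_save_load_round_trip(self, tmp_path):
        m = _random_matrix(10, 3)
        m.to_tsv(tmp_path / "m.tsv")
        back = load_score_table(tmp_path / "m.tsv", metric_name="random")
        for (a1, b1, s1), (a2, b2, s2) in zip(back.pairs(), m.pairs()):
            assert (a1, b1) == (a2, b2)
            assert s1 == pytest.approx(s2, abs=1e-12)


class TestBuildNetwork:
    def test_direct_edge_count(self):
        m = SimilarityMatrix(entity_ids=["a", "b", "c"])
        m.set("a", "b", 0.9)
        m.set("a", "c", 0.5)
        m.set("b", "c", 0.2)
        net = build_network(m, threshold=0.5)
        assert net.graph.number_of_edges() == 2  # inclusive threshold
        assert set(net.graph.nodes) == {"a", "b", "c"}

    def test_threshold_above_max_keeps_isolated_nodes(self):
        m = _random_matrix(20, 5)
        net = build_network(m, threshold=1.01)
        assert net.graph.number_of_edges() == 0
        assert net.graph.number_of_nodes() == 20

    def test_edge_set_matches_brute_force_oracle(self):
        m = _random_matrix(60, 7)
        for threshold in np.linspace(0.05, 0.95, 7):
            net = build_network(m, threshold=threshold)
            got = {tuple(sorted(e)) for e in net.graph.edges}
            assert got == brute_force_edges(m.pairs(), threshold)

    def test_monotonicity_in_threshold(self):
        m = _random_matrix(50, 9)
        prev_edges, prev_comps = None, None
        for threshold in np.linspace(0.0, 1.0, 11):
            net = build_network(m, threshold=threshold)
            n_edges = net.graph.number_of_edges()
            n_comps = len(connected_components(net))
            if prev_edges is not None:
                assert n_edges <= prev_edges
                assert n_comps >= prev_comps
            prev_edges, prev_comps = n_edges, n_comps


class TestComponents:
    def test_no_edges_all_singletons(self):
        net = build_network(_random_matrix(5, 1), threshold=2.0)
        assert len(connected_components(net)) == 5

    def test_triad_single_component(self):
        m = SimilarityMatrix(entity_ids=["a", "b", "c"])
        for x, y in (("a", "b"), ("b", "c"), ("a", "c")):
            m.set(x, y, 1.0)
        assert connected_components(build_network(m, 0.5)) == [["a", "b", "c"]]

    def test_planted_clusters_with_subthreshold_bridge(self):
        m = SimilarityMatrix(entity_ids=[])
        for grp in ("x", "y"):
            for i in range(3):
                for j in range(i + 1, 3):
                    m.set(f"{grp}{i}", f"{grp}{j}", 0.9)
        m.set("x0", "y0", 0.4)  # bridge below threshold
        comps = connected_components(build_network(m, threshold=0.5))
        assert len(comps) == 2


class TestAnnotate:
    def test_all_labeled_no_flags(self):
        net = build_network(_random_matrix(3, 2), threshold=0.0)
        labels = pd.DataFrame(
            [{"entity_id": n, "subgroup": "SG"} for n in net.graph.nodes]
        )
        messages = annotate_network(net, labels)
        assert messages == []
        assert all(not d["unlabeled"] for _, d in net.graph.nodes(data=True))

    def test_shared_reaction_node_carries_both_subgroups(self):
        net = build_network(_random_matrix(3, 2), threshold=0.0)
        labels = pd.DataFrame(
            [
                {"entity_id": "e000", "subgroup": "MR"},
                {"entity_id": "e000", "subgroup": "GalD"},
                {"entity_id": "e001", "subgroup": "MR"},
                {"entity_id": "e002", "subgroup": "MLE"},
            ]
        )
        annotate_network(net, labels)
        assert sorted(net.graph.nodes["e000"]["subgroup"]) == ["GalD", "MR"]

    def test_unknown_ids_reported(self):
        net = build_network(_random_matrix(2, 2), threshold=0.0)
        labels = pd.DataFrame([{"entity_id": "ghost", "subgroup": "SG"}])
        with pytest.warns(UserWarning, match="ghost"):
            messages = annotate_network(net, labels)
        assert any("ghost" in m for m in messages)


class TestConcordance:
    def test_identical_partitions_perfect_scores(self):
        labels = {f"e{i}": i % 4 for i in range(40)}
        rep = concordance(labels, dict(labels))
        assert rep.adjusted_rand_index == pytest.approx(1.0)
        assert rep.purity_1_vs_2 == 1.0 and rep.purity_2_vs_1 == 1.0

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="no entities"):
            concordance({"a": 1}, {"b": 1})

    def test_homophily_undefined_for_edgeless_label(self):
        m = SimilarityMatrix(entity_ids=["a", "b", "c"])
        m.set("a", "b", 0.9)
        net = build_network(m, threshold=0.5)
        hom = edge_homophily(net, {"a": "x", "b": "x", "c": "lonely"})
        assert hom["x"] == 1.0
        assert hom["lonely"] is None  # no within-set pairs to measure

    def test_permuted_labels_center_ari_at_zero(self):
        rng = np.random.default_rng(42)
        n = 200
        base = {f"e{i}": i % 8 for i in range(n)}
        aris = []
        for _ in range(20):
            permuted_values = rng.permutation(list(base.values()))
            permuted = dict(zip(base.keys(), permuted_values))
            aris.append(concordance(base, permuted).adjusted_rand_index)
        assert abs(float(np.mean(aris))) <= 0.05

    def test_purity_multilabel_any_match_and_fractional(self):
        clusters = {"a": 0, "b": 0}
        labels = {"a": ["x", "y"], "b": "x"}
        assert cluster_purity(clusters, labels) == 1.0
        assert cluster_purity(clusters, labels, fractional_multilabel=True) == 0.75


class TestExport:
    @pytest.fixture()
    def net(self):
        m = SimilarityMatrix(entity_ids=["a", "b", "c", "d"])
        m.set("a", "b", 0.9)
        m.set("b", "c", 0.8)
        net = build_network(m, threshold=0.5, node_shape="square")
        annotate_network(
            net,
            pd.DataFrame(
                [
                    {"entity_id": "a", "subgroup": "MR"},
                    {"entity_id": "b", "subgroup": "MR"},
                    {"entity_id": "c", "subgroup": "MLE"},
                    {"entity_id": "d", "subgroup": "MLE"},
                ]
            ),
        )
        return net

    def test_edge_tsv_row_count_and_round_trip(self, net, tmp_path):
        path = export_network(net, "edge_tsv", tmp_path / "edges.tsv")
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 2
        back = import_edge_tsv(path)
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, net.graph.edges)
        )

    def test_sif_line_grammar_and_round_trip(self, net, tmp_path):
        path = export_network(net, "sif", tmp_path / "net.sif")
        lines = path.read_text().splitlines()
        # source <relation> target... grouping, isolated nodes as bare ids
        assert "a\tsim\tb" in lines and "b\tsim\tc" in lines and "d" in lines
        back = import_sif(path)
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, net.graph.edges)
        )
        assert "d" in back.graph

    def test_xgmml_round_trip_preserves_attributes(self, net, tmp_path):
        path = export_network(net, "xgmml_minimal", tmp_path / "net.xgmml")
        back = import_xgmml(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, net.graph.edges)
        )
        assert back.graph.nodes["a"]["subgroup"] == "MR"

    def test_node_tsv_carries_labels(self, net, tmp_path):
        path = export_network(net, "node_tsv", tmp_path / "nodes.tsv")
        df = pd.read_csv(path, sep="\t").set_index("node")
        assert df.loc["a", "subgroup"] == "MR"
        assert df.loc["d", "shape"] == "square"

    def test_unknown_format_rejected(self, net, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            export_network(net, "graphml", tmp_path / "x")
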