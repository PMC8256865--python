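"""GRN construction: scope, direct layer, catalog expansion, annotation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fusiongrn.builder import (
    DEGTable,
    EssentialityCalls,
    GRN,
    TFCatalog,
    annotate_nodes,
    build_direct_layer,
    build_grn,
    classify_essentiality,
    expand_and_prune,
    infer_edge_sign,
    regulatory_scope,
)


def deg_table(rows):
    return DEGTable(pd.DataFrame(rows, columns=["gene_id", "logFC", "FDR"]))


def catalog(pairs):
    return TFCatalog(pd.DataFrame(pairs, columns=["source", "target"]))


class TestRegulatoryScope:
    def test_threshold_is_strict(self):
        degs = deg_table([("g1", -1.0, 0.049), ("g2", 0.5, 0.05)])
        assert regulatory_scope(degs) == {"g1"}

    def test_empty_table(self):
        assert regulatory_scope(deg_table([])) == set()

    def test_all_below_threshold(self):
        degs = deg_table([("g1", 1.0, 0.001), ("g2", -2.0, 0.01)])
        assert regulatory_scope(degs) == {"g1", "g2"}

    def test_fdr_out_of_range_rejected_on_load(self):
        with pytest.raises(ValueError):
            deg_table([("g1", 1.0, 1.5)])

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError):
            deg_table([("g1", 1.0, 0.1), ("g1", 2.0, 0.2)])


class TestDirectLayer:
    def test_bound_intersected_with_scope(self):
        grn = build_direct_layer("root", {"g1", "g2", "g3"}, {"g2", "g3", "g4"})
        assert set(grn.graph.edges) == {("root", "g2"), ("root", "g3")}
        assert all(d["provenance"] == "direct" for _, _, d in grn.graph.edges(data=True))

    def test_disjoint_bound_and_scope_gives_root_only(self):
        grn = build_direct_layer("root", {"g1"}, {"g2"})
        assert set(grn.graph.nodes) == {"root"}

    def test_no_self_loop_for_root_gene(self):
        grn = build_direct_layer("root", {"root", "g1"}, {"root", "g1"})
        assert ("root", "root") not in grn.graph.edges


class TestExpandAndPrune:
    def test_unreachable_catalog_edge_dropped(self):
        direct = build_direct_layer("root", {"g2", "g3"}, {"g2", "g3", "g4", "g6"})
        cat = catalog([("g2", "g4"), ("g5", "g6")])
        grn = expand_and_prune(direct, cat, {"g2", "g3", "g4", "g6"})
        assert set(grn.graph.nodes) == {"root", "g2", "g3", "g4"}
        assert set(grn.graph.edges) == {
            ("root", "g2"), ("root", "g3"), ("g2", "g4"),
        }
        # BFS oracle: retained nodes = reachability over candidate edges
        cand = nx.DiGraph(list(direct.graph.edges) + [("g2", "g4")])
        assert set(grn.graph.nodes) == nx.descendants(cand, "root") | {"root"}

    def test_empty_catalog_leaves_direct_graph(self):
        direct = build_direct_layer("root", {"g1"}, {"g1"})
        grn = expand_and_prune(direct, catalog([]), {"g1"})
        assert set(grn.graph.edges) == {("root", "g1")}

    def test_cycle_within_reachable_region_retained(self):
        direct = build_direct_layer("root", {"g2"}, {"g2", "g4"})
        cat = catalog([("g2", "g4"), ("g4", "g2")])
        grn = expand_and_prune(direct, cat, {"g2", "g4"})
        assert ("g2", "g4") in grn.graph.edges and ("g4", "g2") in grn.graph.edges

    def test_direct_provenance_wins_over_catalog(self):
        direct = build_direct_layer("root", {"g1"}, {"g1", "g2"})
        grn = expand_and_prune(
            direct, catalog([("g1", "g2")]), {"g1", "g2"}
        )
        assert grn.graph.edges["g1", "g2"]["provenance"] == "catalog"
        # a catalog edge duplicating a direct edge keeps direct provenance
        direct2 = build_direct_layer("root", {"g1"}, {"g1"})
        grn2 = expand_and_prune(direct2, catalog([("root", "g1")]), {"g1", "root"})
        assert grn2.graph.edges["root", "g1"]["provenance"] == "direct"

    def test_reachability_invariant_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            genes = [f"g{i}" for i in range(12)]
            scope = set(rng.choice(genes, size=8, replace=False))
            bound = set(rng.choice(genes, size=4, replace=False))
            pairs = [
                (genes[int(rng.integers(12))], genes[int(rng.integers(12))])
                for _ in range(15)
            ]
            pairs = [(u, v) for u, v in pairs if u != v]
            grn = expand_and_prune(
                build_direct_layer("root", bound, scope), catalog(pairs), scope
            )
            assert grn.is_reachable_from_root()
            assert set(grn.graph.nodes) - {"root"} <= scope

    def test_scope_monotonicity(self):
        """Enlarging the DEG scope can only add nodes and edges."""
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(15)]
        bound = set(genes[:5])
        pairs = [
            (genes[int(rng.integers(15))], genes[int(rng.integers(15))])
            for _ in range(25)
        ]
        pairs = [(u, v) for u, v in pairs if u != v]
        for _ in range(10):
            small = set(rng.choice(genes, size=6, replace=False))
            big = small | set(rng.choice(genes, size=5, replace=False))
            g_small = expand_and_prune(
                build_direct_layer("root", bound, small), catalog(pairs), small
            )
            g_big = expand_and_prune(
                build_direct_layer("root", bound, big), catalog(pairs), big
            )
            assert set(g_small.graph.nodes) <= set(g_big.graph.nodes)
            assert set(g_small.graph.edges) <= set(g_big.graph.edges)


class TestEdgeSigns:
    def test_negative_kd_response_means_activation(self):
        assert infer_edge_sign(-1.2) == "+"

    def test_positive_kd_response_means_repression(self):
        assert infer_edge_sign(0.8) == "-"

    def test_zero_logfc_is_malformed(self):
        with pytest.raises(ValueError):
            infer_edge_sign(0.0)


class TestEssentiality:
    @pytest.fixture()
    def calls(self):
        flags = pd.DataFrame(
            {
                "HT-29": [True, False, False, True],
                "HT-1080": [False, False, False, False],
                "MOLM-13": [False, True, False, True],
                "MV4-11": [False, False, False, False],
            },
            index=["gA", "gB", "gC", "gD"],
        )
        return EssentialityCalls(flags, ("MOLM-13", "MV4-11"), ("HT-29", "HT-1080"))

    def test_nonleukemia_line_means_nonspecific(self, calls):
        assert classify_essentiality(calls, "gA") == "nonspecific_essential"

    def test_leukemia_only_means_specific(self, calls):
        assert classify_essentiality(calls, "gB") == "leukemia_specific"

    def test_essential_nowhere(self, calls):
        assert classify_essentiality(calls, "gC") == "nonessential"

    def test_nonspecific_takes_precedence(self, calls):
        assert classify_essentiality(calls, "gD") == "nonspecific_essential"

    def test_absent_gene_warns_nonessential(self, calls):
        with pytest.warns(UserWarning):
            assert classify_essentiality(calls, "missing") == "nonessential"

    def test_empty_partition_rejected(self):
        flags = pd.DataFrame({"HT-29": [True]}, index=["g"])
        with pytest.raises(ValueError):
            EssentialityCalls(flags, (), ("HT-29",))


class TestAnnotateNodes:
    def test_all_nodes_annotated_count_unchanged(self):
        degs = deg_table([("g1", -1.0, 0.01), ("g2", 0.7, 0.02)])
        grn = build_grn("root", degs, {"g1", "g2"}, catalog([]))
        assert len(grn) == 3
        assert grn.nodes["g1"]["logfc"] == pytest.approx(-1.0)
        assert grn.graph.edges["root", "g1"]["sign"] == "+"
        assert grn.graph.edges["root", "g2"]["sign"] == "-"

    def test_node_missing_from_degs_is_an_error(self):
        degs = deg_table([("g1", -1.0, 0.01)])
        grn = build_direct_layer("root", {"g1"}, {"g1"})
        grn.graph.add_edge("g1", "ghost")
        with pytest.raises(ValueError, match="scope invariant"):
            annotate_nodes(grn, degs)


class TestCatalogAndIO:
    def test_self_edges_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="self-edge"):
            cat = TFCatalog(
                pd.DataFrame([("a", "a"), ("a", "b")], columns=["source", "target"])
            )
        assert cat.pairs() == [("a", "b")]

    def test_duplicate_pairs_collapsed(self):
        cat = catalog([("a", "b"), ("a", "b"), ("b", "c")])
        assert len(cat) == 2

    def test_edge_tsv_round_trip(self, tmp_path):
        degs = deg_table([("g1", -1.0, 0.01), ("g2", 0.7, 0.02)])
        grn = build_grn("root", degs, {"g1"}, catalog([("g1", "g2")]))
        path = tmp_path / "grn.tsv"
        grn.write_edge_tsv(path)
        back = GRN.read_edge_tsv(path)
        assert back.root == "root"
        assert set(back.graph.edges) == set(grn.graph.edges)
        for e in grn.graph.edges:
            assert back.graph.edges[e]["sign"] == grn.graph.edges[e]["sign"]

    def test_graphml_export(self, tmp_path):
        degs = deg_table([("g1", -1.0, 0.01)])
        grn = build_grn("root", degs, {"g1"}, catalog([]))
        grn.write_graphml(tmp_path / "grn.graphml")
        back = nx.read_graphml(tmp_path / "grn.graphml")
        assert set(back.nodes) == {"root", "g1"}
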