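"""Expression thresholding, per-sample subnetworks, activity clustering."""

import numpy as np
import pandas as pd
import pytest

import fusiongrn as fg
from fusiongrn.builder import DEGTable, TFCatalog, regulatory_scope
from fusiongrn.subnetworks import (
    ExpressionMatrix,
    GRNBuildInputs,
    activity_and_conservation,
    cluster_activity,
    derive_subnetworks,
    expressed_gene_sets,
)


def expr_matrix(log2_values, samples, datasets, genes=None):
    """Build an ExpressionMatrix from log2(TPM+1)-scale values."""
    values = np.asarray(log2_values, dtype=float)
    tpm = pd.DataFrame(
        2.0 ** values - 1.0,
        index=genes or [f"g{i}" for i in range(values.shape[0])],
        columns=samples,
    )
    return ExpressionMatrix(tpm, pd.Series(datasets, index=samples))


@pytest.fixture()
def build_inputs():
    degs = DEGTable(
        pd.DataFrame(
            [("g1", -1.0, 0.01), ("g2", -2.0, 0.02), ("g3", 1.0, 0.03)],
            columns=["gene_id", "logFC", "FDR"],
        )
    )
    catalog = TFCatalog(
        pd.DataFrame([("g1", "g2"), ("g2", "g3")], columns=["source", "target"])
    )
    return GRNBuildInputs("root", degs, {"g1"}, catalog)


class TestExpressedGeneSets:
    def test_grand_mean_threshold_is_strict(self):
        expr = expr_matrix([[1.0], [3.0]], ["s1"], ["D"])
        expressed = expressed_gene_sets(expr)
        assert expressed["s1"] == {"g1"}  # threshold 2, only the 3 passes

    def test_all_equal_entries_express_nothing(self):
        expr = expr_matrix([[2.0, 2.0], [2.0, 2.0]], ["s1", "s2"], ["D", "D"])
        expressed = expressed_gene_sets(expr)
        assert expressed["s1"] == set() and expressed["s2"] == set()

    def test_datasets_thresholded_independently(self):
        # dataset E sits on a higher scale; shared values fall on opposite
        # sides of the two thresholds
        expr = expr_matrix(
            [[1.0, 5.0], [3.0, 9.0]], ["s1", "s2"], ["D", "E"]
        )
        expressed = expressed_gene_sets(expr)
        assert expressed["s1"] == {"g1"}  # D threshold 2
        assert expressed["s2"] == {"g1"}  # E threshold 7

    def test_per_sample_mode_uses_column_means(self):
        expr = expr_matrix(
            [[1.0, 5.0], [3.0, 3.0]], ["s1", "s2"], ["D", "D"]
        )
        expressed = expressed_gene_sets(expr, per_sample=True)
        assert expressed["s1"] == {"g1"}  # s1 mean 2
        assert expressed["s2"] == {"g0"}  # s2 mean 4

    def test_negative_tpm_rejected(self):
        tpm = pd.DataFrame({"s1": [-1.0]}, index=["g"])
        with pytest.raises(ValueError):
            ExpressionMatrix(tpm, pd.Series({"s1": "D"}))


class TestDeriveSubnetworks:
    def test_expressed_superset_reproduces_full_grn(self, build_inputs):
        full = fg.build_grn(
            build_inputs.root, build_inputs.degs, build_inputs.bound,
            build_inputs.catalog,
        )
        subnets = derive_subnetworks(
            build_inputs, {"s1": {"g1", "g2", "g3", "extra"}}
        )
        assert set(subnets["s1"].graph.edges) == set(full.graph.edges)

    def test_nothing_expressed_gives_root_only(self, build_inputs):
        subnets = derive_subnetworks(build_inputs, {"s1": set()})
        assert set(subnets["s1"].graph.nodes) == {"root"}

    def test_losing_a_bridge_drops_downstream_nodes(self, build_inputs):
        # g1 is the only route from root; without it nothing is reachable
        subnets = derive_subnetworks(build_inputs, {"s1": {"g2", "g3"}})
        assert set(subnets["s1"].graph.nodes) == {"root"}
        # with g1 but not g2, the chain stops at g1
        subnets = derive_subnetworks(build_inputs, {"s2": {"g1", "g3"}})
        assert set(subnets["s2"].graph.nodes) == {"root", "g1"}

    def test_monotone_in_expressed_set(self, build_inputs):
        rng = np.random.default_rng(6)
        genes = ["g1", "g2", "g3"]
        for _ in range(10):
            small = {g for g in genes if rng.random() < 0.5}
            big = small | {g for g in genes if rng.random() < 0.5}
            subnets = derive_subnetworks(build_inputs, {"a": small, "b": big})
            assert set(subnets["a"].graph.nodes) <= set(subnets["b"].graph.nodes)

    def test_subnetworks_keep_reachability_invariant(self, clean_small_data):
        data = clean_small_data
        inputs = GRNBuildInputs(
            data.truth.root, data.kd_a,
            fg.pipeline.root_bound_genes(data), data.catalog,
        )
        expressed = expressed_gene_sets(data.expression)
        some_samples = dict(list(expressed.items())[:4])
        for sub in derive_subnetworks(inputs, some_samples).values():
            assert sub.is_reachable_from_root()
            assert set(sub.graph.nodes) - {data.truth.root} <= regulatory_scope(
                data.kd_a
            )


class TestActivityAndConservation:
    @pytest.fixture()
    def toy_subnets(self, build_inputs):
        full = fg.build_grn(
            build_inputs.root, build_inputs.degs, build_inputs.bound,
            build_inputs.catalog,
        )
        expressed = {
            "s1": {"g1", "g2", "g3"},
            "s2": {"g1", "g2", "g3"},
            "s3": {"g1"},
            "s4": set(),
        }
        return full, derive_subnetworks(build_inputs, expressed)

    def test_counting(self, toy_subnets):
        full, subnets = toy_subnets
        groups = pd.Series({"s1": "D", "s2": "D", "s3": "D", "s4": "D"})
        activity, conservation = activity_and_conservation(subnets, full, groups)
        assert activity.loc["g1"].tolist() == [1, 1, 1, 0]
        assert conservation.loc["g1", "D"] == pytest.approx(75.0)
        assert conservation.loc["root", "D"] == pytest.approx(100.0)
        assert conservation.loc["g3", "D"] == pytest.approx(50.0)

    def test_conservation_matches_direct_recomputation(self, toy_subnets):
        full, subnets = toy_subnets
        groups = pd.Series({"s1": "D", "s2": "D", "s3": "E", "s4": "E"})
        activity, conservation = activity_and_conservation(subnets, full, groups)
        for gene in activity.index:
            for ds in ("D", "E"):
                cols = [s for s in activity.columns if groups[s] == ds]
                direct = 100.0 * np.mean(
                    [gene in subnets[s].graph for s in cols]
                )
                assert conservation.loc[gene, ds] == pytest.approx(direct)
        assert ((conservation.values >= 0) & (conservation.values <= 100)).all()


class TestClustering:
    def test_two_separated_blocks_recovered(self):
        rows = [[1, 1, 1, 0, 0]] * 6 + [[0, 0, 0, 1, 1]] * 5
        activity = pd.DataFrame(
            rows, index=[f"g{i}" for i in range(11)],
            columns=[f"s{i}" for i in range(5)], dtype=np.int8,
        )
        labels = cluster_activity(activity, k=2, seed=0).labels
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_rows_single_cluster(self):
        activity = pd.DataFrame(
            [[1, 0, 1]] * 4, index=list("abcd"), columns=list("xyz")
        )
        labels = cluster_activity(activity, k=1, seed=0).labels
        assert labels.nunique() == 1

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(8)
        activity = pd.DataFrame(
            rng.integers(0, 2, size=(30, 8)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(8)],
        )
        first = cluster_activity(activity, k=4, seed=3).labels
        second = cluster_activity(activity, k=4, seed=3).labels
        pd.testing.assert_series_equal(first, second)

    def test_k_exceeding_active_nodes_is_an_error(self):
        activity = pd.DataFrame(
            [[1, 0], [0, 1], [0, 0]], index=list("abc"), columns=list("xy")
        )
        with pytest.raises(ValueError):
            cluster_activity(activity, k=3, seed=0)
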