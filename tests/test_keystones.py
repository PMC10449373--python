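import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_signed_graph
from oracles import walk_enumeration_wi
from sodanet import (
    OtuTable,
    build_network,
    call_keystones,
    keystone_report,
    keystone_sign,
    network_properties,
    preferred_season,
    topological_importance,
)


def _edges(rows):
    df = pd.DataFrame(
        rows,
        columns=["otu_a", "otu_b", "ls_score", "sign", "delay", "sscc", "edge_type"],
    )
    df["significant"] = True
    df["network"] = np.where(df["delay"] == 0, "synchronous", "time_shifted")
    return df


class TestBuildNetwork:
    def test_delay_routes_edges(self):
        df = _edges(
            [
                ("a", "b", 0.5, 1, 0, 0.9, "SSCC"),
                ("b", "c", 0.4, -1, -1, -0.8, "LS"),
            ]
        )
        sync = build_network(df, "synchronous")
        shifted = build_network(df, "time_shifted")
        assert set(sync.edges) == {("a", "b")}
        assert set(shifted.edges) == {("b", "c")}
        # a node may live in both networks
        assert "b" in sync and "b" in shifted

    def test_weights_follow_edge_type(self):
        df = _edges(
            [
                ("a", "b", 0.5, 1, 0, 0.9, "SSCC"),
                ("c", "d", 0.4, -1, 0, -0.2, "LS"),
            ]
        )
        g = build_network(df, "synchronous")
        assert g["a"]["b"]["weight"] == pytest.approx(0.9)  # SSCC value
        assert g["c"]["d"]["weight"] == pytest.approx(-0.4)  # signed LS

    def test_empty_edge_set_warns(self):
        df = _edges([("a", "b", 0.5, 1, 1, 0.9, "LS")])
        with pytest.warns(UserWarning, match="empty network"):
            g = build_network(df, "synchronous")
        assert g.number_of_nodes() == 0


class TestNetworkProperties:
    def test_complete_graph_density_one(self):
        g = nx.complete_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert network_properties(g)["density"] == pytest.approx(1.0)

    def test_isolated_nodes_never_enter(self):
        df = _edges([("a", "b", 0.5, 1, 0, 0.9, "LS")])
        g = build_network(df, "synchronous")
        props = network_properties(g)
        assert props["nodes"] == 2 and props["density"] == pytest.approx(1.0)

    def test_sign_tallies(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5, type="LS")
        g.add_edge("b", "c", weight=0.7, type="SSCC")
        props = network_properties(g)
        assert props["positive_edges"] == 2 and props["negative_edges"] == 0
        assert props["ls_edges"] == 1 and props["sscc_edges"] == 1


class TestTopologicalImportance:
    def test_single_edge_hand_value(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        wi = topological_importance(g)
        assert wi["A"]["wi"] == pytest.approx(2 / 3)
        assert wi["B"]["wi"] == pytest.approx(2 / 3)

    def test_star_hand_values(self):
        g = nx.Graph()
        for leaf in ("x", "y", "z"):
            g.add_edge("c", leaf, weight=2.0)
        wi = topological_importance(g)
        assert wi["c"]["wi"] == pytest.approx(2.0)
        for leaf in ("x", "y", "z"):
            assert wi[leaf]["wi"] == pytest.approx(4 / 9)

    def test_weight_scale_invariance(self):
        g = random_signed_graph(np.random.default_rng(0))
        doubled = g.copy()
        for _, _, d in doubled.edges(data=True):
            d["weight"] *= 2
        a = topological_importance(g)
        b = topological_importance(doubled)
        for node in g.nodes:
            assert a[node]["wi"] == pytest.approx(b[node]["wi"])

    def test_sigma1_conserves_nonisolated_count(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = random_signed_graph(rng)
            wi = topological_importance(g)
            non_isolated = sum(1 for n in g.nodes if g.degree(n) > 0)
            total = sum(v["sigma"][0] for v in wi.values())
            assert total == pytest.approx(non_isolated)

    def test_matches_walk_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            g = random_signed_graph(rng)
            nodes = list(g.nodes)
            w = np.abs(nx.to_numpy_array(g, nodelist=nodes, weight="weight"))
            strength = w.sum(axis=1)
            a = np.divide(
                w, strength[:, None], out=np.zeros_like(w), where=strength[:, None] > 0
            )
            _, wi_oracle = walk_enumeration_wi(a, 3)
            wi = topological_importance(g)
            for j, node in enumerate(nodes):
                assert wi[node]["wi"] == pytest.approx(wi_oracle[j], abs=1e-12)

    def test_star_center_beats_leaves(self):
        for k in range(2, 6):
            g = nx.star_graph(k)
            nx.set_edge_attributes(g, 1.0, "weight")
            wi = topological_importance(g)
            assert all(wi[0]["wi"] > wi[leaf]["wi"] for leaf in range(1, k + 1))


class TestKeystoneRule:
    def test_seven_above_threshold_no_expansion(self):
        wi = {f"n{i}": 1.2 for i in range(7)}
        assert call_keystones(wi) == set(wi)

    def test_expansion_includes_exact_ones(self):
        wi = {"a": 1.5, "b": 1.2, "c": 1.1, "d": 1.0, "e": 1.0, "f": 0.4}
        assert call_keystones(wi) == {"a", "b", "c", "d", "e"}

    def test_no_expansion_when_six_strict(self):
        wi = {f"s{i}": 1.2 for i in range(6)}
        wi["edge_case"] = 1.0
        assert call_keystones(wi) == {f"s{i}" for i in range(6)}

    def test_all_below_one_empty(self):
        assert call_keystones({"a": 0.9, "b": 0.2}) == set()

    def test_monotone_in_wi(self):
        wi = {"a": 1.5, "b": 0.8, "c": 1.0}
        before = call_keystones(wi)
        wi["b"] = 2.0
        after = call_keystones(wi)
        assert before & after >= before - {"b"}
        assert "a" in after


class TestKeystoneSign:
    def _g(self, weights):
        g = nx.Graph()
        for i, w in enumerate(weights):
            g.add_edge("hub", f"n{i}", weight=w)
        return g

    def test_all_positive(self):
        assert keystone_sign(self._g([0.5, 0.7]), "hub") == "positive"

    def test_mixed_net_negative(self):
        assert keystone_sign(self._g([0.5, -0.9]), "hub") == "negative"

    def test_exact_tie_unspecified(self):
        assert keystone_sign(self._g([0.5, -0.5]), "hub") == "unspecified"

    def test_absent_node_rejected(self):
        with pytest.raises(ValueError):
            keystone_sign(self._g([0.5]), "ghost")


class TestPreferredSeason:
    LABELS = ["spring"] * 4 + ["summer"] * 6 + ["autumn"] * 4

    def test_constant_series_none(self):
        assert preferred_season([0.1] * 14, self.LABELS, "relabund") == "none"

    def test_spring_profile_relabund(self):
        v = np.zeros(14)
        v[:4] = 0.5
        # independently recompute the rule's two sides
        excess = v[:4].mean() - v.mean()
        assert excess == pytest.approx(0.3571, abs=1e-4)
        assert v.std() == pytest.approx(0.2259, abs=1e-4)
        assert preferred_season(v, self.LABELS, "relabund") == "spring"

    def test_zscore_two_positive_seasons_unspecified(self):
        v = np.zeros(14)
        v[:4] = 0.5
        v[10:] = 0.5
        assert preferred_season(v, self.LABELS, "zscore") == "unspecified"

    def test_zscore_single_season(self):
        v = np.zeros(14)
        v[4:10] = 0.3
        assert preferred_season(v, self.LABELS, "zscore") == "summer"

    def test_missing_season_warns(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = preferred_season([0.1, 0.2, 0.3, 0.4], ["spring"] * 4, "zscore")
        assert out in ("spring", "none")


class TestKeystoneReport:
    def test_empty_networks_empty_report(self, tiny_table):
        report = keystone_report({"synchronous": nx.Graph()}, tiny_table, ["spring", "spring"], set())
        assert report.empty

    def test_core_label_and_sorting(self):
        g = nx.Graph()
        for leaf in range(6):
            g.add_edge("hub", f"n{leaf}", weight=1.0)
        counts = pd.DataFrame(
            np.ones((4, 7)),
            index=[f"S{i}" for i in range(4)],
            columns=["hub"] + [f"n{i}" for i in range(6)],
        )
        table = OtuTable(counts)
        report = keystone_report(
            {"synchronous": g}, table, ["spring", "spring", "summer", "autumn"], {"hub"}
        )
        assert (report["wi3"].diff().dropna() <= 1e-12).all()
        hub_row = report.loc[report["otu_id"] == "hub"].iloc[0]
        assert hub_row["core_label"] == "core"
        assert report.loc[report["otu_id"] != "hub", "core_label"].eq("noncore").all()
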