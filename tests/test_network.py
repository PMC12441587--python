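"""Network construction, edge-weight schemes and node strength."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from symptomnet.association import estimate_all
from symptomnet.items import ITEM_CODES
from symptomnet.network import (
    build_network,
    include_edge,
    network_edge_list,
    node_strength,
    or_ratio_weight,
    significant_or_weight,
    strength_change,
)
from symptomnet.states import add_states, filter_complete_cases


def edge_row(item_i, item_j, wave, or_value, ci_low, ci_high, n_ij,
             stratum="HH", sex="F"):
    return {
        "stratum": stratum, "sex": sex, "wave": wave,
        "item_i": item_i, "item_j": item_j,
        "n_ij": n_ij, "n_i_notj": 30, "n_noti_j": 30, "n_noti_notj": 200,
        "or": or_value, "log_or": np.log(or_value), "sigma": 0.3,
        "ci_low": ci_low, "ci_high": ci_high,
        "sig_diff": ci_low > 1 or ci_high < 1, "sig_above": ci_low > 1,
        "corrected": False,
    }


def edges_frame(rows):
    return pd.DataFrame(rows)


class TestInclusionRule:
    def test_strict_threshold(self):
        assert include_edge(21, None, "significant_or", wave=6)
        assert not include_edge(20, None, "significant_or", wave=6)
        assert not include_edge(0, None, "significant_or", wave=6)

    def test_or_ratio_needs_both_waves(self):
        assert include_edge(25, 21, "or_ratio")
        assert not include_edge(25, 19, "or_ratio")
        assert not include_edge(19, 25, "or_ratio")
        assert not include_edge(25, None, "or_ratio")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            include_edge(25, 25, "betweenness")


class TestWeights:
    def test_or_ratio_arithmetic(self):
        assert or_ratio_weight(2.0, 6.0) == pytest.approx(3.0)
        assert or_ratio_weight(4.0, 4.0) == pytest.approx(1.0)

    def test_or_ratio_reciprocal_symmetry(self):
        assert or_ratio_weight(2.0, 5.0) * or_ratio_weight(5.0, 2.0) == (
            pytest.approx(1.0)
        )

    def test_or_ratio_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            or_ratio_weight(0.0, 3.0)
        with pytest.raises(ValueError, match="undefined"):
            or_ratio_weight(np.inf, 3.0)

    def test_significant_or_gate(self):
        assert significant_or_weight(3.5, 1.2, 10.2) == pytest.approx(3.5)
        assert significant_or_weight(1.4, 0.9, 2.2) == 0.0
        # significantly BELOW unity: zero under the one-sided gate, kept
        # under the two-sided gate
        assert significant_or_weight(0.5, 0.3, 0.8, gate="above") == 0.0
        assert significant_or_weight(0.5, 0.3, 0.8, gate="diff") == (
            pytest.approx(0.5)
        )

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValueError, match="gate"):
            significant_or_weight(2.0, 1.5, 3.0, gate="bonferroni")


class TestBuildNetwork:
    def test_hand_built_three_pair_fixture(self):
        rows = [
            edge_row("dep", "pes", 6, 3.0, 1.5, 6.0, n_ij=30),   # in, weighted
            edge_row("dep", "sle", 6, 1.3, 0.8, 2.1, n_ij=40),   # in, weight 0
            edge_row("sui", "gui", 6, 5.0, 2.0, 12.0, n_ij=20),  # below threshold
        ]
        g = build_network(edges_frame(rows), "HH", "F", wave=6)
        assert set(g.nodes) == set(ITEM_CODES)
        assert set(map(frozenset, g.edges)) == {
            frozenset({"dep", "pes"}), frozenset({"dep", "sle"})
        }
        assert g["dep"]["pes"]["weight"] == pytest.approx(3.0)
        assert g["dep"]["sle"]["weight"] == 0.0

    def test_no_significant_pairs_gives_isolated_nodes(self):
        rows = [edge_row("dep", "pes", 6, 1.2, 0.9, 1.6, n_ij=5)]
        g = build_network(edges_frame(rows), "HH", "F", wave=6)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 12

    def test_edge_count_bounded_by_66(self, small_cohort):
        kept, _ = filter_complete_cases(small_cohort)
        edges = estimate_all(add_states(kept), by=())
        for scheme, wave in (("significant_or", 6), ("or_ratio", None)):
            g = build_network(edges, "all", "all", wave=wave, scheme=scheme)
            assert g.number_of_edges() <= 66

    def test_or_ratio_weights(self):
        rows = [
            edge_row("dep", "pes", 6, 2.0, 1.5, 2.7, n_ij=30),
            edge_row("dep", "pes", 8, 6.0, 4.0, 9.0, n_ij=35),
            edge_row("sle", "fat", 6, 2.0, 1.5, 2.7, n_ij=30),
            edge_row("sle", "fat", 8, 3.0, 2.0, 4.5, n_ij=19),  # w8 below
        ]
        g = build_network(edges_frame(rows), "HH", "F", scheme="or_ratio")
        assert set(map(frozenset, g.edges)) == {frozenset({"dep", "pes"})}
        assert g["dep"]["pes"]["weight"] == pytest.approx(3.0)

    def test_scheme_consistency_gate(self, small_cohort):
        # every positive-weight edge under significant_or has ci_low > 1
        kept, _ = filter_complete_cases(small_cohort)
        edges = estimate_all(add_states(kept), by=())
        g = build_network(edges, "all", "all", wave=6)
        lows = edges.set_index(["item_i", "item_j", "wave"])["ci_low"]
        for i, j, data in g.edges(data=True):
            if data["weight"] > 0:
                key = (i, j, 6) if (i, j, 6) in lows.index else (j, i, 6)
                assert lows[key] > 1.0


class TestNodeStrength:
    def test_empty_network_all_zero(self):
        g = build_network(edges_frame([]), "HH", "F", wave=6)
        s = node_strength(g)
        assert (s["strength"] == 0.0).all()
        assert len(s) == 12

    def test_triangle_hand_sum(self):
        rows = [
            edge_row("dep", "pes", 6, 2.0, 1.5, 2.7, n_ij=30),
            edge_row("pes", "sui", 6, 3.0, 2.0, 4.5, n_ij=30),
            edge_row("dep", "sui", 6, 4.0, 2.5, 6.4, n_ij=30),
        ]
        g = build_network(edges_frame(rows), "HH", "F", wave=6)
        s = node_strength(g).set_index("item")["strength"]
        assert s["dep"] == pytest.approx(6.0)
        assert s["pes"] == pytest.approx(5.0)
        assert s["sui"] == pytest.approx(7.0)

    def test_handshake_identity(self, small_cohort):
        kept, _ = filter_complete_cases(small_cohort)
        edges = estimate_all(add_states(kept), by=("transition",))
        for stratum in ("HH", "OCOC", "ACAC"):
            g = build_network(edges, stratum, "all", wave=6)
            total_strength = node_strength(g)["strength"].sum()
            # independent oracle: manual iteration over the edge set
            total_weight = sum(d["weight"] for _, _, d in g.edges(data=True))
            assert total_strength == pytest.approx(2 * total_weight, rel=1e-12)

    def test_wrong_scheme_rejected(self):
        rows = [
            edge_row("dep", "pes", 6, 2.0, 1.5, 2.7, n_ij=30),
            edge_row("dep", "pes", 8, 6.0, 4.0, 9.0, n_ij=35),
        ]
        g = build_network(edges_frame(rows), "HH", "F", scheme="or_ratio")
        with pytest.raises(ValueError, match="significant_or"):
            node_strength(g)

    def test_adding_significant_edge_is_monotone(self):
        rows = [edge_row("dep", "pes", 6, 2.0, 1.5, 2.7, n_ij=30)]
        g0 = build_network(edges_frame(rows), "HH", "F", wave=6)
        rows.append(edge_row("pes", "sui", 6, 3.0, 2.0, 4.5, n_ij=30))
        g1 = build_network(edges_frame(rows), "HH", "F", wave=6)
        s0 = node_strength(g0).set_index("item")["strength"]
        s1 = node_strength(g1).set_index("item")["strength"]
        assert (s1 >= s0 - 1e-12).all()


class TestStrengthChange:
    def _pair_networks(self, rows6, rows8):
        g6 = build_network(edges_frame(rows6), "HH", "F", wave=6)
        g8 = build_network(edges_frame(rows8), "HH", "F", wave=8)
        return g6, g8

    def test_identical_networks_zero_delta(self):
        rows6 = [edge_row("dep", "pes", 6, 2.0, 1.5, 2.7, n_ij=30)]
        rows8 = [edge_row("dep", "pes", 8, 2.0, 1.5, 2.7, n_ij=30)]
        g6, g8 = self._pair_networks(rows6, rows8)
        out = strength_change(g6, g8)
        assert (out["delta"] == 0.0).all()

    def test_edge_gaining_significance(self):
        # (dep, pes) not significant at wave 6, OR 4 significant at wave 8:
        # both endpoints gain exactly 4.
        rows6 = [edge_row("dep", "pes", 6, 1.5, 0.9, 2.5, n_ij=30)]
        rows8 = [edge_row("dep", "pes", 8, 4.0, 2.0, 8.0, n_ij=30)]
        g6, g8 = self._pair_networks(rows6, rows8)
        out = strength_change(g6, g8).set_index("item")
        assert out.loc["dep", "delta"] == pytest.approx(4.0)
        assert out.loc["pes", "delta"] == pytest.approx(4.0)
        assert out.loc["sui", "delta"] == 0.0
        # ordered by |delta| descending
        deltas = strength_change(g6, g8)["delta"].abs()
        assert (deltas.diff().dropna() <= 1e-12).all()

    def test_antisymmetric_under_wave_swap(self):
        rows6 = [edge_row("dep", "pes", 6, 2.0, 1.5, 2.7, n_ij=30)]
        rows8 = [edge_row("dep", "pes", 8, 4.0, 2.0, 8.0, n_ij=30)]
        g6, g8 = self._pair_networks(rows6, rows8)
        fwd = strength_change(g6, g8).set_index("item")["delta"]
        rev = strength_change(g8, g6).set_index("item")["delta"]
        assert ((fwd + rev).abs() < 1e-12).all()

    def test_stratum_mismatch_rejected(self):
        g6 = build_network(edges_frame([]), "HH", "F", wave=6)
        g8 = build_network(edges_frame([]), "HA", "F", wave=8)
        with pytest.raises(ValueError, match="mismatch"):
            strength_change(g6, g8)


class TestEdgeList:
    def test_edge_list_mirrors_graph(self):
        rows = [
            edge_row("dep", "pes", 6, 3.0, 1.5, 6.0, n_ij=30),
            edge_row("sle", "fat", 6, 2.0, 1.4, 2.9, n_ij=25),
        ]
        g = build_network(edges_frame(rows), "HH", "F", wave=6)
        el = network_edge_list(g)
        assert len(el) == g.number_of_edges()
        assert set(zip(el["item_i"], el["item_j"])) == set(g.edges)
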