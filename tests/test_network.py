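"""Social-network construction, closeness centrality, stability and
annotator matching."""

import numpy as np
import pytest

from batcolony import network as net
from batcolony import synthetic as syn
from batcolony.errors import ConfigError
from batcolony.session_io import InteractionEvent

from conftest import make_static_session


def _two_bat_session(d=0.3):
    return make_static_session(
        {"A": [0.2, 0.2, 2.4], "B": [0.2 + d, 0.2, 2.4]}
    )


class TestAffiliationNetwork:
    def test_static_pair_distance(self):
        g = net.affiliation_network(_two_bat_session(0.3))
        assert g.weight("A", "B") == pytest.approx(0.3, abs=1e-12)

    def test_median_of_frame_distances(self):
        # B visits three distances; the edge is the median, not the mean
        pos_b = np.tile([0.2, 0.2, 2.4], (3, 1))
        pos_b[:, 0] = [0.3, 0.4, 0.2 + 0.9 * 0.5]  # d = 0.1, 0.2, 0.45
        traj = make_static_session(
            {"A": np.tile([0.2, 0.2, 2.4], (3, 1)), "B": pos_b}, n_frames=3
        )
        assert net.affiliation_network(traj).weight("A", "B") == pytest.approx(0.2)

    def test_never_copresent_pair_has_no_edge(self):
        traj = make_static_session(
            {"A": [0.2, 0.2, 2.4], "B": [2.5, 2.1, 2.4], "C": [0.3, 0.2, 2.4]}
        )
        g = net.affiliation_network(traj)
        assert g.weight("A", "B") is None
        assert g.weight("A", "C") is not None


class TestInteractionNetwork:
    events = [
        InteractionEvent(float(t), "A", "B", "affiliative") for t in range(6)
    ] + [
        InteractionEvent(10.0, "B", "A", "aggressive"),
        InteractionEvent(11.0, "A", "C", "joining"),
        InteractionEvent(12.0, "C", "B", "leaving"),  # does not involve A
    ]

    def test_affiliative_rate(self):
        g = net.interaction_network(self.events, "A", net.MODE_AFFILIATIVE, 7200.0)
        assert g.weight("A", "B") == pytest.approx(3.0)  # 6 events / 2 h

    def test_all_mode_counts_every_type_involving_focal(self):
        g_all = net.interaction_network(self.events, "A", net.MODE_ALL, 3600.0)
        g_aff = net.interaction_network(self.events, "A", net.MODE_AFFILIATIVE, 3600.0)
        g_agg = net.interaction_network(self.events, "A", net.MODE_AGGRESSIVE, 3600.0)
        join_leave = sum(
            1
            for e in self.events
            if e.itype in ("joining", "leaving") and "A" in (e.actor, e.receiver)
        )
        total_all = sum(g_all.weights.values())
        assert total_all == pytest.approx(
            sum(g_aff.weights.values()) + sum(g_agg.weights.values()) + join_leave
        )

    def test_empty_log_gives_zero_star(self):
        g = net.interaction_network([], "A", net.MODE_ALL, 3600.0, bats=["A", "B", "C"])
        assert g.weights == {("A", "B"): 0.0, ("A", "C"): 0.0}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            net.interaction_network([], "A", "bogus", 3600.0)


class TestCloseness:
    @staticmethod
    def _manual(network):
        """Independent oracle: all-pairs Dijkstra via scipy.sparse.csgraph."""
        from scipy.sparse.csgraph import shortest_path

        nodes = network.nodes
        n = len(nodes)
        mat = np.full((n, n), np.inf)
        np.fill_diagonal(mat, 0.0)
        g = network.to_graph()
        for a, b, data in g.edges(data=True):
            i, j = nodes.index(a), nodes.index(b)
            mat[i, j] = mat[j, i] = data["length"]
        dist = shortest_path(mat, method="D")
        out = {}
        for i, v in enumerate(nodes):
            reach = np.isfinite(dist[i]) & (np.arange(n) != i)
            out[v] = reach.sum() / dist[i][reach].sum() if reach.any() else 0.0
        return out

    def test_equilateral_triangle(self):
        g = net.SessionNetwork(
            "s", net.MODE_AFFILIATION, ["A", "B", "C"],
            {("A", "B"): 1.0, ("A", "C"): 1.0, ("B", "C"): 1.0},
        )
        c = net.closeness_centrality(g)
        assert all(v == pytest.approx(1.0) for v in c.values())

    def test_path_graph(self):
        g = net.SessionNetwork(
            "s", net.MODE_AFFILIATION, ["A", "B", "C"],
            {("A", "B"): 1.0, ("B", "C"): 1.0},
        )
        c = net.closeness_centrality(g)
        assert c["B"] == pytest.approx(1.0)
        assert c["A"] == pytest.approx(2.0 / 3.0)
        assert c["C"] == pytest.approx(2.0 / 3.0)

    def test_star_closed_form(self):
        n, ell = 5, 0.25
        weights = {("A", x): ell for x in "BCDE"}
        g = net.SessionNetwork("s", net.MODE_AFFILIATION, list("ABCDE"), weights)
        c = net.closeness_centrality(g)
        assert c["A"] == pytest.approx(1.0 / ell)
        for leaf in "BCDE":
            assert c[leaf] == pytest.approx((n - 1) / ((2 * n - 3) * ell))

    def test_matches_shortest_path_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(3, 8)
            nodes = [chr(65 + i) for i in range(n)]
            weights = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.7:
                        weights[(nodes[i], nodes[j])] = float(rng.uniform(0.05, 2.0))
            if not weights:
                continue
            g = net.SessionNetwork("s", net.MODE_AFFILIATION, nodes, weights)
            got = net.closeness_centrality(g)
            want = self._manual(g)
            for v in nodes:
                assert got.get(v, 0.0) == pytest.approx(want[v], abs=1e-12)

    def test_scaling_invariance(self):
        """Scaling all distances by s divides closeness by s."""
        rng = np.random.default_rng(3)
        nodes = list("ABCD")
        weights = {
            (a, b): float(rng.uniform(0.1, 1.0))
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
        }
        g1 = net.SessionNetwork("s", net.MODE_AFFILIATION, nodes, weights)
        g2 = net.SessionNetwork(
            "s", net.MODE_AFFILIATION, nodes, {k: 3.0 * v for k, v in weights.items()}
        )
        c1, c2 = net.closeness_centrality(g1), net.closeness_centrality(g2)
        for v in nodes:
            assert c2[v] == pytest.approx(c1[v] / 3.0)


class TestStability:
    @staticmethod
    def _net_from_vector(day, weights):
        return net.SessionNetwork(f"d{day}", net.MODE_AFFILIATION, list("ABCD"), weights)

    def test_identical_networks_give_r_one(self):
        rng = np.random.default_rng(0)
        nodes = list("ABCD")
        weights = {
            (a, b): float(rng.uniform(0.1, 1.0))
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
        }
        days = [(d, self._net_from_vector(d, weights)) for d in range(5)]
        curve = net.stability_curve({"g1": days})
        np.testing.assert_allclose(curve.mean_r, 1.0, atol=1e-12)

    def test_random_networks_less_stable_than_identical(self):
        rng = np.random.default_rng(1)
        nodes = list("ABCD")
        rs = []
        for _ in range(20):
            days = []
            for d in range(8):
                weights = {
                    (a, b): float(rng.uniform(0.05, 1.0))
                    for i, a in enumerate(nodes)
                    for b in nodes[i + 1 :]
                }
                days.append((d, self._net_from_vector(d, weights)))
            curve = net.stability_curve({"g": days})
            rs.append(np.nanmean(curve.mean_r))
        assert np.mean(rs) < 0.6  # far from the r = 1 of a frozen network

    def test_formation_schedule_stabilizes(self, colony5):
        """Networks decorrelated early in formation, stable after day k."""
        import dataclasses

        cfg = dataclasses.replace(colony5, n_sessions=12)
        sessions = syn.simulate_colony_sessions(
            cfg, seed=5, formation_k=5, duration=600, frame_rate=5
        )
        days = [(d, net.affiliation_network(s)) for d, s in enumerate(sessions)]
        curve = net.stability_curve({"g": days})
        early = np.nanmean(curve.mean_r[:3])
        late = np.nanmean(curve.mean_r[8:])
        assert early < late


class TestMatchAnnotations:
    # events spaced well beyond the tolerance so shifts cannot alias
    log = [
        InteractionEvent(10.0 * t, "A", "B", "affiliative") for t in range(10)
    ]

    def test_identical_logs(self):
        rep = net.match_annotations(self.log, list(self.log), time_tol=1.0)
        assert rep.agreement_rate == 1.0
        assert rep.mean_onset_diff == 0.0

    def test_shift_beyond_tolerance_kills_agreement(self):
        shifted = [
            InteractionEvent(e.time + 2.0, e.actor, e.receiver, e.itype)
            for e in self.log
        ]
        rep = net.match_annotations(self.log, shifted, time_tol=1.0)
        assert rep.agreement_rate == 0.0

    def test_partial_agreement_is_dice_ratio(self):
        # 7 of 10 events match in type within tolerance -> 2*7/20 = 0.7
        other = []
        for i, e in enumerate(self.log):
            if i < 7:
                other.append(
                    InteractionEvent(e.time + 0.2, e.actor, e.receiver, e.itype)
                )
            else:
                other.append(
                    InteractionEvent(e.time + 0.2, e.actor, e.receiver, "aggressive")
                )
        rep = net.match_annotations(self.log, other, time_tol=1.0)
        assert rep.agreement_rate == pytest.approx(0.7)
        assert rep.mean_onset_diff == pytest.approx(0.2)

    def test_symmetry(self):
        other = self.log[:6]
        a = net.match_annotations(self.log, other, 0.5)
        b = net.match_annotations(other, self.log, 0.5)
        assert a.agreement_rate == b.agreement_rate
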