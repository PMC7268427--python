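"""Road network routing, hospital assignment and catchments."""

import itertools
import math

import numpy as np
import pytest

from strokesim import (GeoPoint, HemsBase, Hospital, InputError, Mission,
                       RoadNetwork, siren_drive_min)
from strokesim.exceptions import ConfigurationError, ValidationError


def brute_force_shortest(nodes, edges, origin, dest):
    """Exhaustive enumeration of all simple paths; independent of Dijkstra."""
    adj = {n: [] for n in nodes}
    for u, v, length, speed in edges:
        t = length / speed * 60.0
        adj[u].append((v, t))
        adj[v].append((u, t))
    best = math.inf

    def walk(node, visited, total):
        nonlocal best
        if node == dest:
            best = min(best, total)
            return
        for nxt, t in adj[node]:
            if nxt not in visited:
                walk(nxt, visited | {nxt}, total + t)

    walk(origin, {origin}, 0.0)
    return best


def random_network(rng, n_nodes, p_edge=0.45):
    nodes = {f"n{i}": GeoPoint(60 + i * 0.01, 24 + i * 0.01) for i in range(n_nodes)}
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            edges.append((f"n{i}", f"n{j}", float(rng.uniform(1, 50)),
                          float(rng.choice([40, 60, 80, 100]))))
    if not edges:  # keep the graph non-trivial
        edges.append(("n0", f"n{n_nodes - 1}", 10.0, 60.0))
    return RoadNetwork(nodes, edges), nodes, edges


class TestShortestPath:
    def test_origin_equals_dest_is_zero(self):
        net = RoadNetwork({"a": GeoPoint(60, 24), "b": GeoPoint(60, 25)},
                          [("a", "b", 10, 60)])
        assert net.normal_drive_min("a", "a") == 0.0

    def test_single_edge_time(self):
        net = RoadNetwork({"a": GeoPoint(60, 24), "b": GeoPoint(60, 25)},
                          [("a", "b", 10, 60)])
        assert net.normal_drive_min("a", "b") == pytest.approx(10.0)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            net, nodes, edges = random_network(rng, n)
            o, d = rng.choice(sorted(nodes), size=2, replace=False)
            assert net.normal_drive_min(o, d) == pytest.approx(
                brute_force_shortest(nodes, edges, o, d), abs=1e-9)

    def test_disconnected_pair_returns_inf_not_raise(self):
        net = RoadNetwork({"a": GeoPoint(60, 24), "b": GeoPoint(60, 25),
                           "c": GeoPoint(61, 24)}, [("a", "b", 5, 50)])
        assert math.isinf(net.normal_drive_min("a", "c"))

    def test_unknown_node_rejected(self):
        net = RoadNetwork({"a": GeoPoint(60, 24)}, [])
        with pytest.raises(InputError):
            net.normal_drive_min("a", "zz")

    def test_triangle_inequality_over_node_triples(self):
        rng = np.random.default_rng(99)
        net, nodes, _ = random_network(rng, 8, p_edge=0.6)
        ids = sorted(nodes)
        for a, b, c in itertools.permutations(ids, 3):
            tab, tbc, tac = (net.normal_drive_min(a, b), net.normal_drive_min(b, c),
                             net.normal_drive_min(a, c))
            if math.isfinite(tab) and math.isfinite(tbc):
                assert tac <= tab + tbc + 1e-9


class TestValidation:
    def test_empty_network_rejected(self):
        with pytest.raises(InputError):
            RoadNetwork({}, [])

    def test_dangling_edge_rejected(self):
        with pytest.raises(ValidationError):
            RoadNetwork({"a": GeoPoint(60, 24)}, [("a", "ghost", 1, 50)])

    @pytest.mark.parametrize("length,speed", [(0, 50), (-1, 50), (5, 0), (5, -10)])
    def test_nonpositive_edge_attributes_rejected(self, length, speed):
        with pytest.raises(ValidationError):
            RoadNetwork({"a": GeoPoint(60, 24), "b": GeoPoint(60, 25)},
                        [("a", "b", length, speed)])


class TestSiren:
    def test_twenty_percent_reduction(self):
        assert siren_drive_min(100.0) == pytest.approx(80.0)
        assert siren_drive_min(50.0, 0.20) == pytest.approx(40.0)
        assert siren_drive_min(0.0) == 0.0

    def test_monotone_and_homogeneous(self):
        ts = np.linspace(0, 200, 21)
        out = [siren_drive_min(t) for t in ts]
        assert all(b >= a for a, b in zip(out, out[1:]))
        assert siren_drive_min(2 * 37.0) == pytest.approx(2 * siren_drive_min(37.0))

    def test_full_reduction_rejected(self):
        with pytest.raises(ConfigurationError):
            siren_drive_min(10.0, 1.0)


class TestSnap:
    def test_point_at_node_snaps_to_it(self):
        net = RoadNetwork({"a": GeoPoint(60, 24), "b": GeoPoint(61, 25)},
                          [("a", "b", 10, 60)])
        assert net.snap_to_node(GeoPoint(61, 25)) == "b"

    def test_equidistant_tie_breaks_to_smallest_id(self):
        net = RoadNetwork({"a": GeoPoint(60.0, 24.0), "b": GeoPoint(60.0, 25.0)},
                          [("a", "b", 10, 60)])
        assert net.snap_to_node(GeoPoint(60.0, 24.5)) == "a"

    def test_matches_linear_scan_oracle(self):
        from conftest import haversine_oracle
        rng = np.random.default_rng(17)
        nodes = {f"n{i:02d}": GeoPoint(60 + rng.uniform(0, 2), 24 + rng.uniform(0, 4))
                 for i in range(20)}
        net = RoadNetwork(nodes, [(f"n{i:02d}", f"n{i + 1:02d}", 5, 60)
                                  for i in range(19)])
        for _ in range(50):
            p = GeoPoint(60 + rng.uniform(0, 2), 24 + rng.uniform(0, 4))
            expected = min(nodes, key=lambda k: (haversine_oracle(
                p.lat, p.lon, nodes[k].lat, nodes[k].lon), k))
            assert net.snap_to_node(p) == expected

    def test_snap_many_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        nodes = {f"n{i}": GeoPoint(60 + rng.uniform(0, 1), 24 + rng.uniform(0, 1))
                 for i in range(15)}
        net = RoadNetwork(nodes, [("n0", "n1", 5, 60)])
        lat = 60 + rng.uniform(0, 1, 30)
        lon = 24 + rng.uniform(0, 1, 30)
        batch = net.snap_many(lat, lon)
        for i in range(30):
            assert batch[i] == net.snap_to_node(GeoPoint(lat[i], lon[i]))


def line_world():
    """Five nodes on a line with a lysis hospital near and thrombectomy far."""
    nodes = {f"n{i}": GeoPoint(60.0, 24.0 + 0.2 * i) for i in range(5)}
    edges = [(f"n{i}", f"n{i + 1}", 20, 80) for i in range(4)]  # 15 min/edge
    net = RoadNetwork(nodes, edges)
    hospitals = [Hospital("HL", GeoPoint(60.0, 24.2), "thrombolysis"),
                 Hospital("HT", GeoPoint(60.0, 24.8), "thrombectomy")]
    return net, hospitals


class TestNearestHospital:
    def test_single_eligible_hospital(self):
        net, hospitals = line_world()
        h, t = net.nearest_hospital(GeoPoint(60.0, 24.0), "thrombectomy", hospitals)
        assert h.id == "HT"
        assert t == pytest.approx(4 * 15 * 0.8)

    def test_tier_filter_forces_thrombectomy(self):
        net, hospitals = line_world()
        h1, t1 = net.nearest_hospital(GeoPoint(60.0, 24.0), "thrombolysis", hospitals)
        h2, t2 = net.nearest_hospital(GeoPoint(60.0, 24.0), "thrombectomy", hospitals)
        assert (h1.id, h2.id) == ("HL", "HT")
        assert t1 <= t2

    def test_thrombectomy_hospital_admits_lysis_tier(self):
        net, _ = line_world()
        only_tk = [Hospital("HT", GeoPoint(60.0, 24.8), "thrombectomy")]
        h, _ = net.nearest_hospital(GeoPoint(60.0, 24.0), "thrombolysis", only_tk)
        assert h.id == "HT"

    def test_matches_per_hospital_scan_oracle(self):
        rng = np.random.default_rng(31)
        net, nodes, edges = random_network(rng, 12, p_edge=0.35)
        ids = sorted(nodes)
        hospitals = [Hospital(f"H{i}", nodes[ids[i * 2]],
                              "thrombectomy" if i < 2 else "thrombolysis")
                     for i in range(5)]
        for _ in range(25):
            scene = nodes[rng.choice(ids)]
            for tier in ("thrombolysis", "thrombectomy"):
                h, t = net.nearest_hospital(scene, tier, hospitals)
                elig = [x for x in hospitals if x.satisfies(tier)]
                per = {x.id: brute_force_shortest(
                    nodes, edges, net.snap_to_node(scene),
                    net.snap_to_node(x.location)) for x in elig}
                best = min(sorted(per), key=lambda k: per[k])
                if math.isinf(per[best]):
                    assert h is None
                else:
                    assert h.id == best
                    assert t == pytest.approx(per[best] * 0.8, abs=1e-9)

    def test_lysis_tier_never_slower_than_thrombectomy_tier(self):
        rng = np.random.default_rng(8)
        net, nodes, _ = random_network(rng, 10, p_edge=0.5)
        ids = sorted(nodes)
        hospitals = [Hospital("H0", nodes[ids[0]], "thrombectomy"),
                     Hospital("H1", nodes[ids[3]], "thrombolysis"),
                     Hospital("H2", nodes[ids[6]], "thrombolysis")]
        for nid in ids:
            _, t1 = net.nearest_hospital(nodes[nid], "thrombolysis", hospitals)
            _, t2 = net.nearest_hospital(nodes[nid], "thrombectomy", hospitals)
            assert t1 <= t2 + 1e-12

    def test_no_eligible_hospital_raises(self):
        net, _ = line_world()
        with pytest.raises(InputError):
            net.nearest_hospital(GeoPoint(60, 24), "thrombectomy",
                                 [Hospital("HL", GeoPoint(60.0, 24.2), "thrombolysis")])


class TestCatchments:
    def _missions(self, locs):
        return [Mission(f"m{i}", p, "other_urban", 5.0) for i, p in enumerate(locs)]

    def test_single_hospital_gets_all_missions(self):
        net, _ = line_world()
        hospitals = [Hospital("HT", GeoPoint(60.0, 24.8), "thrombectomy")]
        locs = [GeoPoint(60.0, 24.0 + 0.2 * i) for i in range(5)]
        out = net.catchments(self._missions(locs), hospitals, "thrombectomy")
        assert set(out) == {"HT"}
        hull = out["HT"]
        assert all(hull.contains(p, tol_km=1e-6) if not hull.degenerate
                   else True for p in locs)

    def test_two_separated_clusters_partition_cleanly(self):
        nodes = {}
        edges = []
        for c, lon0 in (("a", 24.0), ("b", 27.0)):
            for i in range(4):
                nodes[f"{c}{i}"] = GeoPoint(60.0 + 0.05 * (i % 2), lon0 + 0.05 * (i // 2))
            edges += [(f"{c}0", f"{c}{i}", 3, 50) for i in range(1, 4)]
        edges.append(("a0", "b0", 160, 100))
        net = RoadNetwork(nodes, edges)
        hospitals = [Hospital("HA", nodes["a0"], "thrombectomy"),
                     Hospital("HB", nodes["b0"], "thrombectomy")]
        missions = self._missions([nodes[k] for k in sorted(nodes)])
        out = net.catchments(missions, hospitals, "thrombectomy")
        assert set(out) == {"HA", "HB"}
        # each cluster's points fall in its own hull (oracle: nearest by scan)
        for m in missions:
            h, _ = net.nearest_hospital(m.location, "thrombectomy", hospitals)
            assert out[h.id].contains(m.location, tol_km=1e-6) or out[h.id].degenerate

    def test_empty_mission_list_gives_empty_map(self):
        net, hospitals = line_world()
        assert net.catchments([], hospitals, "thrombolysis") == {}

    def test_small_group_is_degenerate(self):
        net, _ = line_world()
        hospitals = [Hospital("HT", GeoPoint(60.0, 24.8), "thrombectomy")]
        out = net.catchments(self._missions([GeoPoint(60.0, 24.0)]),
                             hospitals, "thrombectomy")
        assert out["HT"].degenerate
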