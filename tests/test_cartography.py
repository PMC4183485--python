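import itertools

import numpy as np
import pytest

from cartonet import (Network, Partition, RegionThresholds, build_cartography,
                      classify_node, module_link_counts,
                      participation_coefficients, pz_scatter,
                      within_module_zscores)
from conftest import clique_edges, random_network, random_partition


def star_module():
    """One star of 5 nodes plus enough intra-module wiring to be a module."""
    center = "hub"
    leaves = [f"l{i}" for i in range(4)]
    net = Network.from_edges([(center, l) for l in leaves])
    part = Partition({n: "M" for n in [center] + leaves})
    return net, part, center, leaves


class TestModuleLinkCounts:
    def test_neighbours_counted_per_module(self):
        net = Network.from_edges([("x", "a1"), ("x", "a2"), ("x", "b1")])
        part = Partition({"x": "A", "a1": "A", "a2": "A", "b1": "B"})
        assert module_link_counts(net, part)["x"] == {"A": 2, "B": 1}

    def test_isolated_node_empty_map(self):
        net = Network.from_edges([("a", "b")], nodes=["a", "b", "z"])
        part = Partition({"a": "A", "b": "A", "z": "A"})
        assert module_link_counts(net, part)["z"] == {}

    def test_clique_inside_one_module(self):
        labs = [f"v{i}" for i in range(5)]
        net = Network.from_edges(clique_edges(labs))
        part = Partition({n: "M" for n in labs})
        counts = module_link_counts(net, part)
        assert all(counts[n] == {"M": 4} for n in labs)

    def test_missing_node_rejected(self):
        net = Network.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="missing"):
            module_link_counts(net, Partition({"a": "A"}))


class TestZScores:
    def test_regular_module_all_zero(self):
        labs = [f"v{i}" for i in range(4)]
        net = Network.from_edges(clique_edges(labs))
        part = Partition({n: "M" for n in labs})
        assert set(within_module_zscores(net, part).values()) == {0.0}

    def test_star_module_hand_computed(self):
        # kappa: center 4, leaves 1 -> mean 1.6, population sd 1.2
        net, part, center, leaves = star_module()
        z = within_module_zscores(net, part)
        assert z[center] == pytest.approx(2.0)
        assert all(z[l] == pytest.approx(-0.5) for l in leaves)

    def test_global_mode_uses_all_nodes(self):
        net, part0, center, leaves = star_module()
        # split: center+2 leaves in M1, 2 leaves in M2; global stats pooled
        part = Partition({center: "M1", "l0": "M1", "l1": "M1", "l2": "M2", "l3": "M2"})
        zg = within_module_zscores(net, part, mode="global")
        kappa = [2, 1, 1, 0, 0]  # center, l0, l1, l2, l3 own-module links
        mu, sd = np.mean(kappa), np.std(kappa)
        assert zg[center] == pytest.approx((2 - mu) / sd)

    def test_standardisation_identity_random(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            net = random_network(rng, ensure_edge=True)
            part = random_partition(rng, net)
            z = within_module_zscores(net, part)
            for members in part.modules:
                vals = np.array([z[n] for n in members])
                assert abs(vals.mean()) < 1e-12
                assert vals.std() == pytest.approx(0.0, abs=1e-9) or \
                    vals.std() == pytest.approx(1.0, abs=1e-9)


class TestParticipation:
    def test_all_links_internal(self):
        labs = [f"v{i}" for i in range(4)]
        net = Network.from_edges(clique_edges(labs))
        part = Partition({n: "M" for n in labs})
        for variant in ("original", "modified"):
            assert set(participation_coefficients(net, part, variant).values()) == {0.0}

    def test_uniform_spread_over_four_modules(self):
        net = Network.from_edges([("c", f"a{i}") for i in range(1, 5)])
        part = Partition({"c": "M1", "a1": "M1", "a2": "M2", "a3": "M3", "a4": "M4"})
        p_orig = participation_coefficients(net, part, "original")["c"]
        p_mod = participation_coefficients(net, part, "modified")["c"]
        assert p_orig == pytest.approx(0.75)  # the 1 - 1/N ceiling for N=4
        assert p_mod == pytest.approx(1 - (1 / 4) ** 2)  # 0.9375, above the ceiling

    def test_modified_at_35_percent_intra(self):
        # 20 links, 7 inside (35%): P = 1 - 0.35^2 = 0.8775, the R3/R4 cut
        edges = [("c", f"in{i}") for i in range(7)] + [("c", f"out{i}") for i in range(13)]
        net = Network.from_edges(edges)
        assign = {"c": "M0", **{f"in{i}": "M0" for i in range(7)},
                  **{f"out{i}": f"M{1 + i % 3}" for i in range(13)}}
        p = participation_coefficients(net, Partition(assign), "modified")["c"]
        assert p == pytest.approx(0.8775)

    def test_isolated_node_zero(self):
        net = Network.from_edges([("a", "b")], nodes=["a", "b", "z"])
        part = Partition({"a": "A", "b": "A", "z": "B"})
        for variant in ("original", "modified"):
            assert participation_coefficients(net, part, variant)["z"] == 0.0

    def test_bounds_and_ordering_random(self):
        """P_original <= P_modified <= 1 and P_original <= 1 - 1/N."""
        rng = np.random.default_rng(13)
        for _ in range(30):
            net = random_network(rng, ensure_edge=True)
            part = random_partition(rng, net)
            po = participation_coefficients(net, part, "original")
            pm = participation_coefficients(net, part, "modified")
            for n in net.nodes:
                assert 0 <= po[n] <= pm[n] <= 1 + 1e-12
                assert po[n] <= 1 - 1 / part.n_modules + 1e-12


class TestClassify:
    @pytest.mark.parametrize("z,P,region", [
        (0.0, 0.0, "R1"),
        (0.0, 0.05, "R1"),   # upper boundary belongs to the lower region
        (0.0, 0.3, "R2"),
        (0.0, 0.7, "R3"),
        (0.0, 0.95, "R4"),
        (2.5, 0.0, "R5"),    # z at the hub cut is a hub
        (3.0, 0.0, "R5"),
        (3.0, 0.5, "R6"),
        (3.0, 0.75, "R6"),
        (3.0, 0.9, "R7"),
    ])
    def test_region_examples(self, z, P, region):
        assert classify_node(z, P) == region

    def test_thirty_five_percent_rule(self):
        # intra fraction 0.30 -> modified P = 0.91 > p3 -> kinless R4
        assert classify_node(0.0, 1 - 0.30 ** 2) == "R4"
        # intra fraction 0.40 -> modified P = 0.84 <= p3 -> connector R3
        assert classify_node(0.0, 1 - 0.40 ** 2) == "R3"

    def test_total_on_grid(self):
        """Every (z, P) pair maps to exactly one region."""
        regions = set()
        for z in np.linspace(-4, 6, 100):
            for P in np.linspace(0, 1, 100):
                regions.add(classify_node(z, P))
        assert regions == {f"R{i}" for i in range(1, 8)}

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_node(0.0, 1.5)

    def test_custom_thresholds(self):
        th = RegionThresholds(z_hub=1.0, p1=0.1, p2=0.5, p3=0.9, p5=0.2, p6=0.6)
        assert classify_node(0.5, 0.95, th) == "R4"
        assert classify_node(1.0, 0.5, th) == "R6"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RegionThresholds(p1=0.7, p2=0.6)


class TestBuildCartography:
    def test_disjoint_cliques_all_ultra_peripheral(self, two_cliques):
        net, part = two_cliques
        records = build_cartography(net, part)
        assert len(records) == net.n_nodes
        assert {r.region for r in records} == {"R1"}
        assert all(r.P == 0.0 and r.z == 0.0 for r in records)

    def test_bridge_node_lands_in_r4(self):
        """A node keeping <35% of its links in its own module is kinless."""
        mods = {f"M{m}": [f"m{m}_{i}" for i in range(5)] for m in range(4)}
        edges = sum((clique_edges(v) for v in mods.values()), [])
        bridge = "m0_0"
        # bridge keeps 4 intra links, add 9 inter links: 4/13 < 0.35
        for m in range(1, 4):
            for i in range(3):
                edges.append((bridge, f"m{m}_{i}"))
        net = Network.from_edges(edges)
        part = Partition({n: m for m, nodes in mods.items() for n in nodes})
        rec = {r.node: r for r in build_cartography(net, part)}
        assert rec[bridge].kappa / rec[bridge].k < 0.35
        assert rec[bridge].region == "R4"

    def test_conservation_and_record_count(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            net = random_network(rng, ensure_edge=True)
            part = random_partition(rng, net)
            records = build_cartography(net, part)
            assert len(records) == net.n_nodes
            counts = module_link_counts(net, part)
            for r in records:
                assert sum(counts[r.node].values()) == r.k
                assert 0 <= r.kappa <= r.k

    def test_module_label_permutation_invariance(self):
        rng = np.random.default_rng(15)
        net = random_network(rng, ensure_edge=True)
        part = random_partition(rng, net)
        relabel = {m: f"X{m}" for m in part.module_labels}
        permuted = Partition({n: relabel[m] for n, m in part.assignment.items()})
        a = {r.node: (r.z, r.P, r.region) for r in build_cartography(net, part)}
        b = {r.node: (r.z, r.P, r.region) for r in build_cartography(net, permuted)}
        assert a == b


class TestScatter:
    def test_writes_nonempty_file(self, two_cliques, tmp_path):
        net, part = two_cliques
        records = build_cartography(net, part)
        out = tmp_path / "pz.png"
        pz_scatter(records, out)
        assert out.exists() and out.stat().st_size > 0

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            pz_scatter([], tmp_path / "x.png")
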