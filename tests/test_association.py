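import numpy as np
import pytest

from betafold.association import (
    AssociateEvent,
    ContactGraph,
    Partition,
    interchain_graph,
    label_clusters,
    lifetime_statistics,
    track_associates,
)
from betafold.hbonds import detect_hbonds
from betafold.pipeline import docked_assembly
from betafold.structures import assemble_multichain, build_preset_chain

from conftest import random_frame


def make_partitions(frames, chains="ABCDEFGH", dt=1.0):
    """Partitions from per-frame lists of connected groups (rest singletons)."""
    out = []
    for k, groups in enumerate(frames):
        used = set().union(*[set(g) for g in groups]) if groups else set()
        classes = [frozenset(g) for g in groups]
        classes += [frozenset(c) for c in chains if c not in used]
        out.append(Partition(k, tuple(classes), time=k * dt))
    return out


@pytest.fixture(scope="module")
def spread():
    chain = build_preset_chain("extended", 6)
    return assemble_multichain(chain, 8, spacing=3.0, seed=5)


class TestInterchainGraph:

    def test_spread_box_has_no_edges(self, spread):
        g = interchain_graph(spread)
        assert g.edges == frozenset()
        assert g.nodes == tuple("ABCDEFGH")

    def test_single_bond_single_undirected_edge(self, spread):
        dimer = docked_assembly(spread, [("A", "B")])
        g = interchain_graph(dimer)
        assert g.edges == frozenset({frozenset(("A", "B"))})

    def test_edges_equal_pairwise_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            conf = random_frame(rng, n_residues=8, n_chains=4, box_side=0.8)
            g = interchain_graph(conf)
            expected = set()
            for ev in detect_hbonds(conf, scope="interchain"):
                expected.add(frozenset((ev.donor_residue[0], ev.acceptor_residue[0])))
            assert g.edges == frozenset(expected)

    def test_single_chain_rejected(self):
        chain = build_preset_chain("extended", 6)
        with pytest.raises(ValueError, match="two chains"):
            interchain_graph(chain)


class TestLabelClusters:
    def test_no_edges_all_singletons(self):
        g = ContactGraph(0, tuple("ABCDEFGH"), frozenset())
        part = label_clusters(g)
        assert len(part.classes) == 8
        assert all(len(c) == 1 for c in part.classes)

    def test_transitive_chain_of_edges(self):
        g = ContactGraph(0, tuple("ABCDEFGH"),
                         frozenset({frozenset("AB"), frozenset("BC")}))
        part = label_clusters(g)
        assert frozenset("ABC") in part.classes
        assert sum(len(c) for c in part.classes) == 8

    def test_matches_networkx_components_on_random_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(2, 9))
            nodes = tuple(chr(ord("A") + i) for i in range(n))
            edges = set()
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.3:
                        edges.add(frozenset((nodes[i], nodes[j])))
            part = label_clusters(ContactGraph(0, nodes, frozenset(edges)))
            gx = nx.Graph()
            gx.add_nodes_from(nodes)
            gx.add_edges_from(tuple(e) for e in edges)
            expected = {frozenset(c) for c in nx.connected_components(gx)}
            assert set(part.classes) == expected


class TestTrackAssociates:
    def test_simple_dimer_open_at_end(self):
        parts = make_partitions([[("AB")]] * 10, chains="ABC")
        events = track_associates(parts, dt=1.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.order == 2
        assert ev.lifetime == pytest.approx(10.0)
        assert ev.open_at_end

    def test_sub_associate_survives_inside_trimer(self):
        frames = []
        for k in range(10):
            frames.append([("ABC")] if 4 <= k <= 6 else [("AB")])
        events = track_associates(make_partitions(frames, chains="ABC"), dt=1.0)
        by_order = {e.order: e for e in events}
        assert set(by_order) == {2, 3}
        assert by_order[2].lifetime == pytest.approx(10.0)  # alive inside the trimer
        assert by_order[3].birth == pytest.approx(4.0)
        assert by_order[3].lifetime == pytest.approx(3.0)

    def test_split_follows_larger_overlap(self):
        frames = [[("ABC")], [("ABC")], [("AB")], [("AB")]]
        events = track_associates(make_partitions(frames, chains="ABC"), dt=1.0)
        dimers = [e for e in events if e.order == 2]
        trimers = [e for e in events if e.order == 3]
        assert len(dimers) == 1 and len(trimers) == 1
        assert dimers[0].lifetime == pytest.approx(4.0)
        assert trimers[0].lifetime == pytest.approx(2.0)
        assert dimers[0].lineage == trimers[0].lineage

    def test_merge_keeps_smallest_chain_lineage_alive(self):
        frames = [[("AB"), ("CD")], [("ABCD")], [("AB"), ("CD")]]
        events = track_associates(make_partitions(frames, chains="ABCD"), dt=1.0)
        orders = sorted(e.order for e in events)
        # AB's dimer survives throughout; CD's dies at the merge and a new one
        # is born at the split; the tetramer and trimer live one frame
        assert orders == [2, 2, 2, 3, 4]
        ab = [e for e in events if e.order == 2 and e.lifetime == 3.0]
        assert len(ab) == 1

    def test_gap_tolerance_bridges_single_frame_dropout(self):
        frames = [[("AB")], [], [("AB")]]
        strict = track_associates(make_partitions(frames, chains="AB"), dt=1.0)
        assert len([e for e in strict if e.order == 2]) == 2
        lenient = track_associates(make_partitions(frames, chains="AB"), dt=1.0, gap=1)
        assert len([e for e in lenient if e.order == 2]) == 1

    def test_de_novo_trimer_opens_both_orders(self):
        frames = [[], [("ABC")], [("ABC")], []]
        events = track_associates(make_partitions(frames, chains="ABC"), dt=1.0)
        births = {(e.order, e.birth) for e in events}
        assert births == {(2, 1.0), (3, 1.0)}

    def test_unordered_times_rejected(self):
        parts = make_partitions([[("AB")], [("AB")]], chains="AB")
        parts[1].time = -5.0
        with pytest.raises(ValueError, match="order"):
            track_associates(parts)

    def test_order_nesting_invariant(self):
        rng = np.random.default_rng(3)
        chains = "ABCDE"
        frames = []
        for _ in range(60):
            groups = []
            perm = list(chains)
            rng.shuffle(perm)
            size = int(rng.integers(0, 6))
            if size >= 2:
                groups.append("".join(perm[:size]))
            frames.append(groups)
        events = track_associates(make_partitions(frames, chains=chains), dt=1.0)
        by_lineage: dict[int, list[AssociateEvent]] = {}
        for e in events:
            by_lineage.setdefault(e.lineage, []).append(e)
        for evs in by_lineage.values():
            cover = {}
            for e in evs:
                cover.setdefault(e.order, 0.0)
                cover[e.order] += e.lifetime
            for k in sorted(cover)[1:]:
                assert cover[k] <= cover[k - 1] + 1e-9


class TestLifetimeStatistics:
    def test_single_event_arithmetic(self):
        ev = AssociateEvent(0, 2, 0.0, 5000.0)  # 5 ns alive in a 100 ns run
        table = lifetime_statistics([ev], span_ps=100_000.0)
        assert table.orders == (2,)
        assert table.median_ns[0] == pytest.approx(5.0)
        assert table.longest_ns[0] == pytest.approx(5.0)
        assert table.trajectory_percent[0] == pytest.approx(5.0)
        assert table.per_1000ns[0] == pytest.approx(10.0)

    def test_missing_order_absent_from_table(self):
        ev = AssociateEvent(0, 2, 0.0, 1000.0)
        table = lifetime_statistics([ev], span_ps=10_000.0)
        assert 3 not in table.orders

    def test_median_and_longest_order_statistics(self):
        events = [AssociateEvent(i, 2, 0.0, ns * 1000.0) for i, ns in enumerate((1, 2, 9))]
        table = lifetime_statistics(events, span_ps=100_000.0)
        assert table.median_ns[0] == pytest.approx(2.0)
        assert table.longest_ns[0] == pytest.approx(9.0)

    def test_overlapping_events_do_not_double_count_coverage(self):
        events = [AssociateEvent(0, 2, 0.0, 6000.0), AssociateEvent(1, 2, 3000.0, 9000.0)]
        table = lifetime_statistics(events, span_ps=9000.0)
        assert table.trajectory_percent[0] == pytest.approx(100.0)

    def test_relabeling_chains_leaves_statistics_unchanged(self):
        # overlaps are distinct throughout, so no tie-break depends on labels
        frames = [[("ABC")], [("ABC"), ("DE")], [("ABCDE")], [("DE")]]
        parts = make_partitions(frames, chains="ABCDE")
        swapped = [[g.translate(str.maketrans("ABCDE", "EDCBA")) for g in f] for f in frames]
        parts2 = make_partitions(swapped, chains="ABCDE")
        t1 = lifetime_statistics(track_associates(parts, dt=1.0), span_ps=4.0)
        t2 = lifetime_statistics(track_associates(parts2, dt=1.0), span_ps=4.0)
        assert t1 == t2
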