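"""Multichain associate detection and lifetime bookkeeping.

Chains belong to the same associate when at least one interchain hydrogen
bond (discrete criterion) links them; per frame the chains are sorted
into equivalence classes with a Hoshen-Kopelman style union-find pass
over the pairwise contact graph.  Components are then matched frame to
frame into lineages, and for every order k (dimer, trimer, ...) an event
is alive while its lineage holds at least k chains — the underlying
smaller associate stays alive inside a larger one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hbonds import HBondCriteria, detect_hbonds
from .trajio import Conformation, Topology, Trajectory

__all__ = [
    "ContactGraph",
    "Partition",
    "AssociateEvent",
    "LifetimeTable",
    "interchain_graph",
    "label_clusters",
    "track_associates",
    "lifetime_statistics",
]


@dataclass
class ContactGraph:
    """Per-frame chain-level hydrogen-bond connectivity."""

    frame: int
    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("edges must join two distinct chains")
            if not e <= set(self.nodes):
                raise ValueError(f"edge {set(e)} references unknown chains")


@dataclass
class Partition:
    """Equivalence classes of chains in one frame (connected components)."""

    frame: int
    classes: tuple[frozenset[str], ...]
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        all_members = [c for cls in self.classes for c in cls]
        if len(all_members) != len(set(all_members)):
            raise ValueError("classes must be disjoint")


@dataclass
class AssociateEvent:
    """Birth/death interval of an order-k associate within a lineage."""

    lineage: int
    order: int
    birth: float  # ps
    death: float  # ps (exclusive; birth + n_alive_frames * dt)
    open_at_end: bool = False
    members: tuple[frozenset[str], ...] = ()

    @property
    def lifetime(self) -> float:
        return self.death - self.birth

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("associates have order k >= 2")
        if self.death < self.birth:
            raise ValueError("death must not precede birth")


def interchain_graph(frame: Conformation, criteria: HBondCriteria = HBondCriteria(),
                     box: Sequence[float] | None = None,
                     frame_index: int = 0) -> ContactGraph:
    """Chain contact graph: edge A-B iff >= 1 interchain H-bond either way."""
    chains = frame.topology.chains
    if len(chains) < 2:
        raise ValueError("interchain graph requires at least two chains")
    edges = set()
    for ev in detect_hbonds(frame, criteria=criteria, scope="interchain", box=box,
                            frame_index=frame_index):
        edges.add(frozenset((ev.donor_residue[0], ev.acceptor_residue[0])))
    return ContactGraph(frame_index, chains, frozenset(edges))


def label_clusters(graph: ContactGraph) -> Partition:
    """Hoshen-Kopelman cluster labeling: union-find over the contact edges.

    Classes are the connected components, each canonically labeled by (and
    ordered on) its smallest member chain id.
    """
    parent = {c: c for c in graph.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in graph.edges:
        a, b = sorted(e)
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the lexicographically smallest id as the class label
            lo, hi = sorted((ra, rb))
            parent[hi] = lo
    groups: dict[str, set[str]] = {}
    for c in graph.nodes:
        groups.setdefault(find(c), set()).add(c)
    classes = tuple(
        frozenset(groups[k]) for k in sorted(groups, key=lambda s: min(groups[s]))
    )
    return Partition(graph.frame, classes)


def partitions_from_trajectory(traj: Trajectory,
                               criteria: HBondCriteria = HBondCriteria()) -> list[Partition]:
    """Convenience: label every frame of a multichain trajectory."""
    out = []
    for k in range(traj.n_frames):
        box = None if traj.box is None else traj.box[k]
        part = label_clusters(interchain_graph(traj.frame(k), criteria, box, k))
        part.time = float(traj.times[k])
        out.append(part)
    return out


class _Lineage:
    __slots__ = ("id", "members", "events", "history")

    def __init__(self, lid: int, members: frozenset, birth: float):
        self.id = lid
        self.members = members
        self.events: dict[int, float] = {k: birth for k in range(2, len(members) + 1)}
        self.history: list[frozenset] = [members]


def track_associates(partitions: Sequence[Partition], dt: float | None = None,
                     gap: int = 0) -> list[AssociateEvent]:
    """Follow associates through time and emit order-k lifetime events.

    Components of size >= 2 are matched frame to frame by maximal member
    overlap (ties to the component holding the smallest chain id); the
    matched successor inherits the lineage.  Within a lineage an order-k
    event is alive while the lineage size is >= k; a single frame of
    disconnection kills it unless ``gap`` > 0 consecutive absent frames are
    tolerated.  Events alive in the final frame are flagged open; their
    observed length still counts.  Death times are exclusive: an event
    alive in frames f..g has lifetime (g - f + 1) frame intervals.
    """
    if not partitions:
        return []
    times = [p.time for p in partitions]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("partitions must be in strictly increasing time order")
    if dt is None:
        dt = times[1] - times[0] if len(times) > 1 else 1.0

    events: list[AssociateEvent] = []
    lineages: list[_Lineage] = []
    missing: dict[int, int] = {}  # lineage id -> consecutive absent frames
    next_id = 0

    def close(lin: _Lineage, order: int, death: float, open_end: bool = False) -> None:
        events.append(
            AssociateEvent(lin.id, order, lin.events.pop(order), death,
                           open_at_end=open_end, members=tuple(lin.history))
        )

    for part in partitions:
        t = part.time
        comps = [c for c in part.classes if len(c) >= 2]
        # candidate (overlap, component, lineage) matches, deterministic order
        triples = []
        for lin in lineages:
            for c in comps:
                ov = len(lin.members & c)
                if ov:
                    triples.append((-ov, min(c), min(lin.members), lin.id, lin, c))
        triples.sort(key=lambda x: x[:4])
        matched_lin: set[int] = set()
        matched_comp: set[frozenset] = set()
        survivors: list[_Lineage] = []
        for _ov, _mc, _ml, _lid, lin, c in triples:
            if lin.id in matched_lin or c in matched_comp:
                continue
            matched_lin.add(lin.id)
            matched_comp.add(c)
            lin.members = c
            lin.history.append(c)
            size = len(c)
            for k in [k for k in lin.events if k > size]:
                close(lin, k, t)
            for k in range(2, size + 1):
                lin.events.setdefault(k, t)
            missing.pop(lin.id, None)
            survivors.append(lin)
        for lin in lineages:
            if lin.id in matched_lin:
                continue
            miss = missing.get(lin.id, 0) + 1
            if miss <= gap:
                missing[lin.id] = miss
                survivors.append(lin)
            else:
                for k in list(lin.events):
                    close(lin, k, t)
                missing.pop(lin.id, None)
        for c in comps:
            if c not in matched_comp:
                lin = _Lineage(next_id, c, t)
                next_id += 1
                survivors.append(lin)
        lineages = survivors

    end = times[-1] + dt
    for lin in lineages:
        for k in sorted(lin.events):
            close(lin, k, end, open_end=lin.id not in missing)
    return sorted(events, key=lambda e: (e.birth, e.lineage, e.order))


@dataclass
class LifetimeTable:
    """Per-order lifetime statistics in the style of an associate table."""

    orders: tuple[int, ...]
    median_ns: tuple[float, ...]
    longest_ns: tuple[float, ...]
    trajectory_percent: tuple[float, ...]
    per_1000ns: tuple[float, ...]

    ORDER_NAMES = {2: "dimer", 3: "trimer", 4: "tetramer", 5: "pentamer",
                   6: "hexamer", 7: "heptamer", 8: "octamer"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "associate": [self.ORDER_NAMES.get(k, f"{k}-mer") for k in self.orders],
                "median_lifetime_ns": self.median_ns,
                "longest_lifetime_ns": self.longest_ns,
                "trajectory_percentage": self.trajectory_percent,
                "associates_per_1000ns": self.per_1000ns,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def lifetime_statistics(events: Sequence[AssociateEvent], span_ps: float,
                        dt: float | None = None) -> LifetimeTable:
    """Summarize events per order: median/longest lifetime (ns), percentage
    of the trajectory with >= 1 alive event, and event count per 1000 ns.

    Orders with no events are simply absent from the table.
    """
    if span_ps <= 0:
        raise ValueError("trajectory span must be positive")
    span_ns = span_ps / 1000.0
    by_order: dict[int, list[AssociateEvent]] = {}
    for ev in events:
        by_order.setdefault(ev.order, []).append(ev)
    orders, med, longest, perc, rate = [], [], [], [], []
    for k in sorted(by_order):
        evs = by_order[k]
        lt_ns = np.array([e.lifetime for e in evs]) / 1000.0
        # fraction of the run covered by >= 1 alive event of this order
        intervals = sorted((e.birth, e.death) for e in evs)
        covered, cur_lo, cur_hi = 0.0, None, None
        for lo, hi in intervals:
            if cur_lo is None:
                cur_lo, cur_hi = lo, hi
            elif lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
        if cur_lo is not None:
            covered += cur_hi - cur_lo
        orders.append(k)
        med.append(float(np.median(lt_ns)))
        longest.append(float(np.max(lt_ns)))
        perc.append(100.0 * min(covered / span_ps, 1.0))
        rate.append(len(evs) * 1000.0 / span_ns)
    return LifetimeTable(tuple(orders), tuple(med), tuple(longest),
                         tuple(perc), tuple(rate))
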