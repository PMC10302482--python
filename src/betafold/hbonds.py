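"""Hydrogen-bond analytics: continuous switching score and discrete detection.

Two conventions coexist and are kept strictly separate:

* the *continuous* track scores the hydrogen-to-acceptor-oxygen distance
  with a smooth rational switching function and feeds the helicity /
  hairpin propensity scores;
* the *discrete* track applies the classic geometric criterion to the
  donor(N)-acceptor(O) heavy-atom distance, the D-H-A angle and the N-H
  covalent distance, and feeds per-frame events, occupancy maps and
  associate detection.

The switching function is the rational sigmoid

    s(d) = (1 - (d/d0)^n) / (1 - (d/d0)^m),   0 < n < m,

continuous and strictly decreasing from 1 at contact to 0 at infinity
(the removable point d = d0 takes the limit n/m).  The defaults
d0 = 0.25 nm, n = 6, m = 10 are calibrated so that the score crosses 50%
at 0.27 nm and 10% at 0.44 nm, the conventional anchor levels for amide
H...O hydrogen bonding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .trajio import (
    Conformation,
    Topology,
    Trajectory,
    minimum_image_displacement,
)

__all__ = [
    "SwitchingParams",
    "HBondCriteria",
    "HBondEvent",
    "OccupancyMap",
    "switching_score",
    "detect_hbonds",
    "occupancy_map",
]

Scope = Literal["intrachain", "interchain", "all"]


@dataclass(frozen=True)
class SwitchingParams:
    """Parameters of the rational switching function."""

    d0: float = 0.25  # nm
    n: int = 6
    m: int = 10

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if not 0 < self.n < self.m:
            raise ValueError("exponents must satisfy 0 < n < m")


def switching_score(d, params: SwitchingParams = SwitchingParams()):
    """Smooth [0, 1] degree of hydrogen-bond formation at H...O distance d (nm).

    Accepts a scalar or array; monotonically non-increasing in d, clamped to
    its maximum 1 at d = 0.
    """
    x = np.asarray(d, dtype=float)
    if np.any(x < 0):
        raise ValueError("distances must be non-negative")
    ratio = x / params.d0
    num = 1.0 - ratio ** params.n
    den = 1.0 - ratio ** params.m
    with np.errstate(invalid="ignore", over="ignore"):
        s = np.where(np.isclose(ratio, 1.0), params.n / params.m, num / den)
    # large-distance overflow of ratio**m -> 0/inf handled explicitly
    s = np.where(np.isfinite(s), s, 0.0)
    s = np.clip(s, 0.0, 1.0)
    return float(s) if np.isscalar(d) or np.ndim(d) == 0 else s


@dataclass(frozen=True)
class HBondCriteria:
    """Discrete geometric hydrogen-bond criterion.

    A donor/hydrogen/acceptor triple is a hydrogen bond when the
    donor-acceptor distance is below ``max_donor_acceptor`` (nm), the
    D-H-A angle exceeds ``min_dha_angle`` (degrees) and the hydrogen sits
    within ``max_donor_h`` (nm) of its donor.
    """

    max_donor_acceptor: float = 0.30
    min_dha_angle: float = 150.0
    max_donor_h: float = 0.12

    def __post_init__(self) -> None:
        if min(self.max_donor_acceptor, self.min_dha_angle, self.max_donor_h) <= 0:
            raise ValueError("criteria must be positive")
        if self.min_dha_angle > 180.0:
            raise ValueError("angle cannot exceed 180 degrees")


@dataclass(frozen=True)
class HBondEvent:
    """One detected hydrogen bond in one frame."""

    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    donor_residue: tuple[str, int]
    acceptor_residue: tuple[str, int]
    distance: float  # donor-acceptor, nm
    angle: float  # D-H-A, degrees


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...i,...i", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    frame: Conformation | np.ndarray,
    topology: Topology | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    scope: Scope = "all",
    box: Sequence[float] | None = None,
    frame_index: int = 0,
) -> list[HBondEvent]:
    """Apply the discrete criterion to every backbone N-H donor / O acceptor.

    ``scope`` restricts events to donor/acceptor residues on the same chain
    (``intrachain``), different chains (``interchain``) or anywhere
    (``all``).  Minimum-image distances are used when ``box`` is given.
    Topologies without donors or acceptors yield an empty list.
    """
    if isinstance(frame, Conformation):
        topology = frame.topology
        coords = frame.coords
    else:
        if topology is None:
            raise ValueError("topology required when frame is a bare array")
        coords = np.asarray(frame, dtype=float)
    donors = topology.donors()
    acceptors = topology.acceptors()
    if not donors or not acceptors:
        return []
    box_arr = None if box is None else np.asarray(box, dtype=float)
    events: list[HBondEvent] = []
    n_idx = np.array([d[0] for d in donors])
    h_idx = np.array([d[1] for d in donors])
    a_idx = np.array(acceptors)
    # covalate N-H check once per donor
    nh = np.linalg.norm(
        minimum_image_displacement(coords[n_idx], coords[h_idx], box_arr), axis=1
    )
    ok_donor = nh < criteria.max_donor_h
    for di in np.flatnonzero(ok_donor):
        ni, hi = n_idx[di], h_idx[di]
        d_chain = topology.chain_of[ni]
        dvec = minimum_image_displacement(coords[ni], coords[a_idx], box_arr)
        dist = np.linalg.norm(dvec, axis=1)
        close = dist < criteria.max_donor_acceptor
        for j in np.flatnonzero(close):
            ai = int(a_idx[j])
            if ai == ni:
                continue
            a_chain = topology.chain_of[ai]
            if scope == "intrachain" and a_chain != d_chain:
                continue
            if scope == "interchain" and a_chain == d_chain:
                continue
            hn = minimum_image_displacement(coords[hi], coords[ni], box_arr)
            ha = minimum_image_displacement(coords[hi], coords[ai], box_arr)
            ang = float(_angle_deg(hn, ha))
            if ang > criteria.min_dha_angle:
                events.append(
                    HBondEvent(
                        frame=frame_index,
                        donor=int(ni),
                        hydrogen=int(hi),
                        acceptor=ai,
                        donor_residue=(d_chain, int(topology.resids[ni])),
                        acceptor_residue=(a_chain, int(topology.resids[ai])),
                        distance=float(dist[j]),
                        angle=ang,
                    )
                )
    return events


@dataclass
class OccupancyMap:
    """Residue-residue hydrogen-bond occupancy, pooled over runs.

    ``matrix[i, j]`` is the percentage of pooled frames in which donor
    residue ``residues[i]`` is hydrogen-bonded to acceptor residue
    ``residues[j]``.
    """

    residues: tuple[tuple[str, int], ...]
    matrix: np.ndarray  # percent, donors x acceptors
    n_frames: int
    n_runs: int

    def __post_init__(self) -> None:
        if np.any(self.matrix < 0) or np.any(self.matrix > 100):
            raise ValueError("occupancies must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{c}{r}" if len(set(c for c, _ in self.residues)) > 1 else str(r)
                  for c, r in self.residues]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def occupancy_map(
    trajectories: Trajectory | Iterable[Trajectory],
    criteria: HBondCriteria = HBondCriteria(),
    scope: Scope = "all",
) -> OccupancyMap:
    """Pooled percentage of frames linking each donor/acceptor residue pair.

    Multiple runs must share a topology; their frames are pooled so the map
    is the frame-weighted average of the per-run maps.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    runs = list(trajectories)
    if not runs:
        raise ValueError("at least one trajectory required")
    top = runs[0].topology
    for t in runs[1:]:
        if t.topology != top:
            raise ValueError("all runs must share a topology")
    residues = top.residues
    index = {res: k for k, res in enumerate(residues)}
    counts = np.zeros((len(residues), len(residues)), dtype=int)
    total = 0
    for run in runs:
        for k in range(run.n_frames):
            box = None if run.box is None else run.box[k]
            seen = set()
            for ev in detect_hbonds(run.frame(k), criteria=criteria, scope=scope,
                                    box=box, frame_index=k):
                seen.add((index[ev.donor_residue], index[ev.acceptor_residue]))
            for i, j in seen:
                counts[i, j] += 1
        total += run.n_frames
    return OccupancyMap(residues, 100.0 * counts / total, total, len(runs))
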