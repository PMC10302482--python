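"""Structural comparison: least-squares superposition RMSD, Daura-style
conformational clustering and cumulative-cluster convergence curves.

Clustering follows the classic greedy procedure: compute all pairwise
superposed RMSDs on a selection (by default the CA atoms of the central
residues), repeatedly take the frame with the most neighbours within the
cutoff as a cluster centre and remove it with its neighbours.  The
cumulative count of distinct clusters visited over time gauges sampling
convergence: when the curve plateaus, no new conformations are being
discovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajio import Selection, Trajectory, central_ca_selection

__all__ = [
    "SuperpositionResult",
    "ClusterParams",
    "ClusterResult",
    "ConvergenceCurve",
    "superpose",
    "pairwise_rmsd",
    "daura_cluster",
    "convergence_curve",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition of mobile onto reference."""

    rmsd: float  # nm
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # nm; x_fit = R @ (x - mobile_mean) + translation
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        centred = coords - coords.mean(axis=0)
        return centred @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares optimal superposition over proper rotations+translations.

    ``selection`` (atom indices) restricts the fit; the returned RMSD is the
    minimum attainable over all rigid motions.  Near-collinear geometries
    are flagged degenerate (the rotation is then not unique, the RMSD still
    is).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if selection is not None:
        mob = mob[selection]
        ref = ref[selection]
    if mob.shape != ref.shape:
        raise ValueError(f"atom count mismatch: {mob.shape} vs {ref.shape}")
    if len(mob) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinearity check via the second singular value of the reference
    sv = np.linalg.svd(ref_c, compute_uv=False)
    degenerate = bool(sv[1] < 1e-10 * max(sv[0], 1.0))
    rotation, rmsd = _kabsch(mob_c, ref_c)
    return SuperpositionResult(
        rmsd=rmsd,
        rotation=rotation,
        translation=ref.mean(axis=0),
        degenerate=degenerate,
    )


def _kabsch(mob_c: np.ndarray, ref_c: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation (Kabsch, via SVD) and the attained RMSD for
    centred coordinate sets."""
    u, _s, vt = np.linalg.svd(mob_c.T @ ref_c)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    res = mob_c @ rotation.T - ref_c
    return rotation, float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))


@dataclass(frozen=True)
class ClusterParams:
    """Daura clustering parameters: RMSD cutoff (nm) and atom selection."""

    cutoff: float = 0.1
    selection: Selection | None = None  # None -> CA atoms of central residues

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ClusterResult:
    """Frame assignments of a Daura clustering."""

    labels: np.ndarray  # per-frame cluster id, 0-based in extraction order
    centers: tuple[int, ...]  # frame index of each cluster's centre
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.sizes) != len(self.labels):
            raise ValueError("cluster sizes must sum to the frame count")
        for cid, center in enumerate(self.centers):
            if self.labels[center] != cid:
                raise ValueError("each centre must belong to its own cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def to_frame(self, times: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"frame": np.arange(len(self.labels)),
                           "cluster_id": self.labels})
        if times is not None:
            df.insert(1, "time_ps", times)
        df["is_center"] = df["frame"].isin(self.centers)
        return df


def pairwise_rmsd(traj: Trajectory, selection: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between all frame pairs."""
    if selection is None:
        selection = central_ca_selection(traj.topology)
    if len(selection) == 0:
        raise ValueError("empty atom selection")
    n = traj.n_frames
    sub = traj.coords[:, selection, :]
    sub = sub - sub.mean(axis=1, keepdims=True)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _rot, rmsd = _kabsch(sub[j], sub[i])
            m[i, j] = m[j, i] = rmsd
    return m


def daura_cluster(traj: Trajectory, params: ClusterParams = ClusterParams()) -> ClusterResult:
    """Greedy neighbour-count clustering on superposed-RMSD with a cutoff.

    The unassigned frame with the most unassigned neighbours within
    ``params.cutoff`` becomes the next centre (ties to the earliest frame);
    it and its neighbours form a cluster and are removed; repeat until all
    frames are assigned.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    sel = (params.selection.indices(traj.topology) if params.selection is not None
           else central_ca_selection(traj.topology))
    dist = pairwise_rmsd(traj, sel)
    n = traj.n_frames
    neighbour = dist < params.cutoff  # includes self on the diagonal
    labels = np.full(n, -1, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cid = 0
    while remaining.any():
        counts = (neighbour & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the earliest on ties
        members = np.flatnonzero(neighbour[center] & remaining)
        labels[members] = cid
        centers.append(center)
        sizes.append(len(members))
        remaining[members] = False
        cid += 1
    return ClusterResult(labels, tuple(centers), tuple(sizes))


@dataclass
class ConvergenceCurve:
    """Cumulative number of distinct clusters visited up to each time."""

    times: np.ndarray  # ps
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("cumulative cluster count must be non-decreasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ps": self.times, "cumulative_clusters": self.counts}).to_csv(
            path, index=False
        )


def convergence_curve(result: ClusterResult, times: np.ndarray) -> ConvergenceCurve:
    """First-visit accumulation of cluster ids along the trajectory."""
    times = np.asarray(times, dtype=float)
    if len(times) != len(result.labels):
        raise ValueError("one timestamp per frame required")
    seen: set[int] = set()
    counts = np.empty(len(times), dtype=int)
    for k, lab in enumerate(result.labels):
        seen.add(int(lab))
        counts[k] = len(seen)
    return ConvergenceCurve(times, counts)
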