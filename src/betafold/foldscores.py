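"""Secondary-structure propensity scores and NOE violation analysis.

The helicity score of an N-residue chain is the mean switching score of
the N-2 hydrogen-to-carbonyl-oxygen distances d(H_i, O_{i+2}); the
hairpin-likeness score is the mean switching score over the fold's
designated hydrogen bonds.  Both are rigid-motion invariant, live in
[0, 1] and are conventionally reported as percentages.

NOE violations compare the time-averaged effective interproton distance
<r^-6>^(-1/6) with the experimental upper bound; with chemically
equivalent atoms the per-frame distance is the minimum over all
cross-group pairs, taken before the time average.  Only positive
violations breach an upper bound.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .hbonds import SwitchingParams, switching_score
from .trajio import Selection, Topology, Trajectory, minimum_image_displacement

__all__ = [
    "ScoreSeries",
    "HairpinSpec",
    "NOERestraint",
    "ViolationReport",
    "helicity_series",
    "hairpin_series",
    "noe_violations",
    "read_noe_csv",
    "score_kde",
]


@dataclass
class ScoreSeries:
    """Per-frame secondary-structure propensity score in [0, 1]."""

    times: np.ndarray  # ps
    values: np.ndarray
    kind: Literal["helicity", "hairpin"]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.values

    def mean(self) -> float:
        return float(self.values.mean())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ps": self.times, "score": self.values}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class HairpinSpec:
    """Designated (donor residue, acceptor residue) bonds of a hairpin fold.

    The default is the three-rung cross-strand ladder of a six-residue
    hairpin: 1->6, 2->5 and the middle 3->4 bond.
    """

    pairs: tuple[tuple[int, int], ...] = ((1, 6), (2, 5), (3, 4))

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("designated bonds must be distinct")
        if not self.pairs:
            raise ValueError("at least one designated bond required")


def _single_chain(topology: Topology, chain: str | None) -> str:
    chains = topology.chains
    if chain is None:
        if len(chains) > 1:
            raise ValueError("multi-chain topology: specify chain=")
        return chains[0]
    if chain not in chains:
        raise ValueError(f"no chain {chain!r} in topology")
    return chain


def _ho_distance_series(traj: Trajectory, chain: str,
                        pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """(n_frames, n_pairs) H(i)...O(j) distances, minimum image when boxed."""
    top = traj.topology
    h_idx, o_idx = [], []
    for i, j in pairs:
        h = top.atom_index(chain, i, "H")
        o = top.atom_index(chain, j, "O")
        if h is None or o is None:
            raise ValueError(f"residue pair ({i}, {j}) lacks H or O in chain {chain}")
        h_idx.append(h)
        o_idx.append(o)
    d = np.empty((traj.n_frames, len(pairs)))
    for k in range(traj.n_frames):
        box = None if traj.box is None else traj.box[k]
        vec = minimum_image_displacement(
            traj.coords[k, h_idx], traj.coords[k, o_idx], box
        )
        d[k] = np.linalg.norm(vec, axis=1)
    return d


def helicity_series(traj: Trajectory, params: SwitchingParams = SwitchingParams(),
                    chain: str | None = None) -> ScoreSeries:
    """Helical propensity per frame: mean switching score of H(i)...O(i+2).

    Requires N >= 3 residues.  Residues whose amide H or carbonyl O is
    absent from the topology (proline-like) drop out of both the sum and
    the normalization; for a complete backbone the normalization is N - 2,
    the largest possible number of such bonds.
    """
    chain = _single_chain(traj.topology, chain)
    n_res = traj.topology.n_residues(chain)
    if n_res < 3:
        raise ValueError(f"helicity undefined for N = {n_res} < 3 residues")
    top = traj.topology
    pairs = [
        (i, i + 2)
        for i in range(1, n_res - 1)
        if top.atom_index(chain, i, "H") is not None
        and top.atom_index(chain, i + 2, "O") is not None
    ]
    if not pairs:
        raise ValueError("no resolvable H(i)/O(i+2) pairs in chain")
    d = _ho_distance_series(traj, chain, pairs)
    values = switching_score(d, params).mean(axis=1)
    return ScoreSeries(traj.times.copy(), values, "helicity")


def hairpin_series(traj: Trajectory, spec: HairpinSpec = HairpinSpec(),
                   params: SwitchingParams = SwitchingParams(),
                   chain: str | None = None) -> ScoreSeries:
    """Hairpin likeness per frame: mean switching score of the designated bonds."""
    chain = _single_chain(traj.topology, chain)
    n_res = traj.topology.n_residues(chain)
    for i, j in spec.pairs:
        if not (1 <= i <= n_res and 1 <= j <= n_res):
            raise ValueError(f"designated bond ({i}, {j}) outside 1..{n_res}")
    d = _ho_distance_series(traj, chain, spec.pairs)
    values = switching_score(d, params).mean(axis=1)
    return ScoreSeries(traj.times.copy(), values, "hairpin")


# ---------------------------------------------------------------------------
# NOE violations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NOERestraint:
    """Upper-bound distance restraint between two equivalence groups.

    Groups are sets of atom indices treated as chemically equivalent; the
    per-frame distance is the minimum over all cross-group pairs.
    """

    group_i: tuple[int, ...]
    group_j: tuple[int, ...]
    r_exp: float  # nm
    label: str = ""

    def __post_init__(self) -> None:
        if not self.group_i or not self.group_j:
            raise ValueError("equivalence groups must be non-empty")
        if set(self.group_i) & set(self.group_j):
            raise ValueError("equivalence groups must be disjoint")
        if self.r_exp <= 0:
            raise ValueError("r_exp must be positive")


@dataclass
class ViolationReport:
    """Effective distances and signed violations for a restraint list."""

    restraints: list[NOERestraint]
    r_eff: np.ndarray  # <r^-6>^(-1/6), nm
    violations: np.ndarray  # r_eff - r_exp, nm
    window: tuple[float, float]  # ps

    @property
    def positive(self) -> np.ndarray:
        """Mask of restraints that breach their upper bound."""
        return self.violations > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "restraint": [r.label or f"{r.group_i}-{r.group_j}" for r in self.restraints],
                "r_exp_nm": [r.r_exp for r in self.restraints],
                "r_eff_nm": self.r_eff,
                "violation_nm": self.violations,
                "positive": self.positive,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def noe_violations(traj: Trajectory, restraints: Sequence[NOERestraint],
                   window: tuple[float, float] | None = None) -> ViolationReport:
    """r^-6 time-averaged violations of NOE upper bounds.

    ``window`` is a (start, end) time range in ps; by default the final 60%
    of the trajectory is averaged, discarding the equilibration transient.
    Per frame the minimum distance over all cross-group atom pairs is taken,
    then r^-6 is averaged over the window frames and the effective distance
    <r^-6>^(-1/6) is compared against the experimental upper bound.
    """
    if window is None:
        t0 = traj.times[0] + 0.4 * (traj.times[-1] - traj.times[0])
        window = (float(t0), float(traj.times[-1]))
    mask = (traj.times >= window[0]) & (traj.times <= window[1])
    if not np.any(mask):
        raise ValueError(f"no frames inside averaging window {window}")
    frames = np.flatnonzero(mask)
    r_eff = np.empty(len(restraints))
    for ri, r in enumerate(restraints):
        gi = np.array(r.group_i)
        gj = np.array(r.group_j)
        inv6 = np.empty(len(frames))
        for fi, k in enumerate(frames):
            box = None if traj.box is None else traj.box[k]
            diff = minimum_image_displacement(
                traj.coords[k, gi][:, None, :], traj.coords[k, gj][None, :, :], box
            )
            dmin = float(np.min(np.linalg.norm(diff, axis=-1)))
            inv6[fi] = dmin ** -6
        r_eff[ri] = float(np.mean(inv6)) ** (-1 / 6)
    violations = r_eff - np.array([r.r_exp for r in restraints])
    return ViolationReport(list(restraints), r_eff, violations, window)


def read_noe_csv(path, topology: Topology) -> list[NOERestraint]:
    """Load restraints from CSV with columns chain_i, resid_i, atom_names_i,
    chain_j, resid_j, atom_names_j, r_exp_nm (atom names pipe-separated)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            def group(suffix: str) -> tuple[int, ...]:
                chain = row[f"chain_{suffix}"].strip()
                resid = int(row[f"resid_{suffix}"])
                names = [s.strip() for s in row[f"atom_names_{suffix}"].split("|")]
                idx = []
                for nm in names:
                    i = topology.atom_index(chain, resid, nm)
                    if i is None:
                        raise ValueError(f"atom {chain}:{resid}:{nm} not in topology")
                    idx.append(i)
                return tuple(idx)

            gi, gj = group("i"), group("j")
            label = (f"{row['chain_i']}{row['resid_i']}:{row['atom_names_i']}"
                     f"-{row['chain_j']}{row['resid_j']}:{row['atom_names_j']}")
            out.append(NOERestraint(gi, gj, float(row["r_exp_nm"]), label))
    return out


def score_kde(series: ScoreSeries, grid: np.ndarray | None = None):
    """Gaussian kernel density of a score series (Scott's rule bandwidth).

    Purely presentational companion to the time series; returns (grid,
    density).
    """
    from scipy.stats import gaussian_kde

    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    values = series.values
    if np.ptp(values) < 1e-12:
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - values[0]))] = 1.0
        return grid, density
    kde = gaussian_kde(values)
    return grid, kde(grid)
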