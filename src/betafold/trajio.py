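"""Data model and I/O for peptide structures and trajectories.

Coordinates are stored in nanometres (GROMACS convention), times in
picoseconds, and residue indices are 1-based within each chain.  File I/O
(PDB / GRO / XYZ) is delegated to MDAnalysis, which uses Angstroms
internally; the conversion happens at the module boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "Conformation",
    "Selection",
    "BACKBONE_ROLES",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "minimum_image_distance",
]

#: Backbone roles of a beta-amino acid in chain order.  ``H`` is the amide
#: proton, ``CB`` the carbon bonded to the amide nitrogen and ``CA`` the
#: carbon bearing the carbonyl carbon ``C``.
BACKBONE_ROLES = ("N", "H", "CB", "CA", "C", "O", "other")

NM_PER_ANGSTROM = 0.1


class FormatError(ValueError):
    """Raised when a structure/trajectory file cannot be parsed."""


@dataclass(frozen=True)
class Topology:
    """Chains, residues and atoms with backbone-role annotation.

    All per-atom attributes are parallel arrays of length ``n_atoms``.
    ``resids`` are 1-based and contiguous within each chain.
    """

    names: tuple[str, ...]
    elements: tuple[str, ...]
    chain_of: tuple[str, ...]
    resids: tuple[int, ...]
    resnames: tuple[str, ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "chain_of", "resids", "resnames", "roles"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology attribute {attr!r} has wrong length")
        for role in self.roles:
            if role not in BACKBONE_ROLES:
                raise ValueError(f"unknown backbone role {role!r}")
        for chain in self.chains:
            rid = [r for c, r in zip(self.chain_of, self.resids) if c == chain]
            if min(rid) != 1:
                raise ValueError(f"chain {chain!r}: residue numbering must start at 1")
        # at most one amide H and one carbonyl O per residue
        seen: set[tuple[str, int, str]] = set()
        for c, r, role in zip(self.chain_of, self.resids, self.roles):
            if role in ("H", "O"):
                key = (c, r, role)
                if key in seen:
                    raise ValueError(
                        f"residue {c}:{r} declares more than one backbone {role}"
                    )
                seen.add(key)

    # -- basic queries ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def chains(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.chain_of:
            if c not in out:
                out.append(c)
        return tuple(out)

    def n_residues(self, chain: str) -> int:
        return max(r for c, r in zip(self.chain_of, self.resids) if c == chain)

    @property
    def residues(self) -> tuple[tuple[str, int], ...]:
        """(chain, resid) pairs in order of first appearance."""
        out: list[tuple[str, int]] = []
        for c, r in zip(self.chain_of, self.resids):
            if (c, r) not in out:
                out.append((c, r))
        return tuple(out)

    def atom_index(self, chain: str, resid: int, role_or_name: str) -> int | None:
        for i in range(self.n_atoms):
            if (
                self.chain_of[i] == chain
                and self.resids[i] == resid
                and (self.roles[i] == role_or_name or self.names[i] == role_or_name)
            ):
                return i
        return None

    def donors(self) -> list[tuple[int, int]]:
        """(N index, H index) pairs for every residue carrying an amide H."""
        pairs = []
        for chain, resid in self.residues:
            n = self.atom_index(chain, resid, "N")
            h = self.atom_index(chain, resid, "H")
            if n is not None and h is not None:
                pairs.append((n, h))
        return pairs

    def acceptors(self) -> list[int]:
        """Carbonyl-O indices for every residue."""
        out = []
        for chain, resid in self.residues:
            o = self.atom_index(chain, resid, "O")
            if o is not None:
                out.append(o)
        return out


@dataclass
class Conformation:
    """A single set of Cartesian coordinates (nm) over a topology."""

    topology: Topology
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} topology atoms"
            )

    def copy(self) -> "Conformation":
        return Conformation(self.topology, self.coords.copy())


@dataclass
class Trajectory:
    """Ordered frames of coordinates with timestamps and an optional box."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    times: np.ndarray  # ps
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths, nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame coordinates do not match topology atom count")
        if len(self.times) != len(self.coords):
            raise ValueError("one timestamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (len(self.coords), 3):
                raise ValueError("box must provide three lengths per frame")
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, k: int) -> Conformation:
        return Conformation(self.topology, self.coords[k])

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class Selection:
    """Predicate over atoms by chain, residue range, name and backbone role.

    ``None`` fields match everything, so ``Selection()`` selects all atoms.
    """

    chain: str | None = None
    resid_min: int | None = None
    resid_max: int | None = None
    names: tuple[str, ...] | None = None
    roles: tuple[str, ...] | None = None

    def mask(self, topology: Topology) -> np.ndarray:
        m = np.ones(topology.n_atoms, dtype=bool)
        if self.chain is not None:
            m &= np.array([c == self.chain for c in topology.chain_of])
        if self.resid_min is not None:
            m &= np.array(topology.resids) >= self.resid_min
        if self.resid_max is not None:
            m &= np.array(topology.resids) <= self.resid_max
        if self.names is not None:
            m &= np.isin(np.array(topology.names), self.names)
        if self.roles is not None:
            m &= np.isin(np.array(topology.roles), self.roles)
        return m

    def indices(self, topology: Topology) -> np.ndarray:
        return np.flatnonzero(self.mask(topology))


def central_ca_selection(topology: Topology) -> np.ndarray:
    """Indices of CA atoms excluding the first and last residue of each chain.

    This is the default atom set for conformational clustering; falls back to
    all CA atoms for chains shorter than three residues.
    """
    idx = []
    for chain in topology.chains:
        n_res = topology.n_residues(chain)
        lo, hi = (2, n_res - 1) if n_res >= 3 else (1, n_res)
        for i in range(topology.n_atoms):
            if (
                topology.chain_of[i] == chain
                and topology.roles[i] == "CA"
                and lo <= topology.resids[i] <= hi
            ):
                idx.append(i)
    return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# minimum-image distances
# ---------------------------------------------------------------------------

def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None
) -> np.ndarray:
    """Displacement b - a with each component wrapped into [-L/2, L/2]."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        if np.any(box <= 0):
            raise ValueError("box lengths must be positive")
        d = d - box * np.round(d / box)
    return d


def minimum_image_distance(
    a: Sequence[float], b: Sequence[float], box: Sequence[float] | None = None
) -> float:
    """Euclidean distance under the orthorhombic minimum-image convention.

    Without a box this is the plain Euclidean distance.
    """
    return float(np.linalg.norm(minimum_image_displacement(np.asarray(a), np.asarray(b), None if box is None else np.asarray(box))))


# ---------------------------------------------------------------------------
# role and element inference
# ---------------------------------------------------------------------------

_ROLE_NAMES = {"N": "N", "H": "H", "HN": "H", "CB": "CB", "CA": "CA", "C": "C", "O": "O"}


def infer_role(atom_name: str) -> str:
    return _ROLE_NAMES.get(atom_name.strip().upper(), "other")


def _infer_element(name: str) -> str:
    s = name.strip()
    for ch in s:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _format_of(path: str | Path, format: str | None) -> str:
    if format is not None:
        fmt = format.upper()
    else:
        fmt = Path(path).suffix.lstrip(".").upper()
    if fmt not in ("PDB", "GRO", "XYZ"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    return fmt


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _universe(path: str | Path, **kwargs):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path), **kwargs)
        except (ValueError, EOFError, OSError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc


def _topology_from_universe(u, fmt: str) -> Topology:
    n = len(u.atoms)
    names = tuple(str(a.name) for a in u.atoms)
    try:
        elements = tuple(str(e).upper() if str(e).strip() else _infer_element(nm)
                         for e, nm in zip(u.atoms.elements, names))
    except Exception:
        elements = tuple(_infer_element(nm) for nm in names)
    resids_raw = [int(a.resid) for a in u.atoms]
    try:
        resnames = tuple(str(a.resname) for a in u.atoms)
    except Exception:
        resnames = tuple("UNK" for _ in range(n))
    if fmt == "PDB":
        try:
            chain_raw = [str(c) if str(c).strip() else "A" for c in u.atoms.chainIDs]
        except Exception:
            chain_raw = [str(a.segid) if str(a.segid).strip() else "A" for a in u.atoms]
    else:
        # GRO carries no chain identifiers: start a new chain whenever the
        # residue number decreases.
        chain_raw = []
        label, prev = 0, None
        for r in resids_raw:
            if prev is not None and r < prev:
                label += 1
            chain_raw.append(_chain_label(label))
            prev = r
    # renumber residues 1-based per chain preserving order
    resids: list[int] = []
    counters: dict[str, dict[int, int]] = {}
    for c, r in zip(chain_raw, resids_raw):
        tbl = counters.setdefault(c, {})
        if r not in tbl:
            tbl[r] = len(tbl) + 1
        resids.append(tbl[r])
    roles = tuple(infer_role(nm) for nm in names)
    return Topology(names, elements, tuple(chain_raw), tuple(resids), resnames, roles)


def _chain_label(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    label = ""
    i0 = i
    while True:
        label = letters[i0 % 26] + label
        i0 = i0 // 26 - 1
        if i0 < 0:
            break
    return label


def read_structure(
    path: str | Path,
    format: str | None = None,
    topology: Topology | None = None,
) -> Conformation:
    """Read a single-model PDB/GRO/XYZ file into a :class:`Conformation`.

    XYZ files carry no residue information, so a ``topology`` must be given
    for them; for PDB/GRO it overrides the one inferred from the file.
    """
    fmt = _format_of(path, format)
    u = _universe(path, format=fmt)
    if topology is None:
        if fmt == "XYZ":
            raise ValueError("XYZ files carry no topology; pass topology=...")
        topology = _topology_from_universe(u, fmt)
    if len(u.atoms) != topology.n_atoms:
        raise FormatError(
            f"{path}: {len(u.atoms)} atoms in file, topology has {topology.n_atoms}"
        )
    coords = u.atoms.positions.astype(float) * NM_PER_ANGSTROM
    return Conformation(topology, coords)


def _scan_pdb_models(path: str | Path) -> list[int]:
    """Number of ATOM/HETATM records in each MODEL block (whole file if none)."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if in_model or (not counts and current):
        counts.append(current)
    return counts


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str | None = None,
    dt: float = 100.0,
    times: Sequence[float] | None = None,
) -> Trajectory:
    """Read a multi-model PDB or concatenated-XYZ trajectory.

    Timestamps are taken from ``times`` when given, otherwise synthesized as
    ``k * dt`` (ps).  A frame whose atom count does not match the topology
    raises :class:`FormatError` naming that frame index.
    """
    fmt = _format_of(path, format)
    if fmt == "PDB":
        counts = _scan_pdb_models(path)
        for k, c in enumerate(counts):
            if c != topology.n_atoms:
                raise FormatError(
                    f"{path}: frame {k} has {c} atoms, expected {topology.n_atoms}"
                )
    u = _universe(path, format=fmt)
    if len(u.atoms) != topology.n_atoms:
        raise FormatError(
            f"{path}: frame 0 has {len(u.atoms)} atoms, expected {topology.n_atoms}"
        )
    frames = []
    boxes = []
    try:
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float) * NM_PER_ANGSTROM)
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                boxes.append(np.asarray(ts.dimensions[:3], dtype=float) * NM_PER_ANGSTROM)
    except (ValueError, EOFError, OSError) as exc:
        raise FormatError(f"{path}: frame {len(frames)} unreadable: {exc}") from exc
    coords = np.stack(frames)
    if times is None:
        times = np.arange(len(frames)) * float(dt)
    box = np.stack(boxes) if len(boxes) == len(frames) else None
    return Trajectory(topology, coords, np.asarray(times, dtype=float), box)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _build_universe(topology: Topology, n_frames: int = 1):
    import MDAnalysis as mda

    n = topology.n_atoms
    chains = topology.chains
    resid_keys = list(topology.residues)
    n_res = len(resid_keys)
    atom_res = [resid_keys.index((c, r)) for c, r in zip(topology.chain_of, topology.resids)]
    seg_of_res = [chains.index(c) for c, _ in resid_keys]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=n_res,
            n_segments=len(chains),
            atom_resindex=np.array(atom_res),
            residue_segindex=np.array(seg_of_res),
            trajectory=True,
            n_frames=n_frames,
        )
        u.add_TopologyAttr("names", list(topology.names))
        u.add_TopologyAttr("elements", list(topology.elements))
        u.add_TopologyAttr("resids", [r for _, r in resid_keys])
        first_atom = [next(i for i in range(n) if (topology.chain_of[i], topology.resids[i]) == key) for key in resid_keys]
        u.add_TopologyAttr("resnames", [topology.resnames[i] for i in first_atom])
        u.add_TopologyAttr("segids", list(chains))
        u.add_TopologyAttr("chainIDs", [c[:1] for c in topology.chain_of])
        u.add_TopologyAttr("record_types", ["ATOM"] * n)
        u.add_TopologyAttr("occupancies", [1.0] * n)
        u.add_TopologyAttr("tempfactors", [0.0] * n)
        u.add_TopologyAttr("altLocs", [""] * n)
        u.add_TopologyAttr("icodes", [""] * (n_res))
    return u


def write_structure(
    conf: Conformation,
    path: str | Path,
    format: str | None = None,
    box: Sequence[float] | None = None,
) -> None:
    """Write a conformation to PDB, GRO or XYZ (coordinates nm -> file units)."""
    fmt = _format_of(path, format)
    u = _build_universe(conf.topology)
    u.atoms.positions = conf.coords / NM_PER_ANGSTROM
    if box is not None:
        u.dimensions = [box[0] / NM_PER_ANGSTROM, box[1] / NM_PER_ANGSTROM,
                        box[2] / NM_PER_ANGSTROM, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write a trajectory as multi-model PDB or concatenated XYZ."""
    import MDAnalysis as mda

    fmt = _format_of(path, format)
    if fmt == "GRO":
        raise ValueError("GRO holds a single snapshot; use write_structure per frame")
    u = _build_universe(traj.topology, n_frames=traj.n_frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, multiframe=True) as w:
            for k in range(traj.n_frames):
                u.trajectory[k]
                u.atoms.positions = traj.coords[k] / NM_PER_ANGSTROM
                if traj.box is not None:
                    u.dimensions = list(traj.box[k] / NM_PER_ANGSTROM) + [90.0, 90.0, 90.0]
                w.write(u.atoms)
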