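"""Synthetic beta-peptide structures and pseudo-trajectories.

A beta-amino acid contributes the backbone atoms N, H, CB, CA, C, O; the
chain torsions are phi (about N-CB), theta (about CB-CA), psi (about CA-C)
and the peptide bond omega (about C-N, 180 deg when trans).  Chains are
built by sequential internal-coordinate (NeRF-style) placement from
residue templates holding standard amide bond lengths and angles.

The torsion presets (``extended``, ``helix314``, ``helix2512``,
``hairpin``) are frozen configuration data.  They were calibrated once,
against the hydrogen-bond pattern that defines each fold (H(i)...O(i+2)
contacts for the 14-helix, H(i)...O(i-3) for the 12-helix, the
(1,6)/(2,5)/(3,4) ladder for the hairpin), so that the designated
hydrogen bonds are tightly formed in the built geometry; the presets are
validated functionally by those distances rather than by angle values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .trajio import Conformation, Topology, Trajectory, _chain_label

__all__ = [
    "ResidueTemplate",
    "TorsionSet",
    "SynthesisPlan",
    "TEMPLATES",
    "PRESETS",
    "preset_torsions",
    "build_backbone",
    "build_preset_chain",
    "measure_torsions",
    "dihedral",
    "synthesize_trajectory",
    "assemble_multichain",
]


@dataclass(frozen=True)
class ResidueTemplate:
    """Backbone geometry of one beta-amino acid.

    ``backbone_atoms`` lists (name, element, bond length to the bonded
    predecessor in nm, bond angle at the predecessor in degrees) in the
    order N, H, CB, CA, C, O.  ``ring_theta`` clamps the CB-CA torsion for
    cyclic residues (ACPC/ACHC-like) whose ring fixes it.
    """

    name: str
    backbone_atoms: tuple[tuple[str, str, float, float], ...]
    has_amide_h: bool = True
    ring_theta: float | None = None

    def __post_init__(self) -> None:
        for nm, el, bond, angle in self.backbone_atoms:
            if not 0.05 < bond < 0.25:
                raise ValueError(f"{self.name}/{nm}: bond length {bond} nm out of range")
            if not 60.0 < angle < 180.0:
                raise ValueError(f"{self.name}/{nm}: bond angle {angle} out of range")
        order = tuple(a[0] for a in self.backbone_atoms)
        expected = ("N", "H", "CB", "CA", "C", "O") if self.has_amide_h else ("N", "CB", "CA", "C", "O")
        if order != expected:
            raise ValueError(f"{self.name}: backbone atom order must be {expected}")

    def geometry(self, name: str) -> tuple[float, float]:
        for nm, _el, bond, angle in self.backbone_atoms:
            if nm == name:
                return bond, angle
        raise KeyError(name)


# Standard amide geometry; bond angles are taken at the placement
# predecessor as used by the NeRF chain below.
_BB = (
    ("N", "N", 0.133, 116.6),   # C(i-1)-N,   angle CA(i-1)-C(i-1)-N
    ("H", "H", 0.101, 119.0),   # N-H,        angle C(i-1)-N-H
    ("CB", "C", 0.146, 121.7),  # N-CB,       angle C(i-1)-N-CB
    ("CA", "C", 0.153, 111.5),  # CB-CA,      angle N-CB-CA
    ("C", "C", 0.152, 110.5),   # CA-C,       angle CB-CA-C
    ("O", "O", 0.123, 120.5),   # C-O,        angle CA-C-O
)

TEMPLATES: dict[str, ResidueTemplate] = {
    # generic acyclic beta3-residue
    "B3A": ResidueTemplate("B3A", _BB),
    # trans-2-aminocyclopentanecarboxylic acid: ring clamps theta
    "ACP": ResidueTemplate("ACP", _BB, ring_theta=90.0),
    # trans-2-aminocyclohexanecarboxylic acid
    "ACH": ResidueTemplate("ACH", _BB, ring_theta=55.0),
}


@dataclass(frozen=True)
class TorsionSet:
    """Backbone torsions of one residue, degrees in [-180, 180]."""

    phi: float
    theta: float
    psi: float
    omega: float = 180.0

    def __post_init__(self) -> None:
        for nm in ("phi", "theta", "psi", "omega"):
            v = getattr(self, nm)
            if not -180.0 <= v <= 180.0:
                raise ValueError(f"{nm} = {v} outside [-180, 180] degrees")


@dataclass(frozen=True)
class SynthesisPlan:
    """Recipe for a synthetic pseudo-trajectory between two conformations."""

    n_frames: int = 1000
    dt: float = 100.0  # ps
    noise_sigma: float = 0.01  # nm, i.i.d. Gaussian per atom coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


# Torsion presets (phi, theta, psi) in degrees.  Helices use one torsion
# triple for every residue; the hairpin preset is a per-residue list for a
# six-residue chain (two strands joined by a central turn).  See the module
# docstring for how these values were calibrated.
PRESETS: dict[str, object] = {
    "extended": TorsionSet(phi=180.0, theta=180.0, psi=180.0),
    "helix314": TorsionSet(phi=54.4, theta=76.5, psi=31.7),
    "helix2512": TorsionSet(phi=-98.1, theta=89.7, psi=-95.6),
    "hairpin": (
        TorsionSet(phi=-93.0, theta=-135.9, psi=38.1),
        TorsionSet(phi=-21.3, theta=-89.2, psi=-18.3),
        TorsionSet(phi=-117.4, theta=-77.4, psi=79.0),
        TorsionSet(phi=117.4, theta=35.6, psi=126.4),
        TorsionSet(phi=97.3, theta=1.8, psi=90.6),
        TorsionSet(phi=48.4, theta=-108.6, psi=-125.2),
    ),
}


def preset_torsions(name: str, n_residues: int) -> list[TorsionSet]:
    """Expand a preset into one TorsionSet per residue."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    if isinstance(preset, TorsionSet):
        return [preset] * n_residues
    seq = list(preset)
    if n_residues <= len(seq):
        return seq[:n_residues]
    return seq + [seq[-1]] * (n_residues - len(seq))


# ---------------------------------------------------------------------------
# internal-coordinate placement
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D bonded to c with dihedral a-b-c-D."""
    ang = np.deg2rad(180.0 - angle)
    tor = np.deg2rad(dihedral_deg)
    d_local = bond * np.array(
        [np.cos(ang), np.cos(tor) * np.sin(ang), np.sin(tor) * np.sin(ang)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC sign convention),
    atan2 formulation."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def _chain_topology(sequence: Sequence[str], chain: str = "A") -> Topology:
    names, elements, chain_of, resids, resnames, roles = [], [], [], [], [], []
    for i, code in enumerate(sequence, start=1):
        tpl = TEMPLATES[code]
        for nm, el, _b, _a in tpl.backbone_atoms:
            names.append(nm)
            elements.append(el)
            chain_of.append(chain)
            resids.append(i)
            resnames.append(code)
            roles.append(nm)
    return Topology(tuple(names), tuple(elements), tuple(chain_of),
                    tuple(resids), tuple(resnames), tuple(roles))


def build_backbone(sequence: Sequence[str], torsions: Sequence[TorsionSet],
                   chain: str = "A") -> Conformation:
    """Build a beta-peptide backbone from residue codes and torsions.

    One :class:`TorsionSet` is required per residue.  Cyclic residues have
    their theta clamped to the template's ring value.  Recomputing the
    torsions from the returned coordinates reproduces the inputs.
    """
    if len(sequence) == 0:
        raise ValueError("sequence must be non-empty")
    if len(torsions) != len(sequence):
        raise ValueError(
            f"{len(sequence)} residues but {len(torsions)} torsion sets"
        )
    for code in sequence:
        if code not in TEMPLATES:
            raise KeyError(f"no residue template for code {code!r}")
    tors = [
        replace(t, theta=TEMPLATES[code].ring_theta)
        if TEMPLATES[code].ring_theta is not None else t
        for code, t in zip(sequence, torsions)
    ]
    topology = _chain_topology(sequence, chain)
    pos: dict[tuple[int, str], np.ndarray] = {}

    def geom(i: int, name: str) -> tuple[float, float]:
        return TEMPLATES[sequence[i - 1]].geometry(name)

    for i, t in enumerate(tors, start=1):
        if i == 1:
            b_ncb, _ = geom(1, "CB")
            b_cbca, a_cbca = geom(1, "CA")
            pos[(1, "N")] = np.zeros(3)
            pos[(1, "CB")] = np.array([b_ncb, 0.0, 0.0])
            ang = np.deg2rad(180.0 - a_cbca)
            pos[(1, "CA")] = pos[(1, "CB")] + b_cbca * np.array(
                [np.cos(ang), np.sin(ang), 0.0]
            )
            # no preceding carbonyl exists, so the amide H of residue 1 is
            # placed in the CA-CB-N frame at the geometry an interior
            # residue would have for the same phi (trans peptide plane)
            b_h, a_h = geom(1, "H")
            _b_cb, a_cb = geom(1, "CB")
            pos[(1, "H")] = place_atom(pos[(1, "CA")], pos[(1, "CB")], pos[(1, "N")],
                                       b_h, 360.0 - a_h - a_cb, t.phi + 180.0)
        else:
            b_n, a_n = geom(i, "N")
            pos[(i, "N")] = place_atom(pos[(i - 1, "CB")], pos[(i - 1, "CA")],
                                       pos[(i - 1, "C")], b_n, a_n, tors[i - 2].psi)
            b_cb, a_cb = geom(i, "CB")
            pos[(i, "CB")] = place_atom(pos[(i - 1, "CA")], pos[(i - 1, "C")],
                                        pos[(i, "N")], b_cb, a_cb, t.omega)
            b_h, a_h = geom(i, "H")
            pos[(i, "H")] = place_atom(pos[(i - 1, "CA")], pos[(i - 1, "C")],
                                       pos[(i, "N")], b_h, a_h, t.omega - 180.0)
            b_ca, a_ca = geom(i, "CA")
            pos[(i, "CA")] = place_atom(pos[(i - 1, "C")], pos[(i, "N")],
                                        pos[(i, "CB")], b_ca, a_ca, t.phi)
        b_c, a_c = geom(i, "C")
        pos[(i, "C")] = place_atom(pos[(i, "N")], pos[(i, "CB")], pos[(i, "CA")],
                                   b_c, a_c, t.theta)
        b_o, a_o = geom(i, "O")
        psi_o = t.psi + 180.0
        pos[(i, "O")] = place_atom(pos[(i, "CB")], pos[(i, "CA")], pos[(i, "C")],
                                   b_o, a_o, psi_o)

    coords = np.array([
        pos[(resid, name)]
        for resid, name in zip(topology.resids, topology.names)
    ])
    return Conformation(topology, coords)


def build_preset_chain(preset: str, n_residues: int, residue: str = "B3A",
                       chain: str = "A") -> Conformation:
    """Convenience: homo-chain of ``n_residues`` in a named preset fold."""
    return build_backbone([residue] * n_residues,
                          preset_torsions(preset, n_residues), chain=chain)


def measure_torsions(conf: Conformation, chain: str | None = None) -> list[TorsionSet]:
    """Recover per-residue torsions from coordinates (inverse of the builder).

    Torsions that are undefined at chain ends (phi/omega of residue 1, psi
    of the last residue) are reported as the builder's defaults so that a
    measure -> rebuild round trip is idempotent.
    """
    top = conf.topology
    chains = top.chains
    if chain is None:
        if len(chains) > 1:
            raise ValueError("multi-chain conformation: specify chain=")
        chain = chains[0]
    n_res = top.n_residues(chain)

    def xyz(resid: int, role: str) -> np.ndarray:
        idx = top.atom_index(chain, resid, role)
        if idx is None:
            raise ValueError(f"residue {chain}:{resid} lacks backbone atom {role}")
        return conf.coords[idx]

    out = []
    for i in range(1, n_res + 1):
        theta = dihedral(xyz(i, "N"), xyz(i, "CB"), xyz(i, "CA"), xyz(i, "C"))
        if i < n_res:
            psi = dihedral(xyz(i, "CB"), xyz(i, "CA"), xyz(i, "C"), xyz(i + 1, "N"))
        else:
            # the C-terminal psi only steers the carbonyl O; recover it there
            psi = dihedral(xyz(i, "CB"), xyz(i, "CA"), xyz(i, "C"), xyz(i, "O")) - 180.0
            if psi < -180.0:
                psi += 360.0
        if i > 1:
            phi = dihedral(xyz(i - 1, "C"), xyz(i, "N"), xyz(i, "CB"), xyz(i, "CA"))
            omega = dihedral(xyz(i - 1, "CA"), xyz(i - 1, "C"), xyz(i, "N"), xyz(i, "CB"))
        else:
            omega = 180.0
            try:
                # recover phi of residue 1 from the amide-H placement
                phi = dihedral(xyz(1, "CA"), xyz(1, "CB"), xyz(1, "N"), xyz(1, "H")) + 180.0
                if phi > 180.0:
                    phi -= 360.0
            except ValueError:
                phi = 180.0
        out.append(TorsionSet(phi=phi, theta=theta, psi=psi, omega=omega))
    return out


# ---------------------------------------------------------------------------
# trajectory synthesis
# ---------------------------------------------------------------------------

def _interp_angle(a: float, b: float, f: float) -> float:
    """Linear interpolation along the shorter arc, result in [-180, 180]."""
    delta = (b - a + 180.0) % 360.0 - 180.0
    v = a + f * delta
    v = (v + 180.0) % 360.0 - 180.0
    return -180.0 if v == 180.0 and (a < 0 or b < 0) else v


def _chain_state(conf: Conformation, chain: str):
    """Torsions + rigid placement + Cartesian residual of one chain."""
    top = conf.topology
    idx = [i for i in range(top.n_atoms) if top.chain_of[i] == chain]
    seq = []
    for i in idx:
        if top.roles[i] == "N":
            seq.append(top.resnames[i])
    tors = measure_torsions(
        Conformation(_chain_topology(seq, chain), conf.coords[idx]), chain
    )
    canon = build_backbone(seq, tors, chain=chain).coords
    actual = conf.coords[idx]
    c_can = canon.mean(axis=0)
    c_act = actual.mean(axis=0)
    rot, _ = Rotation.align_vectors(actual - c_act, canon - c_can)
    fitted = rot.apply(canon - c_can) + c_act
    residual = actual - fitted
    return idx, seq, tors, rot, c_can, c_act, residual


def synthesize_trajectory(conf_start: Conformation, conf_end: Conformation,
                          plan: SynthesisPlan) -> Trajectory:
    """Interpolate internal coordinates start -> end and add Gaussian noise.

    Frame k (k = 0..n_frames-1) rebuilds every chain at torsions linearly
    interpolated along the shorter arc, carries each chain's rigid placement
    by quaternion slerp + linear translation, blends any Cartesian residual
    of the endpoints, and finally adds i.i.d. Gaussian displacements of
    scale ``noise_sigma`` drawn from a PRNG seeded with ``plan.seed``.
    Identical plans give identical trajectories.
    """
    if conf_start.topology != conf_end.topology:
        raise ValueError("start and end conformations must share a topology")
    top = conf_start.topology
    rng = np.random.default_rng(plan.seed)
    n = plan.n_frames
    fracs = np.zeros(1) if n == 1 else np.arange(n) / (n - 1)

    states = []
    for chain in top.chains:
        s = _chain_state(conf_start, chain)
        e = _chain_state(conf_end, chain)
        key_rots = Rotation.concatenate([s[3], e[3]])
        slerp = Slerp([0.0, 1.0], key_rots)
        states.append((chain, s, e, slerp))

    coords = np.empty((n, top.n_atoms, 3))
    for k, f in enumerate(fracs):
        for chain, s, e, slerp in states:
            idx, seq, t0, _r0, c_can0, c_act0, res0 = s
            _idx, _seq, t1, _r1, c_can1, c_act1, res1 = e
            tors = [
                TorsionSet(
                    phi=_interp_angle(a.phi, b.phi, f),
                    theta=_interp_angle(a.theta, b.theta, f),
                    psi=_interp_angle(a.psi, b.psi, f),
                    omega=_interp_angle(a.omega, b.omega, f),
                )
                for a, b in zip(t0, t1)
            ]
            canon = build_backbone(seq, tors, chain=chain).coords
            rot = slerp([f])[0]
            c_can = (1 - f) * c_can0 + f * c_can1
            c_act = (1 - f) * c_act0 + f * c_act1
            residual = (1 - f) * res0 + f * res1
            coords[k, idx] = rot.apply(canon - c_can) + c_act + residual
    if plan.noise_sigma > 0:
        coords += rng.normal(0.0, plan.noise_sigma, size=coords.shape)
    times = np.arange(n) * plan.dt
    return Trajectory(top, coords, times)


# ---------------------------------------------------------------------------
# multichain assembly
# ---------------------------------------------------------------------------

def assemble_multichain(conf: Conformation, n_copies: int = 8,
                        spacing: float = 3.0, seed: int = 0) -> Conformation:
    """Place randomly rotated copies of a chain on a cubic grid.

    ``n_copies`` must be a perfect cube (8 gives the 2 x 2 x 2 arrangement);
    each copy receives a uniformly random proper rotation about its centroid
    and distinct chain identifiers A, B, C, ...
    """
    side = round(n_copies ** (1 / 3))
    if side ** 3 != n_copies:
        raise ValueError(f"n_copies = {n_copies} is not a perfect cube")
    top = conf.topology
    if len(top.chains) != 1:
        raise ValueError("assemble_multichain expects a single-chain conformation")
    centroid = conf.coords.mean(axis=0)
    diameter = float(np.max(np.linalg.norm(conf.coords - centroid, axis=1))) * 2
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    names, elements, chain_of, resids, resnames, roles = [], [], [], [], [], []
    blocks = []
    copy = 0
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                rot = Rotation.random(rng=rng)
                offset = spacing * np.array([ix, iy, iz], dtype=float)
                blocks.append(rot.apply(conf.coords - centroid) + offset)
                label = _chain_label(copy)
                for i in range(top.n_atoms):
                    names.append(top.names[i])
                    elements.append(top.elements[i])
                    chain_of.append(label)
                    resids.append(top.resids[i])
                    resnames.append(top.resnames[i])
                    roles.append(top.roles[i])
                copy += 1
    new_top = Topology(tuple(names), tuple(elements), tuple(chain_of),
                       tuple(resids), tuple(resnames), tuple(roles))
    out = Conformation(new_top, np.concatenate(blocks, axis=0))
    if diameter >= spacing:
        # grid cells overlap; caller asked for a tight packing deliberately
        pass
    return out
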