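import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betafold import trajio
from betafold.hbonds import (
    HBondCriteria,
    SwitchingParams,
    detect_hbonds,
    occupancy_map,
    switching_score,
)
from betafold.structures import SynthesisPlan, build_preset_chain, synthesize_trajectory
from betafold.trajio import Conformation, Topology, Trajectory

from conftest import random_frame


def brute_force_hbonds(conf, criteria=HBondCriteria(), scope="all", box=None):
    """Literal triple-loop transcription of the discrete criterion."""
    top = conf.topology
    found = []
    for donor_chain, donor_resid in top.residues:
        n = top.atom_index(donor_chain, donor_resid, "N")
        h = top.atom_index(donor_chain, donor_resid, "H")
        if n is None or h is None:
            continue
        for acc_chain, acc_resid in top.residues:
            o = top.atom_index(acc_chain, acc_resid, "O")
            if o is None or o == n:
                continue
            if scope == "intrachain" and donor_chain != acc_chain:
                continue
            if scope == "interchain" and donor_chain == acc_chain:
                continue
            def dist(i, j):
                return trajio.minimum_image_distance(conf.coords[i], conf.coords[j], box)
            if dist(n, h) >= criteria.max_donor_h:
                continue
            if dist(n, o) >= criteria.max_donor_acceptor:
                continue
            v1 = trajio.minimum_image_displacement(conf.coords[h], conf.coords[n],
                                                   None if box is None else np.asarray(box))
            v2 = trajio.minimum_image_displacement(conf.coords[h], conf.coords[o],
                                                   None if box is None else np.asarray(box))
            ang = np.degrees(np.arccos(np.clip(
                v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
            if ang > criteria.min_dha_angle:
                found.append(((donor_chain, donor_resid), (acc_chain, acc_resid)))
    return sorted(found)


class TestSwitchingScore:
    def test_anchor_values(self):
        # conventional calibration: ~50% at 0.27 nm, ~10% at 0.44 nm
        assert switching_score(0.27) == pytest.approx(0.50, abs=0.01)
        assert switching_score(0.44) == pytest.approx(0.10, abs=0.01)

    def test_anchor_crossings_at_printed_precision(self):
        from scipy.optimize import brentq

        d50 = brentq(lambda d: switching_score(d) - 0.5, 0.2, 0.35)
        d10 = brentq(lambda d: switching_score(d) - 0.1, 0.35, 0.6)
        assert round(d50, 2) == 0.27
        assert round(d10, 2) == 0.44

    def test_long_distance_limit(self):
        assert switching_score(5.0) < 1e-3

    def test_contact_plateau_is_one(self):
        assert switching_score(0.0) == 1.0

    @given(st.floats(0.0, 2.0), st.floats(0.0, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        s_lo, s_hi = switching_score(lo), switching_score(hi)
        assert 0.0 <= s_hi <= s_lo <= 1.0

    def test_continuous_across_d0(self):
        params = SwitchingParams()
        eps = 1e-9
        below = switching_score(params.d0 - eps, params)
        at = switching_score(params.d0, params)
        above = switching_score(params.d0 + eps, params)
        assert below == pytest.approx(at, abs=1e-6)
        assert above == pytest.approx(at, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SwitchingParams(d0=-1)
        with pytest.raises(ValueError):
            SwitchingParams(n=10, m=6)


def _triple_conformation(n_o_dist, angle_deg, n_h_dist=0.10):
    """One donor residue and one acceptor residue with controlled geometry."""
    names = ("N", "H", "CB", "CA", "C", "O")
    top = Topology(
        names=names * 2,
        elements=("N", "H", "C", "C", "C", "O") * 2,
        chain_of=("A",) * 6 + ("B",) * 6,
        resids=(1,) * 6 + (1,) * 6,
        resnames=("B3A",) * 12,
        roles=names * 2,
    )
    coords = np.zeros((12, 3))
    # chain A: donor N-H along +x, its own C=O parked far away
    coords[0] = [0.0, 0.0, 0.0]  # donor N
    coords[1] = [n_h_dist, 0.0, 0.0]  # H along +x
    coords[2] = [0.0, -1.0, 0.0]
    coords[3] = [0.3, -1.0, 0.0]
    coords[4] = [0.6, -1.0, 0.0]
    coords[5] = [0.9, -1.0, 0.0]  # A's carbonyl O, 1.35 nm from its N
    # chain B: its donor parked far away, its carbonyl O is the acceptor
    coords[6] = [5.0, 5.0, 5.0]  # B's N
    coords[7] = [5.1, 5.0, 5.0]  # B's H
    coords[8] = [5.0, 6.0, 5.0]
    coords[9] = [5.3, 6.0, 5.0]
    coords[10] = [5.6, 6.0, 5.0]
    if angle_deg == 180.0:
        coords[11] = [n_o_dist, 0.0, 0.0]  # collinear N-H...O
    else:
        # direction from H making the requested D-H-A angle with H->N (-x)
        theta = np.deg2rad(180.0 - angle_deg)
        coords[11] = coords[1] + 0.19 * np.array([np.cos(theta), np.sin(theta), 0.0])
    return Conformation(top, coords)


class TestDetectHbonds:
    def test_collinear_geometry_yields_one_event(self):
        conf = _triple_conformation(n_o_dist=0.29, angle_deg=180.0)
        events = detect_hbonds(conf)
        assert len(events) == 1
        ev = events[0]
        assert ev.donor_residue == ("A", 1)
        assert ev.acceptor_residue == ("B", 1)
        assert ev.distance == pytest.approx(0.29)
        assert ev.angle == pytest.approx(180.0)

    def test_bent_geometry_rejected(self):
        conf = _triple_conformation(n_o_dist=0.29, angle_deg=120.0)
        assert detect_hbonds(conf) == []

    def test_loose_hydrogen_rejected(self):
        conf = _triple_conformation(n_o_dist=0.29, angle_deg=180.0, n_h_dist=0.13)
        assert detect_hbonds(conf) == []

    def test_scope_filters_chains(self):
        conf = _triple_conformation(n_o_dist=0.29, angle_deg=180.0)
        assert len(detect_hbonds(conf, scope="interchain")) == 1
        assert detect_hbonds(conf, scope="intrachain") == []

    @pytest.mark.parametrize("scope", ["all", "intrachain", "interchain"])
    def test_matches_brute_force_on_random_frames(self, scope):
        rng = np.random.default_rng(123)
        for _ in range(60):
            conf = random_frame(rng, n_residues=8, n_chains=2, box_side=1.0)
            got = sorted((e.donor_residue, e.acceptor_residue)
                         for e in detect_hbonds(conf, scope=scope))
            assert got == brute_force_hbonds(conf, scope=scope)

    def test_matches_brute_force_under_periodic_box(self):
        rng = np.random.default_rng(9)
        box = np.array([1.0, 1.0, 1.0])
        for _ in range(30):
            conf = random_frame(rng, n_residues=8, n_chains=2, box_side=1.0)
            got = sorted((e.donor_residue, e.acceptor_residue)
                         for e in detect_hbonds(conf, box=box))
            assert got == brute_force_hbonds(conf, box=box)

    def test_agrees_with_mdanalysis_hbond_analysis(self, tmp_path, helix_traj):
        """Cross-check counts against the independent MDAnalysis implementation."""
        import MDAnalysis as mda
        from MDAnalysis.analysis.hydrogenbonds import HydrogenBondAnalysis

        sub = Trajectory(helix_traj.topology, helix_traj.coords[:20], helix_traj.times[:20])
        path = tmp_path / "helix.pdb"
        trajio.write_trajectory(sub, path)
        u = mda.Universe(str(path))
        hb = HydrogenBondAnalysis(
            universe=u, donors_sel="name N", hydrogens_sel="name H",
            acceptors_sel="name O", d_a_cutoff=3.0, d_h_a_angle_cutoff=150.0,
            d_h_cutoff=1.2,
        )
        hb.run()
        ours = sum(
            len(detect_hbonds(sub.frame(k), frame_index=k)) for k in range(sub.n_frames)
        )
        assert len(hb.results.hbonds) == ours


class TestOccupancyMap:
    def test_persistent_bond_scores_100(self, helix_chain):
        plan = SynthesisPlan(n_frames=10, dt=1.0, noise_sigma=0.0, seed=0)
        sub = synthesize_trajectory(helix_chain, helix_chain, plan)
        occ = occupancy_map(sub, scope="intrachain")
        idx = {res: k for k, res in enumerate(occ.residues)}
        assert occ.matrix[idx[("A", 2)], idx[("A", 4)]] == pytest.approx(100.0)
        assert occ.matrix[idx[("A", 2)], idx[("A", 3)]] == pytest.approx(0.0)

    def test_two_runs_pool_to_half(self, helix_chain, extended_chain):
        plan = SynthesisPlan(n_frames=10, dt=1.0, noise_sigma=0.0, seed=0)
        folded = synthesize_trajectory(helix_chain, helix_chain, plan)
        unfolded = synthesize_trajectory(extended_chain, extended_chain, plan)
        occ = occupancy_map([folded, unfolded], scope="intrachain")
        assert occ.n_frames == 20
        assert occ.n_runs == 2
        idx = {res: k for k, res in enumerate(occ.residues)}
        assert occ.matrix[idx[("A", 2)], idx[("A", 4)]] == pytest.approx(50.0)

    def test_ideal_helix_fingerprint_on_i_plus_2_diagonal(self, helix_traj):
        occ = occupancy_map(helix_traj, scope="intrachain")
        idx = {res: k for k, res in enumerate(occ.residues)}
        strong = np.argwhere(occ.matrix >= 10.0)
        assert len(strong) > 0
        for i, j in strong:
            assert occ.residues[j][1] - occ.residues[i][1] == 2

    def test_concatenation_equals_frame_weighted_average(self, helix_chain, extended_chain):
        plan_a = SynthesisPlan(n_frames=6, dt=1.0, noise_sigma=0.01, seed=1)
        plan_b = SynthesisPlan(n_frames=14, dt=1.0, noise_sigma=0.01, seed=2)
        a = synthesize_trajectory(helix_chain, helix_chain, plan_a)
        b = synthesize_trajectory(helix_chain, extended_chain, plan_b)
        pooled = occupancy_map([a, b])
        occ_a = occupancy_map(a)
        occ_b = occupancy_map(b)
        expected = (6 * occ_a.matrix + 14 * occ_b.matrix) / 20
        np.testing.assert_allclose(pooled.matrix, expected, atol=1e-9)

    def test_topology_mismatch_rejected(self, helix_traj):
        other = build_preset_chain("helix314", 5)
        plan = SynthesisPlan(n_frames=2, dt=1.0, noise_sigma=0.0, seed=0)
        small = synthesize_trajectory(other, other, plan)
        with pytest.raises(ValueError, match="topology"):
            occupancy_map([helix_traj, small])
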