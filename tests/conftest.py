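import numpy as np
import pytest

from betafold import trajio
from betafold.structures import SynthesisPlan, build_preset_chain, synthesize_trajectory


def random_frame(rng, n_residues=8, n_chains=2, box_side=1.5):
    """Random conformation with a full beta backbone per residue.

    Amide hydrogens are placed at random distances 0.08-0.16 nm from their
    nitrogen so that the covalent N-H criterion is exercised both ways.
    """
    names, elements, chain_of, resids, resnames, roles = [], [], [], [], [], []
    coords = []
    per_chain = n_residues // n_chains
    for ci in range(n_chains):
        chain = chr(ord("A") + ci)
        for r in range(1, per_chain + 1):
            n_pos = rng.uniform(0, box_side, 3)
            for nm, el in (("N", "N"), ("H", "H"), ("CB", "C"), ("CA", "C"),
                           ("C", "C"), ("O", "O")):
                names.append(nm)
                elements.append(el)
                chain_of.append(chain)
                resids.append(r)
                resnames.append("B3A")
                roles.append(nm)
                if nm == "N":
                    coords.append(n_pos)
                elif nm == "H":
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    coords.append(n_pos + rng.uniform(0.08, 0.16) * u)
                else:
                    coords.append(rng.uniform(0, box_side, 3))
    top = trajio.Topology(tuple(names), tuple(elements), tuple(chain_of),
                          tuple(resids), tuple(resnames), tuple(roles))
    return trajio.Conformation(top, np.array(coords))


@pytest.fixture(scope="session")
def helix_chain():
    return build_preset_chain("helix314", 6)


@pytest.fixture(scope="session")
def extended_chain():
    return build_preset_chain("extended", 6)


@pytest.fixture(scope="session")
def helix_traj(helix_chain):
    plan = SynthesisPlan(n_frames=100, dt=100.0, noise_sigma=0.005, seed=7)
    return synthesize_trajectory(helix_chain, helix_chain, plan)
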