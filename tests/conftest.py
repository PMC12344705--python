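"""Shared fixtures: toy structures and pre-built model pipelines."""

import numpy as np
import pytest

import mcganm as m


@pytest.fixture(scope="session")
def dimer_structure():
    """Two-chain toy with a ligand near the centroid and side-chain atoms."""
    spec = m.ToySpec(n_residues=40, atoms_per_residue=6, geometry="helix",
                     rng_seed=7, chain_split=20, ligand=(5, 6.0))
    return m.make_toy_structure(spec)


@pytest.fixture(scope="session")
def dimer_pipeline(dimer_structure):
    """Structure → HR selection → model → network → Hessian → modes."""
    s = dimer_structure
    hr = m.select_hr_region(s, "ligand", radius=12.0)
    model = m.build_mcg_nodes(s, hr, cutoff_rc=10.0)
    network = m.build_spring_network(model, s)
    hessian = m.assemble_hessian(network, model)
    modes = m.compute_modes(hessian, expected_zero_modes=6)
    return s, hr, model, network, hessian, modes


@pytest.fixture(scope="session")
def small_allatom_pipeline():
    """All-residues-HR (degenerate all-atom) model on a small chain."""
    spec = m.ToySpec(n_residues=8, atoms_per_residue=5, geometry="extended",
                     rng_seed=3)
    s = m.make_toy_structure(spec)
    hr = frozenset(s.residues)
    model = m.build_mcg_nodes(s, hr, cutoff_rc=8.0)
    network = m.build_spring_network(model, s)
    return s, model, network


@pytest.fixture()
def two_body():
    """Two unit-mass nodes 1 Å apart on x, joined by a unit spring."""
    nodes = [
        m.Node(0, "atom", np.array([0.0, 0.0, 0.0]), 1.0, ("A", 1, ""), (0,)),
        m.Node(1, "atom", np.array([1.0, 0.0, 0.0]), 1.0, ("A", 2, ""), (1,)),
    ]
    model = m.MCGModel(nodes=nodes, hr_residues=frozenset())
    network = m.SpringNetwork(np.array([0]), np.array([1]), np.array([1.0]),
                              n_nodes=2)
    return model, network
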