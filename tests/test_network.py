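"""Mixed-resolution network construction, Hessian, modes and validation."""

import numpy as np
import pytest
import scipy.linalg

import mcganm as m
from mcganm.errors import (
    DiagnosticError,
    GeometryError,
    ModelError,
    RangeError,
    SelectionError,
    StatisticsError,
)

from oracles import (
    brute_force_contact_edges,
    dense_anm_hessian,
    finite_difference_hessian,
    two_pass_pearson,
)


# ---------------------------------------------------------------------------
# HR selection
# ---------------------------------------------------------------------------

class TestSelectHRRegion:
    def test_full_chain_containment(self):
        spec = m.ToySpec(n_residues=12, geometry="extended", rng_seed=1,
                         chain_split=6)
        s = m.make_toy_structure(spec)
        chain_b = [k for k in s.residues if k[0] == "B"]
        center = np.mean(
            [a.position for a in s.atoms if a.chain_id == "B"], axis=0
        )
        hr = m.select_hr_region(s, center, radius=60.0, promote_chains=False)
        assert set(chain_b) <= hr

    def test_point_selection_single_residue(self):
        spec = m.ToySpec(n_residues=10, geometry="extended", rng_seed=2)
        s = m.make_toy_structure(spec)
        target = s.atoms[7]  # an atom of residue 2
        hr = m.select_hr_region(s, target.position, radius=0.1,
                                promote_chains=False)
        assert hr == {target.residue_key}

    def test_matches_distance_oracle(self, dimer_structure):
        s = dimer_structure
        center = np.array([5.0, 1.0, 20.0])
        radius = 12.0
        hr = m.select_hr_region(s, center, radius, promote_chains=False)
        oracle = set()
        for key in s.residues:
            atoms = s.residue_atoms(key)
            if atoms[0].is_hetero:
                continue
            for a in atoms:
                if a.is_heavy and np.linalg.norm(a.position - center) <= radius:
                    oracle.add(key)
                    break
        assert hr == oracle

    def test_chain_promotion(self, dimer_structure):
        s = dimer_structure
        chain_b = [k for k in s.residues if k[0] == "B"]
        # pick a center covering >50% of chain B but not all of it
        sub = [a.position for a in s.atoms
               if a.chain_id == "B" and a.residue_number <= 15]
        center = np.mean(sub, axis=0)
        hr_no = m.select_hr_region(s, center, radius=14.0,
                                   promote_chains=False)
        n_b = sum(k[0] == "B" for k in hr_no)
        assert 0.5 * len(chain_b) < n_b < len(chain_b)
        hr_yes = m.select_hr_region(s, center, radius=14.0,
                                    promote_chains=True)
        assert set(chain_b) <= hr_yes

    def test_empty_selection_raises(self, dimer_structure):
        with pytest.raises(SelectionError):
            m.select_hr_region(dimer_structure, np.array([1e4, 1e4, 1e4]),
                               radius=1.0)


# ---------------------------------------------------------------------------
# node building
# ---------------------------------------------------------------------------

class TestBuildNodes:
    def test_node_counting(self):
        spec = m.ToySpec(n_residues=4, atoms_per_residue=5,
                         geometry="extended", rng_seed=4)
        s = m.make_toy_structure(spec)
        hr = frozenset([s.residues[0]])
        model = m.build_mcg_nodes(s, hr)
        assert model.n_nodes == 5 + 3
        kinds = [n.kind for n in model.nodes]
        assert kinds == ["atom"] * 5 + ["residue"] * 3

    def test_all_hr_equals_heavy_atom_set(self, small_allatom_pipeline):
        s, model, _ = small_allatom_pipeline
        assert model.n_nodes == len(s.heavy_atoms)
        assert all(n.kind == "atom" for n in model.nodes)
        np.testing.assert_allclose(
            model.positions, np.stack([a.position for a in s.heavy_atoms])
        )

    def test_centroid_placement_arithmetic(self):
        spec = m.ToySpec(n_residues=3, atoms_per_residue=4,
                         geometry="extended", rng_seed=9)
        s = m.make_toy_structure(spec)
        model = m.build_mcg_nodes(s, frozenset(), lr_placement="centroid")
        key = s.residues[1]
        heavy = m.residue_heavy_atoms(s, key)
        weights = np.array([a.mass for a in heavy])
        expected = (
            np.stack([a.position for a in heavy]) * weights[:, None]
        ).sum(axis=0) / weights.sum()
        node = next(n for n in model.nodes if n.residue_key == key)
        np.testing.assert_allclose(node.position, expected, atol=1e-12)
        assert node.mass == pytest.approx(weights.sum())

    def test_lr_masses_are_residue_sums(self, dimer_pipeline):
        s, hr, model, *_ = dimer_pipeline
        for node in model.nodes:
            if node.kind == "residue":
                heavy = m.residue_heavy_atoms(s, node.residue_key)
                assert node.mass == pytest.approx(sum(a.mass for a in heavy))
                assert len(node.source_atoms) == len(heavy)


# ---------------------------------------------------------------------------
# spring network
# ---------------------------------------------------------------------------

class TestSpringNetwork:
    def test_heaviside_cutoff(self):
        atoms = [
            m.AtomRecord(1, "CA", "C", "A", "GLY", 1, "", np.zeros(3),
                         1.0, 0.0, 12.011, False),
            m.AtomRecord(2, "CA", "C", "A", "GLY", 2, "",
                         np.array([10.5, 0.0, 0.0]), 1.0, 0.0, 12.011, False),
        ]
        s = m.Structure(atoms)
        model = m.build_mcg_nodes(s, frozenset(s.residues), cutoff_rc=10.0)
        # 10.5 Å apart at rc = 10 Å: the Heaviside factor kills the spring
        with pytest.raises(ModelError):
            m.build_spring_network(model, s)

    def test_contact_count_weighting(self, dimer_pipeline):
        """Residue-involving springs carry the brute-force contact count."""
        s, hr, model, network, *_ = dimer_pipeline
        node_atoms = {n.index: list(n.source_atoms) for n in model.nodes}
        positions = {i: s.atoms[i].position
                     for atoms in node_atoms.values() for i in atoms}
        oracle = brute_force_contact_edges(node_atoms, positions,
                                           model.cutoff_rc)
        got = {(i, j): g for i, j, g in network.edges()}
        assert set(got) == set(oracle)
        for pair, count in oracle.items():
            assert got[pair] == pytest.approx(count * network.gamma_unit)

    def test_two_lr_residues_three_contacts(self):
        """Hand-placed pair of residues with exactly 3 close atom pairs."""
        atoms = []
        serial = 1
        # residue 1: three atoms in a line at x=0; residue 2: three at x
        # chosen so exactly 3 cross pairs are within 6 Å
        coords = {
            1: [(0.0, 0.0, 0.0), (0.0, 2.0, 0.0), (0.0, 40.0, 0.0)],
            2: [(5.0, 0.0, 0.0), (5.0, 5.0, 0.0), (5.0, 80.0, 0.0)],
        }
        for resnum, pts in coords.items():
            for k, p in enumerate(pts):
                atoms.append(m.AtomRecord(
                    serial=serial, name=f"C{k}", element="C", chain_id="A",
                    residue_name="ALA", residue_number=resnum,
                    insertion_code="", position=np.array(p), occupancy=1.0,
                    b_factor=0.0, mass=12.011, is_hetero=False,
                ))
                serial += 1
        s = m.Structure(atoms)
        model = m.build_mcg_nodes(s, frozenset(), lr_placement="centroid",
                                  cutoff_rc=6.0)
        network = m.build_spring_network(model, s, gamma0=2.0)
        # cross distances: 5.0 ✓, √50 ✗, √29 ✓, √34 ✓, rest ≫ 6 → 3 contacts
        assert network.n_edges == 1
        assert network.gamma[0] == pytest.approx(3 * 2.0)

    def test_cutoff_monotonicity(self, dimer_structure):
        s = dimer_structure
        hr = m.select_hr_region(s, "ligand", radius=12.0)
        edges_prev: set = set()
        for rc in (6.0, 8.0, 10.0):
            model = m.build_mcg_nodes(s, hr, cutoff_rc=rc)
            net = m.build_spring_network(model, s)
            edges = set(zip(net.i.tolist(), net.j.tolist()))
            assert edges_prev <= edges
            edges_prev = edges


# ---------------------------------------------------------------------------
# Hessian
# ---------------------------------------------------------------------------

class TestHessian:
    def test_two_body_closed_form(self, two_body):
        model, network = two_body
        h = m.assemble_hessian(network, model)
        modes = m.compute_modes(h)
        # single spring, unit masses: nonzero eigenvalue γ(1/m₁+1/m₂) = 2
        assert modes.n_zero_modes == 5
        assert modes.nonzero_eigenvalues == pytest.approx([2.0])

    def test_translational_invariance_row_sums(self, dimer_pipeline):
        *_, hessian, _ = dimer_pipeline
        n = hessian.n_nodes
        h = hessian.unweighted.toarray()
        # superblock row sums: Σ_j H_ij = 0 for every i
        row_sums = h.reshape(n, 3, n, 3).sum(axis=2)
        np.testing.assert_allclose(row_sums, 0.0, atol=1e-10)

    def test_finite_difference_oracle(self):
        """Hessian equals the second derivative of the pair potential."""
        model, network = m.make_connected_network_fixture(20, seed=13)
        h = m.assemble_hessian(network, model)
        pos = model.positions
        edges = network.edges()
        rest = [np.linalg.norm(pos[j] - pos[i]) for i, j, _ in edges]
        fd = finite_difference_hessian(pos.ravel().copy(), edges, rest)
        dense = h.unweighted.toarray()
        scale = np.abs(fd).max()
        np.testing.assert_allclose(dense, fd, atol=1e-5 * scale)

    def test_offdiagonal_blocks_rank_one(self, two_body):
        model, network = two_body
        h = m.assemble_hessian(network, model).unweighted.toarray()
        block = h[0:3, 3:6]
        assert np.linalg.matrix_rank(block, tol=1e-10) <= 1

    def test_coincident_nodes_raise(self):
        nodes = [
            m.Node(0, "atom", np.zeros(3), 1.0, ("A", 1, ""), (0,)),
            m.Node(1, "atom", np.zeros(3) + 1e-9, 1.0, ("A", 2, ""), (1,)),
        ]
        model = m.MCGModel(nodes=nodes, hr_residues=frozenset())
        network = m.SpringNetwork(np.array([0]), np.array([1]),
                                  np.array([1.0]), n_nodes=2)
        with pytest.raises(GeometryError):
            m.assemble_hessian(network, model)

    def test_all_atom_limit_matches_conventional_anm(self,
                                                     small_allatom_pipeline):
        """Degenerate all-HR model ≡ uniform-γ heavy-atom ANM."""
        s, model, network = small_allatom_pipeline
        heavy = s.heavy_atoms
        pos = np.stack([a.position for a in heavy])
        rc = model.cutoff_rc
        # oracle: independent all-pairs scan with uniform gamma
        oracle_edges = []
        for i in range(len(heavy)):
            for j in range(i + 1, len(heavy)):
                if np.linalg.norm(pos[i] - pos[j]) <= rc:
                    oracle_edges.append((i, j, 1.0))
        assert set(zip(network.i.tolist(), network.j.tolist())) == {
            (i, j) for i, j, _ in oracle_edges
        }
        assert np.all(network.gamma == 1.0)
        # spectrum against a dense, independently assembled ANM Hessian
        dense = dense_anm_hessian(pos, oracle_edges)
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(model.masses), 3)
        dense_mw = dense * np.outer(inv_sqrt_m, inv_sqrt_m)
        oracle_evals = np.sort(scipy.linalg.eigvalsh(dense_mw))
        got = m.compute_modes(m.assemble_hessian(network, model))
        scale = oracle_evals.max()
        np.testing.assert_allclose(got.eigenvalues, oracle_evals,
                                   atol=1e-8 * scale)


# ---------------------------------------------------------------------------
# modes
# ---------------------------------------------------------------------------

class TestModes:
    def test_six_zero_modes_and_rigid_body_span(self):
        model, network = m.make_connected_network_fixture(25, seed=2)
        h = m.assemble_hessian(network, model)
        modes = m.compute_modes(h, expected_zero_modes=6)
        assert modes.n_zero_modes == 6
        basis = m.rigid_body_basis(model)
        angles = scipy.linalg.subspace_angles(
            modes.eigenvectors[:, :6], basis
        )
        assert np.max(angles) < 1e-4

    def test_dense_vs_partial_solver(self):
        model, network = m.make_connected_network_fixture(30, seed=1)
        h = m.assemble_hessian(network, model)
        dense = m.compute_modes(h, n_modes="all")
        # force the sparse path by shrinking the dense-dimension threshold
        import mcganm.network as netmod
        old = netmod._DENSE_LIMIT
        netmod._DENSE_LIMIT = 10
        try:
            partial = m.compute_modes(h, n_modes=9)
        finally:
            netmod._DENSE_LIMIT = old
        slow_dense = dense.nonzero_eigenvalues[:3]
        slow_partial = partial.nonzero_eigenvalues[:3]
        np.testing.assert_allclose(slow_partial, slow_dense,
                                   rtol=1e-8)

    def test_zero_mode_count_diagnostic(self):
        # two disconnected two-body systems → 12 - 2 = more than 6 zeros
        nodes = [
            m.Node(0, "atom", np.array([0.0, 0, 0]), 1.0, ("A", 1, ""), (0,)),
            m.Node(1, "atom", np.array([1.0, 0, 0]), 1.0, ("A", 2, ""), (1,)),
            m.Node(2, "atom", np.array([50.0, 0, 0]), 1.0, ("A", 3, ""), (2,)),
            m.Node(3, "atom", np.array([51.0, 0, 0]), 1.0, ("A", 4, ""), (3,)),
        ]
        model = m.MCGModel(nodes=nodes, hr_residues=frozenset())
        network = m.SpringNetwork(np.array([0, 2]), np.array([1, 3]),
                                  np.array([1.0, 1.0]), n_nodes=4)
        h = m.assemble_hessian(network, model)
        with pytest.raises(DiagnosticError, match="zero modes"):
            m.compute_modes(h, expected_zero_modes=6)

    def test_sign_convention(self):
        model, network = m.make_connected_network_fixture(10, seed=8)
        h = m.assemble_hessian(network, model)
        modes = m.compute_modes(h)
        for k in range(modes.n_modes):
            vec = modes.eigenvectors[:, k]
            assert vec[np.argmax(np.abs(vec))] > 0

    def test_mass_scaling_covariance(self):
        model, network = m.make_connected_network_fixture(15, seed=4)
        h1 = m.assemble_hessian(network, model)
        modes1 = m.compute_modes(h1)
        c = 3.7
        scaled_nodes = [
            m.Node(n.index, n.kind, n.position, n.mass * c, n.residue_key,
                   n.source_atoms)
            for n in model.nodes
        ]
        model2 = m.MCGModel(nodes=scaled_nodes, hr_residues=model.hr_residues)
        h2 = m.assemble_hessian(network, model2)
        modes2 = m.compute_modes(h2)
        np.testing.assert_allclose(
            modes2.nonzero_eigenvalues, modes1.nonzero_eigenvalues / c,
            rtol=1e-9,
        )
        p1 = m.residue_fluctuations(modes1, model).per_node_msf
        p2 = m.residue_fluctuations(modes2, model2).per_node_msf
        np.testing.assert_allclose(p2, p1, rtol=1e-9)


# ---------------------------------------------------------------------------
# fluctuations & B-factor validation
# ---------------------------------------------------------------------------

class TestFluctuations:
    def test_two_body_symmetric_split(self, two_body):
        model, network = two_body
        h = m.assemble_hessian(network, model)
        modes = m.compute_modes(h)
        prof = m.residue_fluctuations(modes, model, n_modes_used=1)
        assert prof.per_node_msf[0] == pytest.approx(prof.per_node_msf[1])

    def test_gamma_doubling_halves_msf(self):
        model, network = m.make_connected_network_fixture(12, seed=6)
        h1 = m.assemble_hessian(network, model)
        prof1 = m.residue_fluctuations(m.compute_modes(h1), model)
        net2 = m.SpringNetwork(network.i, network.j, 2.0 * network.gamma,
                               n_nodes=network.n_nodes)
        h2 = m.assemble_hessian(net2, model)
        prof2 = m.residue_fluctuations(m.compute_modes(h2), model)
        np.testing.assert_allclose(prof2.per_node_msf,
                                   prof1.per_node_msf / 2.0, rtol=1e-9)

    def test_pseudo_inverse_oracle_uniform_masses(self):
        """All-modes MSF equals diag-block traces of pinv(Cartesian H)."""
        model, network = m.make_connected_network_fixture(
            20, seed=3, uniform_mass=True
        )
        h = m.assemble_hessian(network, model)
        modes = m.compute_modes(h)
        prof = m.residue_fluctuations(modes, model)
        hc = h.unweighted.toarray()
        pinv = np.linalg.pinv(hc, rcond=1e-10, hermitian=True)
        n = model.n_nodes
        # for uniform masses the Cartesian covariance is exactly pinv(H):
        # MSF_i = (1/m) Σ u²/λ_mw = Σ u²/λ_cart = tr pinv(H)_ii
        oracle = np.array([np.trace(pinv[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                           for i in range(n)])
        np.testing.assert_allclose(prof.per_node_msf, oracle, atol=1e-8)

    def test_requesting_too_many_modes(self, two_body):
        model, network = two_body
        modes = m.compute_modes(m.assemble_hessian(network, model))
        with pytest.raises(RangeError):
            m.residue_fluctuations(modes, model, n_modes_used=5)


class TestBFactorCorrelation:
    def _profile_from(self, structure, values):
        keys = [k for k in structure.residues
                if not structure.residue_atoms(k)[0].is_hetero]
        return m.FluctuationProfile(
            per_node_msf=np.asarray(values),
            per_residue_msf=dict(zip(keys, values)),
            n_modes_used="all",
        )

    def test_perfect_correlation(self, dimer_structure):
        s = dimer_structure
        keys = [k for k in s.residues if not s.residue_atoms(k)[0].is_hetero]
        bvals = [next(a for a in s.residue_atoms(k) if a.name == "CA").b_factor
                 for k in keys]
        prof = self._profile_from(s, bvals)
        assert m.bfactor_correlation(prof, s) == pytest.approx(1.0)

    def test_anti_correlation(self, dimer_structure):
        s = dimer_structure
        keys = [k for k in s.residues if not s.residue_atoms(k)[0].is_hetero]
        bvals = [next(a for a in s.residue_atoms(k) if a.name == "CA").b_factor
                 for k in keys]
        prof = self._profile_from(s, [-b + 100.0 for b in bvals])
        assert m.bfactor_correlation(prof, s) == pytest.approx(-1.0)

    def test_matches_two_pass_oracle(self, dimer_pipeline):
        s, hr, model, network, hessian, modes = dimer_pipeline
        prof = m.residue_fluctuations(modes, model, s)
        r = m.bfactor_correlation(prof, s)
        msf, bexp = [], []
        for key, value in prof.per_residue_msf.items():
            ca = [a for a in s.residue_atoms(key) if a.name == "CA"]
            if ca:
                msf.append(value)
                bexp.append(ca[0].b_factor)
        assert r == pytest.approx(two_pass_pearson(msf, bexp), abs=1e-12)
        assert -1.0 <= r <= 1.0

    def test_affine_invariance(self, dimer_pipeline):
        s, hr, model, network, hessian, modes = dimer_pipeline
        prof = m.residue_fluctuations(modes, model, s)
        r0 = m.bfactor_correlation(prof, s)
        scaled = m.FluctuationProfile(
            per_node_msf=prof.per_node_msf,
            per_residue_msf={k: 8 * np.pi ** 2 / 3 * v + 4.2
                             for k, v in prof.per_residue_msf.items()},
            n_modes_used=prof.n_modes_used,
        )
        assert m.bfactor_correlation(scaled, s) == pytest.approx(r0, abs=1e-12)

    def test_degenerate_inputs(self, dimer_structure):
        s = dimer_structure
        keys = [k for k in s.residues if not s.residue_atoms(k)[0].is_hetero]
        tiny = m.FluctuationProfile(
            per_node_msf=np.array([1.0, 2.0]),
            per_residue_msf={keys[0]: 1.0, keys[1]: 2.0},
            n_modes_used="all",
        )
        with pytest.raises(StatisticsError):
            m.bfactor_correlation(tiny, s)
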