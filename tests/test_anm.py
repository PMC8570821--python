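import numpy as np
import pytest

import enmsampler as es
from enmsampler.anm import (
    AnmParams,
    build_hessian,
    compute_modes,
    extend_to_all_atoms,
    node_mask_for,
)
from enmsampler.errors import ContractError, DegeneracyError, ModelError
from enmsampler.fixtures import domain_residue_ranges

from conftest import random_rotation
from oracles import brute_force_hessian

BENT_CHAIN = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0]])


class TestBuildHessian:
    def test_superelement_formula(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0.5, 0.5, 0]])
        h = build_hessian(nodes, AnmParams(cutoff=2.0, gamma=1.0))
        np.testing.assert_allclose(h[0:3, 3:6], -np.diag([1.0, 0, 0]), atol=1e-12)

    def test_pairs_beyond_cutoff_have_zero_block(self):
        h = build_hessian(BENT_CHAIN, AnmParams(cutoff=1.2))
        np.testing.assert_array_equal(h[0:3, 6:9], np.zeros((3, 3)))

    def test_translation_invariance(self, helix):
        nodes = helix.coords[node_mask_for(helix)]
        h = build_hessian(nodes, AnmParams(cutoff=8.0))
        for k in range(3):
            t = np.zeros(h.shape[0])
            t[k::3] = 1.0
            assert np.max(np.abs(h @ t)) < 1e-10

    def test_matches_naive_double_loop(self, two_domain):
        nodes = two_domain.coords[node_mask_for(two_domain)]
        h = build_hessian(nodes, AnmParams(cutoff=15.0, gamma=2.5))
        np.testing.assert_allclose(h, brute_force_hessian(nodes, 15.0, 2.5), atol=1e-12)

    def test_isolated_node_named_in_error(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0.5, 1, 0], [50, 50, 50]])
        with pytest.raises(ModelError, match="3"):
            build_hessian(nodes, AnmParams(cutoff=3.0))

    def test_collinear_nodes_rejected(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ModelError):
            build_hessian(nodes, AnmParams(cutoff=1.5))


class TestComputeModes:
    @pytest.mark.parametrize("cutoff", [6.0, 9.0, 15.0])
    def test_exactly_six_zero_modes_helix(self, helix, cutoff):
        nodes = helix.coords[node_mask_for(helix)]
        h = build_hessian(nodes, AnmParams(cutoff=cutoff))
        basis = compute_modes(h, AnmParams(cutoff=cutoff, n_modes=3))
        assert basis.n_modes == 3  # succeeding implies 6 discarded modes

    def test_exactly_six_zero_modes_two_domain(self, two_domain):
        nodes = two_domain.coords[node_mask_for(two_domain)]
        w = np.linalg.eigvalsh(build_hessian(nodes, AnmParams()))
        assert int(np.sum(w < 1e-8 * w[-1])) == 6

    def test_orthonormal_vectors_and_rayleigh_quotients(self, helix):
        nodes = helix.coords[node_mask_for(helix)]
        h = build_hessian(nodes, AnmParams(cutoff=9.0))
        basis = compute_modes(h, AnmParams(cutoff=9.0, n_modes=4))
        gram = basis.node_vectors @ basis.node_vectors.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        for lam, v in zip(basis.eigenvalues, basis.node_vectors):
            assert abs(v @ h @ v - lam) < 1e-8
        assert np.all(np.diff(basis.eigenvalues) >= 0)
        assert np.all(basis.eigenvalues > 0)

    def test_bent_chain_matches_independent_eigensolver(self):
        params = AnmParams(cutoff=1.5, n_modes=3)
        h = build_hessian(BENT_CHAIN, params)
        basis = compute_modes(h, params)
        w_ref = np.linalg.eigvalsh(brute_force_hessian(BENT_CHAIN, 1.5, 1.0))
        np.testing.assert_allclose(basis.eigenvalues, w_ref[6:9], atol=1e-10)

    def test_eigenvalues_invariant_under_rigid_motion(self, helix):
        nodes = helix.coords[node_mask_for(helix)]
        params = AnmParams(cutoff=9.0, n_modes=3)
        w0 = compute_modes(build_hessian(nodes, params), params).eigenvalues
        rot = random_rotation(np.random.default_rng(3))
        moved = nodes @ rot.T + np.array([10.0, -5.0, 2.0])
        w1 = compute_modes(build_hessian(moved, params), params).eigenvalues
        np.testing.assert_allclose(w1, w0, atol=1e-8)

    def test_gamma_scaling_law(self, helix):
        nodes = helix.coords[node_mask_for(helix)]
        p1 = AnmParams(cutoff=9.0, gamma=1.0, n_modes=3)
        p2 = AnmParams(cutoff=9.0, gamma=4.0, n_modes=3)
        b1 = compute_modes(build_hessian(nodes, p1), p1)
        b2 = compute_modes(build_hessian(nodes, p2), p2)
        np.testing.assert_allclose(b2.eigenvalues, 4.0 * b1.eigenvalues, rtol=1e-10)
        for v1, v2 in zip(b1.node_vectors, b2.node_vectors):
            assert abs(abs(v1 @ v2) - 1.0) < 1e-8

    def test_too_many_modes_requested(self):
        params = AnmParams(cutoff=1.5, n_modes=4)  # 3 nodes -> 3 nonrigid modes
        with pytest.raises(ContractError):
            compute_modes(build_hessian(BENT_CHAIN, AnmParams(cutoff=1.5)), params)

    def test_underconnected_network_is_degenerate(self):
        h = build_hessian(BENT_CHAIN, AnmParams(cutoff=1.2))  # 2 springs only
        with pytest.raises(DegeneracyError):
            compute_modes(h, AnmParams(cutoff=1.2, n_modes=1))


class TestExtension:
    def test_calpha_only_structure_is_identity(self, helix):
        mask = es.select(helix, "calpha")
        ca_only = es.Structure(
            atom_serial=np.arange(1, mask.sum() + 1),
            atom_name=helix.atom_name[mask],
            element=helix.element[mask],
            residue_index=helix.residue_index[mask],
            residue_name=helix.residue_name[mask],
            chain_id=helix.chain_id[mask],
            coords=helix.coords[mask],
            coarse_grained=True,
        )
        basis = es.compute_anm_modes(ca_only)
        np.testing.assert_array_equal(basis.atom_vectors, basis.node_vectors)

    def test_side_chain_rows_copy_their_calpha(self, helix, helix_modes):
        m = helix_modes.n_modes
        atom_vec = helix_modes.atom_vectors.reshape(m, helix.n_atoms, 3)
        node_vec = helix_modes.node_vectors.reshape(m, -1, 3)
        ca_idx = np.nonzero(helix_modes.node_mask)[0]
        resid_of_node = {helix.residue_index[i]: k for k, i in enumerate(ca_idx)}
        for i in range(helix.n_atoms):
            k = resid_of_node[helix.residue_index[i]]
            np.testing.assert_array_equal(atom_vec[:, i, :], node_vec[:, k, :])

    def test_norm_matches_direct_expansion(self, helix, helix_modes):
        """With 2 atoms per residue each copying its node, the atom-vector
        norm is sqrt(2) times the (unit) node-vector norm."""
        norms = np.linalg.norm(helix_modes.atom_vectors, axis=1)
        np.testing.assert_allclose(norms, np.sqrt(2.0), atol=1e-10)

    def test_residue_without_node_is_an_error(self, helix):
        s = helix.with_coords(helix.coords)
        s.atom_name[0] = "CX"  # residue 1 loses its CA
        with pytest.raises(ModelError):
            node_mask_for(s)


class TestHingeMode:
    def test_softest_mode_is_the_interdomain_hinge(self, two_domain):
        """The softest nonrigid mode of the two-domain toy should be the
        counter-rotation of the domains about the axis joining them,
        constructed here analytically from the fixture geometry."""
        spec = es.ToySpec(n_residues=40, geometry="two_domain", linker_length=4)
        basis = es.compute_anm_modes(two_domain, AnmParams(n_modes=5))
        mask = basis.node_mask
        nodes = two_domain.coords[mask]
        resid = two_domain.residue_index[mask]
        (a1, b1), (a2, b2) = domain_residue_ranges(spec)
        in1 = (resid >= a1) & (resid <= b1)
        in2 = (resid >= a2) & (resid <= b2)
        axis = nodes[in2].mean(0) - nodes[in1].mean(0)
        axis /= np.linalg.norm(axis)
        center = nodes[~(in1 | in2)].mean(0)
        field = np.zeros_like(nodes)
        field[in1] = -np.cross(axis, nodes[in1] - center)
        field[in2] = np.cross(axis, nodes[in2] - center)
        f = field.ravel() / np.linalg.norm(field)
        overlaps = np.abs(basis.node_vectors @ f)
        assert np.argmax(overlaps) == 0
        assert overlaps[0] > overlaps[1:].max()
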