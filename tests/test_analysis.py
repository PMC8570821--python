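import numpy as np
import pytest

import enmsampler as es
from enmsampler.errors import AnalysisError, ContractError, GeometryError, SelectionError

from conftest import random_rotation
from oracles import brute_force_min_rmsd, rigid_basis


def planted_ensemble(structure, amplitudes, seed=11):
    """Conformers displaced along one direction orthogonal to rigid motions."""
    ca = es.select(structure, "calpha")
    x0 = structure.coords[ca]
    rng = np.random.default_rng(seed)
    d = rng.normal(size=x0.size)
    rig = rigid_basis(x0)
    d -= rig.T @ (rig @ d)
    d /= np.linalg.norm(d)
    coords = x0[None] + np.asarray(amplitudes)[:, None, None] * d.reshape(x0.shape)[None]
    return coords, d


class TestSuperpose:
    def test_identity(self, helix):
        moved, rmsd = es.superpose(helix.coords, helix.coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(moved, helix.coords, atol=1e-12)

    def test_rigid_motion_removed(self, helix):
        rot = random_rotation(np.random.default_rng(2))
        moved_in = helix.coords @ rot.T + np.array([1.0, 2.0, 3.0])
        moved, rmsd = es.superpose(moved_in, helix.coords)
        assert rmsd < 1e-9
        np.testing.assert_allclose(moved, helix.coords, atol=1e-8)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(5, 3))
        b = a + 0.4 * rng.normal(size=(5, 3))
        _, rmsd = es.superpose(a, b)
        assert abs(rmsd - brute_force_min_rmsd(a, b)) < 1e-6

    def test_mask_estimates_fit_applied_to_all_atoms(self, helix, helix_ca):
        rot = random_rotation(np.random.default_rng(9))
        moved_in = helix.coords @ rot.T + 5.0
        moved, rmsd = es.superpose(moved_in, helix.coords, helix_ca)
        assert rmsd < 1e-9
        np.testing.assert_allclose(moved, helix.coords, atol=1e-8)

    def test_collinear_selection_rejected(self):
        line = np.stack([np.arange(4.0), np.zeros(4), np.zeros(4)], axis=1)
        with pytest.raises(GeometryError):
            es.superpose(line, line + 1.0)


class TestEnsemblePca:
    def test_identical_conformers_have_zero_variance(self, helix, helix_ca):
        ens = es.Ensemble(np.repeat(helix.coords[None], 5, axis=0))
        model = es.ensemble_pca(ens, helix_ca, p=2)
        np.testing.assert_allclose(model.variances, 0.0, atol=1e-20)

    def test_recovers_planted_direction_and_variance(self, helix):
        rng = np.random.default_rng(4)
        amps = rng.normal(0.0, 0.01, size=30)
        coords, d = planted_ensemble(helix, amps)
        model = es.ensemble_pca(coords, None, p=2)
        cos = abs(model.components[0] @ d)
        assert cos > 1 - 1e-6
        assert model.variances[0] == pytest.approx(np.var(amps, ddof=1), rel=1e-6)

    def test_variance_sum_equals_mean_square_fluctuation(self, helix, helix_ca, helix_conformers):
        m = helix_conformers.n_conformers
        model = es.ensemble_pca(helix_conformers, helix_ca, p=m - 1)
        total = 0.0
        for c in helix_conformers.coords[:, helix_ca]:
            moved, _ = es.superpose(c, model.mean_coords)
            total += np.sum((moved - model.mean_coords) ** 2)
        assert model.variances.sum() == pytest.approx(total / (m - 1), rel=1e-8)

    def test_components_orthonormal_and_sorted(self, helix, helix_ca, helix_conformers):
        model = es.ensemble_pca(helix_conformers, helix_ca, p=3)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)
        assert np.all(np.diff(model.variances) <= 0)

    def test_too_few_conformers_rejected(self, helix, helix_ca):
        ens = es.Ensemble(np.repeat(helix.coords[None], 3, axis=0))
        with pytest.raises(ContractError):
            es.ensemble_pca(ens, helix_ca, p=3)


class TestProject:
    def test_mean_conformer_maps_to_origin(self, helix, helix_ca, helix_conformers):
        model = es.ensemble_pca(helix_conformers, helix_ca, p=2)
        proj = es.project(model.mean_coords[None], model)
        np.testing.assert_allclose(proj, 0.0, atol=1e-8)

    def test_full_rank_projection_reconstructs_coordinates(self, helix, helix_ca, helix_conformers):
        m = helix_conformers.n_conformers
        model = es.ensemble_pca(helix_conformers, helix_ca, p=m - 1)
        proj = es.project(helix_conformers, model, helix_ca)
        for k in range(m):
            rebuilt = model.mean_coords.ravel() + proj[k] @ model.components
            aligned, _ = es.superpose(
                helix_conformers.coords[k][helix_ca], model.mean_coords
            )
            np.testing.assert_allclose(rebuilt, aligned.ravel(), atol=1e-8)

    def test_recovers_planted_amplitudes(self, helix):
        rng = np.random.default_rng(8)
        amps = rng.normal(0.0, 0.01, size=25)
        coords, _ = planted_ensemble(helix, amps)
        model = es.ensemble_pca(coords, None, p=1)
        proj = es.project(coords, model)[:, 0]
        centered = amps - amps.mean()
        sign = np.sign(proj[np.argmax(np.abs(proj))] * centered[np.argmax(np.abs(proj))])
        np.testing.assert_allclose(proj, sign * centered, atol=1e-8)

    def test_projections_invariant_under_rigid_motion(self, helix, helix_ca, helix_conformers):
        model = es.ensemble_pca(helix_conformers, helix_ca, p=2)
        proj = es.project(helix_conformers, model, helix_ca)
        rot = random_rotation(np.random.default_rng(12))
        moved = es.Ensemble(helix_conformers.coords @ rot.T + np.array([2.0, 0.0, -4.0]))
        proj_moved = es.project(moved, model, helix_ca)
        np.testing.assert_allclose(proj_moved, proj, atol=1e-8)


class TestKdeMap:
    def test_bimodal_sample_localized(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 0.05, size=(60, 2))
        b = rng.normal(0.0, 0.05, size=(60, 2)) + np.array([5.0, 5.0])
        dmap = es.kde_map(np.vstack([a, b]), es.GridSpec(nx=200, ny=200))
        dx = dmap.grid_x[1] - dmap.grid_x[0]
        dy = dmap.grid_y[1] - dmap.grid_y[0]
        half = dmap.density.copy()
        i0, j0 = np.unravel_index(np.argmax(half), half.shape)
        assert abs(dmap.grid_x[i0]) < 5 * dx + 0.3 or abs(dmap.grid_x[i0] - 5) < 5 * dx + 0.3
        # peaks of each half of the plane sit at the cloud centers
        xmid = np.searchsorted(dmap.grid_x, 2.5)
        for sl, cx in ((slice(None, xmid), 0.0), (slice(xmid, None), 5.0)):
            sub = dmap.density[sl]
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            x = dmap.grid_x[sl][i]
            y = dmap.grid_y[j]
            assert abs(x - cx) <= dx + 0.05 and abs(y - cx) <= dy + 0.05

    def test_density_normalized(self):
        rng = np.random.default_rng(1)
        dmap = es.kde_map(rng.normal(size=(100, 2)))
        assert abs(dmap.integral() - 1.0) < 1e-3

    def test_duplicating_points_leaves_map_unchanged(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 2))
        grid = es.GridSpec(nx=50, ny=50, xlim=(-5, 5), ylim=(-5, 5))
        a = es.kde_map(pts, grid, bandwidth=0.25)
        b = es.kde_map(np.vstack([pts, pts]), grid, bandwidth=0.25)
        np.testing.assert_allclose(b.density, a.density, atol=1e-6)

    def test_degenerate_dimension_raises(self):
        pts = np.stack([np.arange(10.0), np.zeros(10)], axis=1)
        with pytest.raises(AnalysisError):
            es.kde_map(pts)


class TestInterdomainAngle:
    def make_triangle(self, positions):
        n = len(positions)
        return es.Structure(
            atom_serial=np.arange(1, n + 1),
            atom_name=np.array(["CA"] * n, dtype=object),
            element=np.array(["C"] * n, dtype=object),
            residue_index=np.arange(1, n + 1),
            residue_name=np.array(["ALA"] * n, dtype=object),
            chain_id=np.array(["A"] * n, dtype=object),
            coords=np.array(positions, dtype=float),
            coarse_grained=True,
        )

    def test_collinear_centroids_give_180(self):
        s = self.make_triangle([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        spec = es.AngleSpec("resid 1-1", "resid 2-2", "resid 3-3")
        assert es.interdomain_angle(s.coords, spec, s) == pytest.approx(180.0)

    def test_perpendicular_arms_give_90(self):
        s = self.make_triangle([[0.0, 1, 0], [0, 0, 0], [1, 0, 0]])
        spec = es.AngleSpec("resid 1-1", "resid 2-2", "resid 3-3")
        assert es.interdomain_angle(s.coords, spec, s) == pytest.approx(90.0)

    def test_hand_computed_geometry(self):
        s = self.make_triangle([[0.0, 0, 0], [1, 0, 0], [1, 1, 0]])
        spec = es.AngleSpec("resid 1-1", "resid 2-2", "resid 3-3")
        expected = np.degrees(np.arccos(0.0))
        assert es.interdomain_angle(s.coords, spec, s) == pytest.approx(expected)

    def test_angle_invariant_under_rigid_motion(self, two_domain):
        spec = es.AngleSpec("resid 1-18", "resid 19-22", "resid 23-40")
        base = es.interdomain_angle(two_domain.coords, spec, two_domain)
        rot = random_rotation(np.random.default_rng(6))
        moved = two_domain.coords @ rot.T + np.array([7.0, 8.0, 9.0])
        assert es.interdomain_angle(moved, spec, two_domain) == pytest.approx(base, abs=1e-9)

    def test_overlapping_selections_rejected(self, two_domain):
        spec = es.AngleSpec("resid 1-20", "resid 19-22", "resid 23-40")
        with pytest.raises(SelectionError):
            es.interdomain_angle(two_domain.coords, spec, two_domain)

    def test_empty_selection_rejected(self, two_domain):
        spec = es.AngleSpec("resid 1-18", "name XX", "resid 23-40")
        with pytest.raises(SelectionError):
            es.interdomain_angle(two_domain.coords, spec, two_domain)
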