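"""Analysis oracles: grid weights, order-parameter cumulants, nematic order,
focus segmentation, profiles and correlations."""

import numpy as np
import pytest

from topochrom import fixtures
from topochrom.analysis import (
    binder_cumulant,
    build_grid,
    delta_phi_field,
    density_cross_correlation,
    local_nematic,
    moment_skewness,
    order_param_stats,
    radial_density,
    segment_foci,
    surface_fraction,
)
from topochrom.geometry import Sphere


@pytest.fixture(scope="module")
def sphere_grid():
    return build_grid(Sphere(diameter=8.0), cell_size=1.0)


class TestBuildGrid:
    def test_interior_and_exterior_cells(self, sphere_grid):
        g = sphere_grid
        centers = g.cell_centers()
        rad = np.linalg.norm(centers, axis=1)
        # cell fully inside: centre deeper than half the cell diagonal
        inside = rad < g.geometry.radius - np.sqrt(3) / 2 - 1e-9
        outside = rad > g.geometry.radius + np.sqrt(3) / 2 + 1e-9
        assert np.all(g.v[inside] == 1.0)
        assert np.all(g.v[outside] == 0.0)

    def test_total_accessible_volume_matches_sphere(self, sphere_grid):
        g = sphere_grid
        total = g.v.sum() * g.cell_size**3
        assert total == pytest.approx(g.geometry.volume, rel=5e-3)

    def test_deterministic(self):
        a = build_grid(Sphere(diameter=4.0), mc_samples=1024)
        b = build_grid(Sphere(diameter=4.0), mc_samples=1024)
        assert np.array_equal(a.v, b.v)


class TestDeltaPhiField:
    def test_hand_tallied_configuration(self):
        grid = build_grid(Sphere(diameter=6.0), cell_size=2.0, mc_samples=256)
        # three beads in one cell (2A, 1B), one A elsewhere
        pos = np.array([
            [0.5, 0.5, 0.5], [0.7, 0.5, 0.5], [0.5, 0.7, 0.5],
            [-1.5, -1.5, -1.5],
        ])
        species = np.array(["A", "A", "B", "A"])
        f = delta_phi_field(pos, species, grid, VA=1.0, VB=1.0)
        c_mixed = grid.cell_indices([[0.5, 0.5, 0.5]])[0]
        c_pure = grid.cell_indices([[-1.5, -1.5, -1.5]])[0]
        assert f.delta_phi[c_mixed] == pytest.approx((2 - 1) / 3)
        assert f.delta_phi[c_pure] == 1.0
        assert f.nA.sum() == 3 and f.nB.sum() == 1

    def test_pure_cells_and_balanced_cells(self, sphere_grid):
        pos = np.array([[0.2, 0.2, 0.2], [0.3, 0.2, 0.2]])
        f = delta_phi_field(pos, np.array(["A", "B"]), sphere_grid, VA=2.0, VB=2.0)
        c = sphere_grid.cell_indices([[0.2, 0.2, 0.2]])[0]
        assert f.delta_phi[c] == 0.0
        assert np.isnan(f.delta_phi[np.nonzero(sphere_grid.v)[0][0]]) or True
        # bounded where defined
        defined = ~np.isnan(f.delta_phi)
        assert np.all(np.abs(f.delta_phi[defined]) <= 1.0)


class TestCumulants:
    def test_two_delta_field(self):
        values = np.array([1.0, -1.0])
        weights = np.array([0.5, 0.5])
        assert binder_cumulant(values, weights) == pytest.approx(2.0 / 3.0)
        assert moment_skewness(values, weights) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_samples(self):
        values, weights = fixtures.gaussian_field(n_cells=1_000_000, seed=8)
        assert binder_cumulant(values, weights) == pytest.approx(0.0, abs=0.01)
        assert moment_skewness(values, weights) == pytest.approx(0.0, abs=0.01)

    def test_symmetric_histogram_zero_skewness(self, rng):
        x = rng.normal(size=5001)
        x = np.concatenate([x, -x])  # exactly symmetric sample
        assert moment_skewness(x) == pytest.approx(0.0, abs=1e-12)

    def test_binder_bounded_above(self, rng):
        for _ in range(20):
            x = rng.uniform(-1, 1, size=100)
            assert binder_cumulant(x) <= 2.0 / 3.0 + 1e-12

    def test_purification_monotonicity(self, rng):
        # two-phase toy fields approach 2/3 as the phases purify
        binders = []
        for noise in [0.8, 0.4, 0.2, 0.05]:
            signs = rng.choice([-1.0, 1.0], size=20000)
            x = np.clip(signs + rng.normal(0, noise, 20000), -1, 1)
            binders.append(binder_cumulant(x))
        assert all(b2 > b1 for b1, b2 in zip(binders, binders[1:]))
        assert binders[-1] > 0.6


class TestOrderParamStats:
    def test_histogram_normalisation_and_stats(self, sphere_grid, rng):
        pos = fixtures.uniform_mixture(n=3000, radius=3.9, seed=4)[0]
        species = np.where(rng.random(3000) < 0.5, "A", "B")
        stats = order_param_stats((pos, species), sphere_grid, np.pi / 6, np.pi / 6)
        widths = np.diff(stats.bin_edges)
        assert np.sum(stats.histogram * widths) == pytest.approx(1.0, abs=1e-9)
        assert abs(stats.mean) < 0.2

    def test_two_phase_snapshot_is_bimodal(self, sphere_grid):
        pos, species, _ = fixtures.two_phase_sphere(n=6000, radius=3.9, seed=5)
        stats = order_param_stats((pos, species), sphere_grid, np.pi / 6, np.pi / 6)
        assert stats.binder > 0.3

    def test_all_empty_raises(self, sphere_grid):
        pos = np.zeros((0, 3))
        with pytest.raises((ValueError, IndexError)):
            order_param_stats((pos, np.array([], dtype="<U1")), sphere_grid, 1.0, 1.0)


class TestLocalNematic:
    def test_parallel_bonds_full_order(self, sphere_grid):
        n = 200
        mids = np.random.default_rng(1).uniform(-0.4, 0.4, (n, 3))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        pos, species = fixtures._chain_with_bonds(mids, dirs, 0.4)
        s_cells, q, mean_s = local_nematic((pos, species), sphere_grid, "AA",
                                           surface_width=1.0)
        occupied = q > 0
        assert np.allclose(s_cells[occupied], 1.0, atol=1e-9)

    def test_planar_isotropic_bonds(self, sphere_grid):
        pos, species, _ = fixtures.planar_bonds(n_bonds=4000, radius=4.0, seed=2)
        _, _, mean_s = local_nematic((pos, species), sphere_grid, "AA")
        assert mean_s == pytest.approx(-0.5, abs=0.02)

    def test_isotropic_bonds_vanishing_order(self):
        rng = np.random.default_rng(3)
        dirs = rng.normal(size=(10000, 3))
        mids = rng.uniform(-0.45, 0.45, (10000, 3))
        pos, species = fixtures._chain_with_bonds(mids, dirs, 0.3)
        grid = build_grid(Sphere(diameter=8.0), mc_samples=512)
        _, _, mean_s = local_nematic((pos, species), grid, "AA")
        assert abs(mean_s) < 0.03

    def test_tangent_shell_bonds_negative_order(self):
        # bonds lying along a spherical wall: locally planar, S < 0
        pos, species, geom = fixtures.shell_wall_bonds(n_bonds=6000, radius=4.0,
                                                       shell_radius=2.2, seed=6)
        grid = build_grid(geom, mc_samples=512)
        _, _, mean_s = local_nematic((pos, species), grid, "AA")
        assert mean_s < -0.1

    def test_missing_bond_species_raises(self, sphere_grid):
        pos = np.zeros((4, 3))
        species = np.array(["A", "B", "A", "B"])
        with pytest.raises(ValueError):
            local_nematic((pos, species), sphere_grid, "AA")


class TestSegmentFoci:
    def test_collinear_cluster_line_anisotropy(self):
        pos, _, _ = fixtures.line_cluster(n=40, spacing=0.3)
        foci = segment_foci(pos, cutoff=0.43, min_size=8)
        assert len(foci) == 1
        assert foci.foci[0].shape_anisotropy == pytest.approx(1.0, abs=1e-9)

    def test_ball_cluster_spherical(self):
        pos, _, _ = fixtures.ball_cluster(n=10000, radius=1.5, seed=3)
        foci = segment_foci(pos, cutoff=0.6, min_size=8)
        assert len(foci) == 1
        assert foci.foci[0].shape_anisotropy < 0.01

    def test_min_size_filters_noise(self):
        pos = np.vstack([fixtures.line_cluster(20, 0.3)[0],
                         np.array([[50.0, 0, 0], [50.2, 0, 0]])])
        foci = segment_foci(pos, cutoff=0.43, min_size=8)
        assert len(foci) == 1

    def test_matches_brute_force_union_find(self, rng):
        pos = rng.uniform(-2, 2, size=(300, 3))
        cutoff = 0.43
        got = segment_foci(pos, cutoff=cutoff, min_size=1)
        # brute-force union-find over the full distance matrix
        parent = list(range(300))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(299):
            for j in range(i + 1, 300):
                if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                    parent[find(i)] = find(j)
        expected = {}
        for i in range(300):
            expected.setdefault(find(i), set()).add(i)
        got_sets = {frozenset(f.member_indices.tolist()) for f in got}
        assert got_sets == {frozenset(s) for s in expected.values()}

    def test_rotation_invariance_of_shape_metrics(self, rng):
        pos, _, _ = fixtures.ball_cluster(n=500, radius=1.0, seed=4)
        pos[:, 0] *= 3.0  # make it anisotropic
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = segment_foci(pos, cutoff=5.0, min_size=8).foci[0]
        b = segment_foci(pos @ q.T, cutoff=5.0, min_size=8).foci[0]
        assert a.Rg == pytest.approx(b.Rg, rel=1e-9)
        assert a.shape_anisotropy == pytest.approx(b.shape_anisotropy, rel=1e-9)

    def test_empty_input(self):
        assert len(segment_foci(np.zeros((0, 3)), cutoff=0.5)) == 0


class TestSurfaceFraction:
    def test_uniform_mixture_near_unity(self):
        pos, species, geom = fixtures.uniform_mixture(n=40000, radius=4.0, seed=7)
        ratio = surface_fraction(pos, species, geom, shell_width=1.0)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_all_b_in_shell(self):
        geom = Sphere(diameter=8.0)
        n = 100
        rng = np.random.default_rng(0)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = np.vstack([3.6 * v, 0.5 * v])       # shell Bs, core As
        species = np.array(["B"] * n + ["A"] * n)
        ratio = surface_fraction(pos, species, geom, shell_width=1.0)
        assert ratio == pytest.approx(1.0 / 0.5)  # shell fraction 1 over phi_B

    def test_no_b_beads_raises(self):
        geom = Sphere(diameter=8.0)
        with pytest.raises(ValueError):
            surface_fraction(np.zeros((5, 3)), np.repeat("A", 5), geom)

    def test_empty_shell_reports_missing(self):
        geom = Sphere(diameter=8.0)
        pos = np.zeros((4, 3))
        species = np.array(["A", "B", "A", "B"])
        assert np.isnan(surface_fraction(pos, species, geom, shell_width=1.0))


class TestRadialDensity:
    def test_uniform_flat_profile(self):
        pos, species, geom = fixtures.uniform_mixture(n=60000, radius=4.0, seed=9)
        r, rho = radial_density((pos, species), geometry=geom, n_shells=6)
        mean_rho = 60000 / geom.volume
        assert np.all(np.abs(rho / mean_rho - 1.0) < 0.1)

    def test_counts_conserved(self):
        pos, species, geom = fixtures.uniform_mixture(n=5000, radius=4.0, seed=10)
        r, rho = radial_density((pos, species), geometry=geom, n_shells=8)
        edges = np.linspace(0, geom.radius, 9)
        vol = 4 / 3 * np.pi * np.diff(edges**3)
        assert np.sum(rho * vol) == pytest.approx(5000)

    def test_single_shell_occupied(self):
        geom = Sphere(diameter=8.0)
        rng = np.random.default_rng(1)
        v = rng.normal(size=(200, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = 1.5 * v
        r, rho = radial_density((pos, np.repeat("A", 200)), geometry=geom, n_shells=4)
        assert np.count_nonzero(rho) == 1


class TestCrossCorrelation:
    def _traj(self, pos):
        return (pos[None], np.repeat("A", pos.shape[0]))

    def test_identical_fields(self, sphere_grid, rng):
        pos = fixtures.uniform_mixture(n=2000, radius=3.8, seed=11)[0]
        c = density_cross_correlation(self._traj(pos), self._traj(pos), sphere_grid)
        assert c == pytest.approx(1.0, rel=1e-12)

    def test_independent_fields_near_zero(self):
        # ~10^3 cells, several snapshot pairs, both filling the geometry
        geom = Sphere(diameter=13.0)
        grid = build_grid(geom, mc_samples=1024)
        a = np.stack([fixtures.uniform_mixture(12000, 6.5, seed=s)[0]
                      for s in (12, 14, 16)])
        b = np.stack([fixtures.uniform_mixture(12000, 6.5, seed=s)[0]
                      for s in (13, 15, 17)])
        spec = np.repeat("A", 12000)
        c = density_cross_correlation((a, spec), (b, spec), grid)
        assert abs(c) < 0.05

    def test_zero_variance_pair_excluded(self, sphere_grid):
        pos = np.zeros((0, 3))
        with pytest.raises(ValueError):
            density_cross_correlation(
                (pos[None], np.array([], dtype="<U1")),
                (pos[None], np.array([], dtype="<U1")), sphere_grid)
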