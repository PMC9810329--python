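"""Integrator correctness: initialisation measure, equilibrium oracles,
neighbour search, determinism and restart."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from topochrom import model
from topochrom.engine import (
    Protocol,
    SimulationState,
    Trajectory,
    init_conformation,
    msd,
    neighbor_candidates,
    run,
    step,
)
from topochrom.geometry import Slab, Sphere
from topochrom.potentials import fene_energy, total_forces, vex_energy, PairState
from topochrom import _kernels  # noqa: F401  (ensures the kernel is compiled once)


def _free_params(n, diameter=80.0, chain=True):
    p = model.monodisperse_params(N=n, phi_A=0.5, eps_hc=0.0, lambda_ra=0.0,
                                  variant="PASSIVE",
                                  geometry=Sphere(diameter=diameter))
    return p.with_overrides(chain=chain)


class TestInitConformation:
    def test_beads_inside_geometry(self):
        params = model.monodisperse_params(N=256, phi_A=0.5)
        seq = model.generate_sequence(256, 4, 0.5, seed=0)
        state = init_conformation(seq, params.geometry, 1, params)
        assert np.all(params.geometry.wall_distance(state.positions) > 0)

    def test_deterministic_under_seed(self):
        params = model.monodisperse_params(N=64, phi_A=0.5)
        seq = model.generate_sequence(64, 4, 0.5, seed=0)
        a = init_conformation(seq, params.geometry, 7, params)
        b = init_conformation(seq, params.geometry, 7, params)
        assert np.array_equal(a.positions, b.positions)

    def test_bond_lengths_follow_fene_boltzmann(self):
        # dimer in a huge cavity: sampled bond lengths vs the ideal-chain law
        params = _free_params(2)
        seq = model.generate_sequence(4, 4, 0.5, seed=0)
        seq = model.PolymerSequence(np.array(["A", "A"]), block_size=1)
        r_samples = []
        for s in range(2000):
            st = init_conformation(seq, params.geometry, s, params)
            r_samples.append(float(np.linalg.norm(st.positions[1] - st.positions[0])))
        pp = params.pair(0, 0)
        grid = np.linspace(1e-6, pp.r0 * (1 - 1e-9), 4000)
        pdf = grid**2 * np.exp(-fene_energy(grid, pp.k, pp.r0))
        cdf = np.concatenate(([0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))))
        cdf /= cdf[-1]
        res = kstest(r_samples, lambda x: np.interp(x, grid, cdf))
        assert res.pvalue > 0.01

    def test_too_tight_geometry_raises(self):
        seq = model.PolymerSequence(np.repeat(["A", "B"], 64), block_size=64)
        params = model.monodisperse_params(N=128, phi_A=0.5)
        with pytest.raises(Exception):
            init_conformation(seq, Sphere(diameter=0.25), 0, params)


class TestStep:
    def test_zero_temperature_no_force_is_stationary(self):
        params = _free_params(1, chain=False)
        seq = model.PolymerSequence(np.array(["A"]), block_size=1)
        state = SimulationState(positions=np.zeros((1, 3)), sequence=seq)
        step(state, params, Protocol(seed=1), kT=0.0)
        assert np.allclose(state.positions, 0.0)

    def test_free_diffusion_matches_einstein_relation(self):
        # ensemble of independent beads on a wide grid inside a huge cavity
        n = 4096
        params = _free_params(n, diameter=120.0, chain=False)
        side = round(n ** (1 / 3)) + 1
        g = np.arange(side) * 2.5
        gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
        pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])[:n].astype(float)
        pos -= pos.mean(axis=0)
        seq = model.PolymerSequence(np.repeat("A", n), block_size=1)
        state = SimulationState(positions=pos.copy(), sequence=seq)
        t_run = 0.2
        proto = Protocol(dt=1e-4, anneal_duration=0.0, production_duration=t_run,
                         snapshot_interval=t_run, seed=3)
        run(state, params, proto)
        d = 50.5086 / 117.6
        diffusion = 1.0 / (3.0 * math.pi * d)  # kT / (6 pi eta (d/2))
        msd_obs = np.sum((state.positions - pos) ** 2, axis=1)
        se = msd_obs.std() / math.sqrt(n)
        assert abs(msd_obs.mean() - 6 * diffusion * t_run) < 3 * se

    def test_passive_dimer_bond_histogram_matches_boltzmann(self):
        # stationary bond-length law of spring + Gaussian repulsion by quadrature
        params = _free_params(2)
        seq = model.PolymerSequence(np.array(["A", "A"]), block_size=1)
        state = SimulationState(
            positions=np.array([[0.0, 0.0, 0.0], [0.45, 0.0, 0.0]]), sequence=seq)
        proto = Protocol(dt=1e-4, anneal_duration=2.0, production_duration=50.0,
                         snapshot_interval=0.05, seed=11)
        traj = run(state, params, proto)
        r = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0], axis=1)
        pp = params.pair(0, 0)
        grid = np.linspace(1e-6, pp.r0 * (1 - 1e-9), 6000)
        energy = fene_energy(grid, pp.k, pp.r0) + vex_energy(
            grid, PairState.REPULSION, pp.eps_vex, pp.alpha_vex)
        pdf = grid**2 * np.exp(-energy)
        cdf = np.concatenate(([0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))))
        cdf /= cdf[-1]
        res = kstest(r[::2], lambda x: np.interp(x, grid, cdf))
        assert res.pvalue > 0.01

    def test_kernel_forces_match_reference(self, rng):
        # one tiny zero-temperature step must reproduce the analytic forces
        params = model.monodisperse_params(N=24, phi_A=0.5, eps_hc=3.0,
                                           geometry=Sphere(diameter=5.0))
        seq = model.generate_sequence(24, 4, 0.5, seed=2)
        state = init_conformation(seq, params.geometry, 3, params)
        pos0 = state.positions.copy()
        f_ref = total_forces(pos0, seq.codes, params)
        dt = 1e-9
        step(state, params, Protocol(dt=dt, seed=1), kT=0.0)
        d = 50.5086 / 117.6
        gam = 3 * math.pi * d
        f_kernel = (state.positions - pos0) / dt * gam
        # tolerance covers the kernel's documented exp-table interpolation error
        assert np.allclose(f_kernel, f_ref, rtol=2e-4, atol=2e-3)

    def test_single_confined_bead_radial_boltzmann(self):
        # equilibrium sanity: radial density follows the confinement weight
        params = model.monodisperse_params(N=1, phi_A=0.5,
                                           geometry=Sphere(diameter=3.0))
        params = params.with_overrides(chain=False)
        seq = model.PolymerSequence(np.array(["A"]), block_size=1)
        state = SimulationState(positions=np.zeros((1, 3)), sequence=seq)
        proto = Protocol(dt=1e-4, anneal_duration=2.0, production_duration=60.0,
                         snapshot_interval=0.05, seed=21)
        traj = run(state, params, proto)
        rad = np.linalg.norm(traj.positions[:, 0, :], axis=1)
        from topochrom.potentials import confinement_energy
        cp = params.confinement[0]
        r_geom = params.geometry.radius
        grid = np.linspace(1e-4, r_geom - 1e-4, 3000)
        pdf = grid**2 * np.exp(-confinement_energy(r_geom - grid, cp))
        cdf = np.concatenate(([0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))))
        cdf /= cdf[-1]
        res = kstest(rad[::3], lambda x: np.interp(x, grid, cdf))
        assert res.pvalue > 0.01


class TestRunProtocol:
    def test_zero_production_gives_empty_trajectory(self, small_params):
        seq = model.generate_sequence(64, 4, 0.5, seed=0)
        state = init_conformation(seq, small_params.geometry, 1, small_params)
        proto = Protocol(anneal_duration=0.01, production_duration=0.0, seed=2)
        traj = run(state, small_params, proto)
        assert traj.n_snapshots == 0
        assert state.time == pytest.approx(0.01, rel=1e-6)

    def test_snapshot_count(self, small_params):
        seq = model.generate_sequence(64, 4, 0.5, seed=0)
        state = init_conformation(seq, small_params.geometry, 1, small_params)
        proto = Protocol(anneal_duration=0.0, production_duration=0.105,
                         snapshot_interval=0.01, seed=2)
        traj = run(state, small_params, proto, soft_start=0.0)
        assert traj.n_snapshots == 10  # floor(production / interval)

    def test_rerun_is_bitwise_reproducible(self, small_params):
        seq = model.generate_sequence(64, 4, 0.5, seed=0)
        proto = Protocol(anneal_duration=0.02, production_duration=0.05,
                         snapshot_interval=0.01, seed=5)
        results = []
        for _ in range(2):
            state = init_conformation(seq, small_params.geometry, 1, small_params)
            traj = run(state, small_params, proto)
            results.append(traj.positions.copy())
        assert np.array_equal(results[0], results[1])

    def test_restart_from_checkpoint_reproduces_trajectory(self, tmp_path,
                                                           small_params):
        params = small_params.with_overrides(
            variant="RANR", rates=small_params.rates.__class__(lambda_ra=10.0))
        seq = model.generate_sequence(64, 4, 0.5, seed=0)
        state = init_conformation(seq, params.geometry, 1, params)
        proto = Protocol(anneal_duration=0.02, production_duration=0.05,
                         snapshot_interval=0.01, seed=9)
        # checkpoint after annealing, then run production twice from it
        run(state, params, Protocol(anneal_duration=0.02, production_duration=0.0,
                                    seed=9))
        ckpt = tmp_path / "state.json"
        state.save(ckpt)
        prod = Protocol(anneal_duration=0.0, production_duration=0.05,
                        snapshot_interval=0.01, seed=17)
        t1 = run(SimulationState.load(ckpt), params, prod, soft_start=0.0)
        t2 = run(SimulationState.load(ckpt), params, prod, soft_start=0.0)
        assert np.array_equal(t1.positions, t2.positions)

    def test_slab_geometry_keeps_beads_between_walls(self):
        geometry = Slab(lx=4.0, ly=4.0, lz=3.0)
        params = model.monodisperse_params(N=64, phi_A=0.5, geometry=geometry)
        seq = model.generate_sequence(64, 4, 0.5, seed=3)
        state = init_conformation(seq, geometry, 4, params)
        proto = Protocol(anneal_duration=0.5, production_duration=0.5,
                         snapshot_interval=0.1, seed=6)
        traj = run(state, params, proto)
        z = traj.positions[..., 2]
        assert np.all((z > 0) & (z < geometry.lz))
        x = traj.positions[..., 0]
        assert np.all((x >= 0) & (x < geometry.lx))


class TestVariantPacking:
    def test_phantom_disables_aa_repulsion(self):
        from topochrom.engine import _pack

        params = model.monodisperse_params(N=8, variant="PHANTOM")
        seq = model.generate_sequence(8, 4, 0.5, seed=0)
        packed = _pack(params, seq, 1e-4, 1.0)
        assert packed["eps_vex"][0, 0] == 0.0
        assert packed["eps_vex"][1, 1] == 8.0

    def test_nontransient_applies_cycle_average(self):
        from topochrom.engine import _pack

        params = model.monodisperse_params(N=8, lambda_ra=0.5,
                                           variant="NONTRANSIENT")
        seq = model.generate_sequence(8, 4, 0.5, seed=0)
        packed = _pack(params, seq, 1e-4, 1.0)
        assert packed["eps_vex"][0, 0] == pytest.approx(params.nontransient_eps())


class TestEventLog:
    def test_active_run_records_catch_and_release_cycle(self):
        params = model.monodisperse_params(N=64, phi_A=0.5, lambda_ra=50.0,
                                           variant="RANR")
        seq = model.generate_sequence(64, 4, 0.5, seed=8)
        state = init_conformation(seq, params.geometry, 8, params)
        proto = Protocol(dt=1e-4, anneal_duration=0.0, production_duration=0.5,
                         snapshot_interval=0.5, seed=9)
        traj = run(state, params, proto, record_events=True, soft_start=0.0)
        kinds = {kind for _, kind, _, _ in traj.events}
        assert "bind" in kinds and "advance" in kinds
        # every advance/unbind refers to a previously bound pair
        bound = set()
        for _, kind, i, j in traj.events:
            if kind == "bind":
                bound.add((i, j))
            else:
                assert (i, j) in bound


class TestNeighborCandidates:
    def test_matches_brute_force(self, rng):
        pos = rng.uniform(-3, 3, size=(200, 3))
        got = neighbor_candidates(pos, 1.0)
        expected = sorted(
            (i, j)
            for i in range(199)
            for j in range(i + 1, 200)
            if np.linalg.norm(pos[i] - pos[j]) <= 1.0
        )
        assert got == expected

    def test_single_bead_empty(self):
        assert neighbor_candidates(np.zeros((1, 3)), 1.0) == []

    def test_periodic_wraparound_pairs_found(self):
        geometry = Slab(lx=5.0, ly=5.0, lz=3.0)
        pos = np.array([[0.1, 2.0, 1.5], [4.95, 2.0, 1.5]])
        assert neighbor_candidates(pos, 0.5, geometry) == [(0, 1)]


class TestMsd:
    def test_identical_snapshots_zero(self):
        pos = np.zeros((3, 5, 3))
        traj = Trajectory(times=np.arange(3.0), positions=pos,
                          species=np.repeat("A", 5), geometry=Sphere(diameter=10.0))
        _, mean = msd(traj)
        assert np.allclose(mean, 0.0)

    def test_linear_drift_quadratic(self):
        t = np.arange(4.0)
        pos = np.zeros((4, 2, 3))
        pos[:, :, 0] = (0.3 * t)[:, None]
        traj = Trajectory(times=t, positions=pos, species=np.repeat("A", 2),
                          geometry=Sphere(diameter=10.0))
        _, mean = msd(traj)
        assert np.allclose(mean, (0.3 * t) ** 2)
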