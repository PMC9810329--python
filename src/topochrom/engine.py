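"""Overdamped Brownian dynamics driver.

Positions evolve by the Euler-Maruyama discretisation of

    dx_i/dt = -grad H_i / gamma_i + sqrt(2 kB T / gamma_i) * zeta(t)

with per-bead Stokes friction ``gamma_i = 6 pi eta (d_i/2)`` (eta = 1 in
simulation units) and a fixed time step (1e-4 tau by default).  A run is
an annealing segment (discarded) followed by a production segment from
which snapshots are stored.  The inner loop lives in the compiled
kernel (`_kernels.run_segment`); this module packs parameters, owns the
random-seed bookkeeping, converts the enzyme registry to and from the
kernel's flat arrays, and exposes initialisation, single-step and
trajectory utilities.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .enzyme import BoundPair, Registry
from .geometry import Geometry
from .model import ModelParams, PolymerSequence
from .potentials import OverstretchError, PairState, WallPenetrationError, fene_energy

__all__ = [
    "Protocol",
    "SimulationState",
    "Trajectory",
    "init_conformation",
    "step",
    "run",
    "neighbor_candidates",
    "msd",
]

logger = logging.getLogger(__name__)

_VARIANT_CODE = {"PASSIVE": 0, "PHANTOM": 0, "NONTRANSIENT": 0,
                 "RANR": 1, "RAR": 2, "RNR": 3}
_EVENT_NAMES = {0: "bind", 1: "advance", 2: "unbind"}


@dataclass(frozen=True)
class Protocol:
    """Integration protocol: time step, durations (tau) and snapshot cadence."""

    dt: float = 1e-4
    anneal_duration: float = 2010.0
    production_duration: float = 2010.0
    snapshot_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.anneal_duration < 0 or self.production_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot interval must be positive")


@dataclass
class SimulationState:
    """Bead positions plus everything needed to continue a run."""

    positions: np.ndarray
    sequence: PolymerSequence
    registry: Registry = field(default_factory=Registry)
    time: float = 0.0
    step_count: int = 0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "species": self.sequence.species.tolist(),
            "block_size": self.sequence.block_size,
            "time": self.time,
            "step_count": self.step_count,
            "bound_pairs": [
                [p.i, p.j, p.state.name, p.bound_since] for p in self.registry
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationState":
        reg = Registry()
        for i, j, state, since in d.get("bound_pairs", []):
            reg.add(BoundPair(int(i), int(j), PairState[state], bound_since=float(since)))
        return cls(
            positions=np.asarray(d["positions"], dtype=float),
            sequence=PolymerSequence(np.asarray(d["species"]), int(d["block_size"])),
            registry=reg,
            time=float(d["time"]),
            step_count=int(d["step_count"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SimulationState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Trajectory:
    """Production snapshots of one run."""

    times: np.ndarray              # (S,)
    positions: np.ndarray          # (S, N, 3)
    species: np.ndarray            # (N,) of 'A'/'B'
    geometry: Geometry
    params: ModelParams | None = None
    protocol: Protocol | None = None
    events: list = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return int(self.times.size)

    def frames(self):
        for t, p in zip(self.times, self.positions):
            yield t, p


# ---------------------------------------------------------------------------
# Initialisation: equilibrated ideal chain
# ---------------------------------------------------------------------------

def _fene_bond_sampler(k: float, r0: float, n_grid: int = 4000):
    """Inverse-CDF sampler of the FENE Boltzmann bond-length density.

    For an ideal (non-interacting) chain the bond length distribution is
    exactly ``p(r) dr ~ r^2 exp(-h_spring(r)) dr`` on [0, r0).
    """
    r = np.linspace(0.0, r0 * (1.0 - 1e-9), n_grid)
    w = np.zeros_like(r)
    w[1:] = r[1:] ** 2 * np.exp(-fene_energy(r[1:], k, r0))
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(r))))
    cdf /= cdf[-1]
    # strictly increasing section for interpolation
    return lambda u: np.interp(u, cdf, r)


def init_conformation(
    seq: PolymerSequence,
    geometry: Geometry,
    seed: int,
    params: ModelParams,
    wall_margin: float = 0.1,
    max_retries: int = 500,
) -> SimulationState:
    """Random-walk initial conformation sampled from the ideal-chain measure.

    Bond lengths are drawn from the FENE Boltzmann weight (exact for an
    ideal chain), directions are isotropic, and any step that leaves the
    geometry (or comes within ``wall_margin`` of the wall) is resampled.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    codes = seq.codes
    n = seq.n_beads
    pos = np.empty((n, 3))
    pos[0] = geometry.random_point(rng, margin=wall_margin)
    samplers = {}
    for b in range(n - 1):
        pp = params.pair(codes[b], codes[b + 1])
        key = (pp.k, pp.r0)
        if key not in samplers:
            samplers[key] = _fene_bond_sampler(pp.k, pp.r0)
        sampler = samplers[key]
        for attempt in range(max_retries + 1):
            r = float(sampler(rng.random()))
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = pos[b] + r * v
            if geometry.wall_distance(geometry.wrap(cand))[0] > wall_margin:
                pos[b + 1] = geometry.wrap(cand)
                break
        else:
            raise RuntimeError(
                f"failed to place bead {b + 1} after {max_retries} retries; "
                "geometry too tight for the chain"
            )
    return SimulationState(positions=pos, sequence=seq)


# ---------------------------------------------------------------------------
# Kernel packing
# ---------------------------------------------------------------------------

def _pack(params: ModelParams, seq: PolymerSequence, dt: float, kT: float):
    codes = seq.codes
    n = seq.n_beads
    eps = np.zeros((2, 2))
    alpha = np.zeros((2, 2))
    for (si, sj), pp in params.pair_params.items():
        eps[si, sj] = eps[sj, si] = pp.eps_vex
        alpha[si, sj] = alpha[sj, si] = pp.alpha_vex
    if params.variant == "PHANTOM":
        eps[0, 0] = 0.0
    elif params.variant == "NONTRANSIENT":
        eps[0, 0] = params.nontransient_eps()
    k_spring = params.pair(0, 0).k
    diam = np.array([params.diameters[int(c)] for c in codes])
    bond_r0 = np.array(
        [params.pair(codes[i], codes[i + 1]).r0 for i in range(n - 1)]
    ) if n > 1 else np.zeros(0)
    gam = 3.0 * math.pi * diam  # 6 pi eta (d/2), eta = 1
    inv_gam = 1.0 / gam
    noise_amp = np.sqrt(2.0 * max(kT, 0.0) * dt / gam)
    conf_pre = np.zeros(2)
    conf_rs = np.ones(2)
    conf_a = np.zeros(2)
    conf_kappa = np.ones(2)
    conf_outer = np.zeros(2)
    from scipy.special import erfc

    for s, cp in params.confinement.items():
        conf_pre[s] = cp.prefactor
        conf_rs[s] = cp.Rs
        conf_a[s] = cp.a
        conf_kappa[s] = cp.kappa
        conf_outer[s] = (cp.prefactor * cp.gamma * 2.0 * cp.kappa
                         / (math.sqrt(math.pi) * erfc(cp.kappa * cp.Rs)))
    geom = params.geometry
    if geom.kind == "sphere":
        geom_args = (0, geom.radius, 0.0, 0.0, 0.0)
    else:
        geom_args = (1, 0.0, geom.lx, geom.ly, geom.lz)
    hc_c = (params.hc.d_b - 1.0 / (params.hc.alpha_hc * params.hc.d_b)
            if params.hc.alpha_hc > 0 else 0.0)
    return {
        "eps_vex": eps,
        "alpha_vex": alpha,
        "k_spring": k_spring,
        "bond_r0": bond_r0,
        "eps_hc": params.hc.eps_hc,
        "alpha_hc": params.hc.alpha_hc,
        "c_hc": hc_c,
        "conf": (conf_pre, conf_rs, conf_a, conf_kappa, conf_outer),
        "geom_args": geom_args,
        "inv_gam": inv_gam,
        "noise_amp": noise_amp,
    }


def _registry_to_arrays(registry: Registry):
    m = len(registry)
    bi = np.empty(m, dtype=np.int64)
    bj = np.empty(m, dtype=np.int64)
    bstate = np.empty(m, dtype=np.int8)
    for k, p in enumerate(sorted(registry, key=lambda q: (q.i, q.j))):
        bi[k], bj[k] = p.i, p.j
        bstate[k] = 1 if p.state is PairState.ATTRACTION else 2
    return bi, bj, bstate


def _arrays_to_registry(bi, bj, bstate, n_out: int, time: float) -> Registry:
    reg = Registry()
    order = np.lexsort((bj[:n_out], bi[:n_out]))
    for k in order:
        state = PairState.ATTRACTION if bstate[k] == 1 else PairState.NONE
        reg.add(BoundPair(int(bi[k]), int(bj[k]), state=state, bound_since=time),
                exclusive=False)
    return reg


def _segment(state: SimulationState, params: ModelParams, dt: float, kT: float,
             n_steps: int, seed: int, snap_every: int = 0, n_snaps: int = 0,
             record_events: bool = False, skin: float = 0.3):
    """Advance the state by ``n_steps`` inside one kernel call."""
    packed = _pack(params, state.sequence, dt, kT)
    n = state.n_beads
    bi, bj, bstate = _registry_to_arrays(state.registry)
    variant = _VARIANT_CODE[params.variant]
    p_ra = -math.expm1(-params.rates.lambda_ra * dt)
    p_an = -math.expm1(-params.rates.lambda_an * dt)
    p_nr = -math.expm1(-params.rates.lambda_nr * dt)
    out_cap = max(1024, n * 60)
    out_i = np.empty(out_cap, dtype=np.int64)
    out_j = np.empty(out_cap, dtype=np.int64)
    out_state = np.empty(out_cap, dtype=np.int8)
    snaps = np.empty((n_snaps, n, 3)) if n_snaps else np.empty((0, n, 3))
    snap_times = np.empty(max(n_snaps, 1))
    ev_cap = 500_000 if record_events else 1
    ev_step = np.empty(ev_cap, dtype=np.int64)
    ev_kind = np.empty(ev_cap, dtype=np.int8)
    ev_i = np.empty(ev_cap, dtype=np.int32)
    ev_j = np.empty(ev_cap, dtype=np.int32)
    conf_pre, conf_rs, conf_a, conf_kappa, conf_outer = packed["conf"]
    status, info, at_step, n_snap, n_ev, n_out = _kernels.run_segment(
        state.positions, state.sequence.codes, dt, kT, n_steps,
        packed["eps_vex"], packed["alpha_vex"], packed["k_spring"],
        packed["bond_r0"], params.chain,
        packed["eps_hc"], packed["alpha_hc"], packed["c_hc"],
        conf_pre, conf_rs, conf_a, conf_kappa, conf_outer,
        *packed["geom_args"],
        packed["inv_gam"], packed["noise_amp"],
        variant, p_ra, p_an, p_nr, params.exclude_neighbors,
        params.exclusive_binding,
        params.cutoff * params.cutoff,
        bi, bj, bstate,
        out_i, out_j, out_state,
        params.cutoff * params.cutoff, params.cutoff + skin,
        _kernels.EXP_TABLE,
        snap_every, snaps, snap_times, state.time,
        record_events, ev_step, ev_kind, ev_i, ev_j,
        seed,
    )
    if status == 1:
        raise OverstretchError(math.nan, float(packed["bond_r0"][info]) if
                               packed["bond_r0"].size else math.nan,
                               pair=(int(info), int(info) + 1),
                               step=state.step_count + at_step)
    if status == 2:
        raise WallPenetrationError(bead=int(info), step=state.step_count + at_step)
    if status == 3:
        raise RuntimeError("neighbour pair list overflowed; system unexpectedly dense")
    state.time += n_steps * dt
    state.step_count += n_steps
    state.registry = _arrays_to_registry(out_i, out_j, out_state, n_out, state.time)
    events = [
        (int(ev_step[m]), _EVENT_NAMES[int(ev_kind[m])], int(ev_i[m]), int(ev_j[m]))
        for m in range(n_ev)
    ]
    return snaps[:n_snap], snap_times[:n_snap], events


def step(state: SimulationState, params: ModelParams, protocol: Protocol,
         kT: float = 1.0, seed: int | None = None) -> SimulationState:
    """Advance the state by a single time step (testing convenience)."""
    if seed is None:
        seed = (protocol.seed * 2654435761 + state.step_count) % (2**31 - 1)
    _segment(state, params, protocol.dt, kT, 1, int(seed))
    return state


def run(state: SimulationState, params: ModelParams, protocol: Protocol,
        kT: float = 1.0, record_events: bool = False,
        soft_start: float = 0.5) -> Trajectory:
    """Anneal, then run production and collect snapshots.

    The first ``soft_start`` tau of the annealing span are integrated at
    a tenfold-reduced time step so the steric overlaps of the freshly
    drawn ideal-chain conformation relax without a bead being kicked
    through the wall's thin repulsive boundary layer; the remainder uses
    the protocol time step.  The annealing segment is discarded apart
    from a mean-square-displacement check against the cavity radius (a
    warning is logged when the rms bead displacement is below the
    radius, i.e. when the annealing span was likely too short to
    decorrelate the initial conformation).
    """
    dt = protocol.dt
    ss = np.random.SeedSequence(protocol.seed)
    anneal_seed, prod_seed, soft_seed = (
        int(s) % (2**31 - 1) for s in ss.generate_state(3))
    soft_span = min(soft_start, protocol.anneal_duration)
    n_soft = int(round(soft_span / (dt / 10.0)))
    n_anneal = int(round((protocol.anneal_duration - soft_span) / dt))
    if n_soft > 0 or n_anneal > 0:
        start = state.positions.copy()
        if n_soft > 0:
            _segment(state, params, dt / 10.0, kT, n_soft, soft_seed)
        if n_anneal > 0:
            _segment(state, params, dt, kT, n_anneal, anneal_seed)
        disp2 = float(np.mean(np.sum((state.positions - start) ** 2, axis=1)))
        if params.geometry.kind == "sphere":
            r = params.geometry.radius
            if disp2 < r * r:
                logger.warning(
                    "annealing check: rms bead displacement %.3g l is below the "
                    "cavity radius %.3g l; consider a longer annealing span",
                    math.sqrt(disp2), r,
                )
            else:
                logger.info("annealing check passed: msd %.3g l^2 > radius^2 %.3g l^2",
                            disp2, r * r)
    snap_every = max(1, int(round(protocol.snapshot_interval / dt)))
    n_prod = int(round(protocol.production_duration / dt))
    n_snaps = n_prod // snap_every
    if n_prod > 0:
        snaps, times, events = _segment(
            state, params, dt, kT, n_prod, prod_seed,
            snap_every=snap_every, n_snaps=n_snaps, record_events=record_events,
        )
    else:
        snaps = np.empty((0, state.n_beads, 3))
        times = np.empty(0)
        events = []
    logger.info("run complete: t=%.4g tau, %d snapshots, %d bound pairs",
                state.time, snaps.shape[0], len(state.registry))
    return Trajectory(
        times=times,
        positions=snaps,
        species=state.sequence.species.copy(),
        geometry=params.geometry,
        params=params,
        protocol=protocol,
        events=events,
    )


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

def neighbor_candidates(positions: np.ndarray, cutoff: float,
                        geometry: Geometry | None = None) -> list[tuple[int, int]]:
    """All pairs within the cutoff (exact, for tests and analysis).

    Uses a k-d tree in open geometries and a brute-force minimum-image
    scan for periodic slabs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        return []
    if geometry is None or not any(geometry.periodic):
        tree = cKDTree(pos)
        return sorted(tree.query_pairs(r=cutoff))
    out = []
    for i in range(pos.shape[0] - 1):
        d = geometry.separation(pos[i + 1:], pos[i])
        r = np.linalg.norm(d, axis=1)
        for j in np.nonzero(r <= cutoff)[0]:
            out.append((i, i + 1 + int(j)))
    return sorted(out)


def msd(trajectory: Trajectory, reference_index: int = 0):
    """Mean square displacement versus the reference snapshot.

    Returns ``(per_bead, mean)`` with shapes (S, N) and (S,).
    """
    pos = trajectory.positions
    if pos.shape[0] < 2:
        raise ValueError("need at least two snapshots")
    ref = pos[reference_index]
    per_bead = np.sum((pos - ref) ** 2, axis=2)
    return per_bead, per_bead.mean(axis=1)
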