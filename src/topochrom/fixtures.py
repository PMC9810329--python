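"""Deterministic synthetic configurations for exercising the analysis suite.

Each generator builds a snapshot (positions + species) or raw field with
a known analytic signature: perfectly mixed spheres, sharp two-phase
partitions, bond sets with prescribed nematic order, collinear or
ball-shaped clusters, and Gaussian order-parameter fields.  They are the
test surface for the analysis operations and are also exposed through
the ``make-fixture`` CLI command.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Sphere

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "uniform_mixture",
    "two_phase_sphere",
    "shell_wall_bonds",
    "planar_bonds",
    "line_cluster",
    "ball_cluster",
    "gaussian_field",
]


@dataclass
class FixtureSpec:
    generator: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def uniform_mixture(n: int = 4000, radius: float = 4.0, phi_a: float = 0.5,
                    seed: int = 0):
    """Well-mixed A/B beads uniform in a sphere; delta_phi is unimodal."""
    rng = np.random.default_rng(seed)
    pos = _uniform_ball(rng, n, radius)
    species = np.where(rng.random(n) < phi_a, "A", "B").astype("<U1")
    return pos, species, Sphere(diameter=2 * radius)


def two_phase_sphere(n: int = 4000, radius: float = 4.0, core_fraction: float = 0.5,
                     seed: int = 0):
    """Sharp two-phase partition: B in a central core, A in the outer shell.

    ``core_fraction`` is the volume fraction of the B core, so the
    boundary radius is ``radius * core_fraction^(1/3)``.
    """
    rng = np.random.default_rng(seed)
    pos = _uniform_ball(rng, n, radius)
    r_core = radius * core_fraction ** (1.0 / 3.0)
    species = np.where(np.linalg.norm(pos, axis=1) < r_core, "B", "A").astype("<U1")
    return pos, species, Sphere(diameter=2 * radius)


def _chain_with_bonds(midpoints: np.ndarray, directions: np.ndarray,
                      bond_length: float):
    """Chain whose AA bonds realise the given midpoints/directions.

    Species pattern A,A,B repeating: each (A, A) pair carries one test
    bond; the trailing B bead breaks the chain so no spurious AA bond
    forms between consecutive test bonds.
    """
    n_bonds = midpoints.shape[0]
    pos = np.empty((3 * n_bonds, 3))
    species = np.empty(3 * n_bonds, dtype="<U1")
    for k in range(n_bonds):
        u = directions[k] / np.linalg.norm(directions[k])
        pos[3 * k] = midpoints[k] - 0.5 * bond_length * u
        pos[3 * k + 1] = midpoints[k] + 0.5 * bond_length * u
        pos[3 * k + 2] = midpoints[k]
        species[3 * k: 3 * k + 3] = ("A", "A", "B")
    return pos, species


def shell_wall_bonds(n_bonds: int = 4000, radius: float = 4.0,
                     shell_radius: float = 3.0, bond_length: float = 0.4,
                     seed: int = 0):
    """AA bonds tangent to a sphere: planar-isotropic locally, S < 0."""
    rng = np.random.default_rng(seed)
    normal = rng.normal(size=(n_bonds, 3))
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    mids = shell_radius * normal
    # random direction orthogonal to the local normal
    t = rng.normal(size=(n_bonds, 3))
    t -= np.sum(t * normal, axis=1, keepdims=True) * normal
    pos, species = _chain_with_bonds(mids, t, bond_length)
    return pos, species, Sphere(diameter=2 * radius)


def planar_bonds(n_bonds: int = 4000, radius: float = 4.0, bond_length: float = 0.4,
                 seed: int = 0):
    """AA bonds isotropic in the xy-plane, midpoints in one cell: S = -1/2."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_bonds)
    dirs = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n_bonds)])
    mids = rng.uniform(-0.3, 0.3, size=(n_bonds, 3))
    pos, species = _chain_with_bonds(mids, dirs, bond_length)
    return pos, species, Sphere(diameter=2 * radius)


def line_cluster(n: int = 50, spacing: float = 0.3, seed: int = 0):
    """Collinear, equally spaced B beads: shape anisotropy kappa^2 = 1."""
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    species = np.full(n, "B", dtype="<U1")
    return pos, species, Sphere(diameter=4 * max(1.0, spacing * n))


def ball_cluster(n: int = 10000, radius: float = 1.5, seed: int = 0):
    """B beads uniformly filling a ball: kappa^2 close to 0."""
    rng = np.random.default_rng(seed)
    pos = _uniform_ball(rng, n, radius)
    species = np.full(n, "B", dtype="<U1")
    return pos, species, Sphere(diameter=6 * radius)


def gaussian_field(n_cells: int = 100000, sigma: float = 0.3, seed: int = 0):
    """Raw order-parameter samples from a centred Gaussian (Binder ~ 0)."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, sigma, n_cells)
    weights = np.ones(n_cells)
    return values, weights


GENERATORS = {
    "uniform_mixture": uniform_mixture,
    "two_phase_sphere": two_phase_sphere,
    "shell_wall_bonds": shell_wall_bonds,
    "planar_bonds": planar_bonds,
    "line_cluster": line_cluster,
    "ball_cluster": ball_cluster,
    "gaussian_field": gaussian_field,
}


def make_fixture(spec: FixtureSpec):
    """Dispatch a named generator; deterministic under ``spec.seed``."""
    if spec.generator not in GENERATORS:
        raise ValueError(
            f"unknown fixture generator {spec.generator!r}; "
            f"choose from {sorted(GENERATORS)}"
        )
    return GENERATORS[spec.generator](seed=spec.seed, **spec.params)
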