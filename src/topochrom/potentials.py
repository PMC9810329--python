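"""Interaction potentials and their analytic radial forces.

Four terms act on a bead: the FENE bond to its chain neighbours, a
truncated Gaussian excluded-volume potential whose sign/presence depends
on the Topoisomerase-II pair state, a short-range heterochromatin
affinity between B beads, and a star-polymer wall potential confining
the chain inside the cavity.  Energies are in units of e = kB*T, lengths
in l, so forces are e/l.

Conventions: "force" functions return the radial component dE/dr with a
minus sign, i.e. a positive value pushes the pair apart (or the bead
away from the wall).  The Gaussian and affinity potentials are truncated
(not shifted) at the cutoff, exactly as defined piecewise; the residual
jump at the cutoff is the truncated tail eps*exp(-alpha*cutoff^2).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc


class PairState(enum.Enum):
    """Interaction state of a bead pair under the Topo-II scheme.

    Unbound pairs (and all AB/BB pairs) are ``REPULSION``; a pair bound
    to an enzyme is either in the ``ATTRACTION`` (sign-flipped Gaussian)
    or the ``NONE`` (no steric interaction) state.
    """

    REPULSION = 1
    ATTRACTION = -1
    NONE = 0

    @property
    def sign(self) -> int:
        return self.value


class OverstretchError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension r0."""

    def __init__(self, r, r0, pair=None, step=None):
        self.r, self.r0, self.pair, self.step = r, r0, pair, step
        msg = f"FENE bond overstretched: r={r} >= r0={r0}"
        if pair is not None:
            msg += f" (beads {pair})"
        if step is not None:
            msg += f" at step {step}"
        super().__init__(msg)


class WallPenetrationError(RuntimeError):
    """A bead reached or crossed the confinement wall."""

    def __init__(self, bead=None, step=None):
        self.bead, self.step = bead, step
        msg = "bead at or beyond the confinement wall"
        if bead is not None:
            msg += f" (bead {bead})"
        if step is not None:
            msg += f" at step {step}"
        super().__init__(msg)


# ---------------------------------------------------------------------------
# FENE bond
# ---------------------------------------------------------------------------

def fene_energy(r, k: float, r0: float):
    """FENE bond energy ``-(1/2) k r0^2 ln(1 - (r/r0)^2)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= r0):
        bad = float(np.max(r))
        raise OverstretchError(bad, r0)
    return -0.5 * k * r0**2 * np.log1p(-((r / r0) ** 2))


def fene_force(r, k: float, r0: float):
    """Radial force ``-dE/dr = -k r / (1 - (r/r0)^2)`` (always attractive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= r0):
        raise OverstretchError(float(np.max(r)), r0)
    return -k * r / (1.0 - (r / r0) ** 2)


# ---------------------------------------------------------------------------
# Gaussian excluded volume / transient attraction
# ---------------------------------------------------------------------------

def vex_energy(r, state: PairState, eps_vex: float, alpha_vex: float, cutoff: float = 1.0):
    """State-dependent Gaussian pair energy, truncated at the cutoff."""
    r = np.asarray(r, dtype=float)
    val = state.sign * eps_vex * np.exp(-alpha_vex * r**2)
    return np.where(r <= cutoff, val, 0.0)


def vex_force(r, state: PairState, eps_vex: float, alpha_vex: float, cutoff: float = 1.0):
    """Radial force ``-dE/dr = sign * 2 eps alpha r exp(-alpha r^2)``."""
    r = np.asarray(r, dtype=float)
    val = state.sign * 2.0 * eps_vex * alpha_vex * r * np.exp(-alpha_vex * r**2)
    return np.where(r <= cutoff, val, 0.0)


# ---------------------------------------------------------------------------
# Heterochromatin affinity (BB pairs)
# ---------------------------------------------------------------------------

def _hc_center(alpha_hc: float, d_b: float) -> float:
    # Gaussian centre shifted so the full expression is minimised exactly at r=d_b
    return d_b - 1.0 / (alpha_hc * d_b)


def hc_energy(r, eps_hc: float, alpha_hc: float, d_b: float, cutoff: float = 1.0):
    """Heterochromatin affinity ``-eps r^2 exp[-alpha (c - r)^2]``, c = d_b - 1/(alpha d_b).

    The r^2 prefactor shifts the minimum of the bare Gaussian so that the
    full potential is minimised at ``r = d_b``, i.e. exactly where the
    bond-plus-repulsion minimum sits, leaving the bead sizing untouched.
    Applies to BB pairs only (enforced by the caller).
    """
    r = np.asarray(r, dtype=float)
    c = _hc_center(alpha_hc, d_b)
    val = -eps_hc * r**2 * np.exp(-alpha_hc * (c - r) ** 2)
    return np.where(r <= cutoff, val, 0.0)


def hc_force(r, eps_hc: float, alpha_hc: float, d_b: float, cutoff: float = 1.0):
    """Radial force ``-dE/dr = 2 eps r exp[-alpha (c-r)^2] (1 + alpha r (c - r))``."""
    r = np.asarray(r, dtype=float)
    c = _hc_center(alpha_hc, d_b)
    val = 2.0 * eps_hc * r * np.exp(-alpha_hc * (c - r) ** 2) * (1.0 + alpha_hc * r * (c - r))
    return np.where(r <= cutoff, val, 0.0)


# ---------------------------------------------------------------------------
# Star-polymer wall confinement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfinementParams:
    """Wall potential parameters for one bead species.

    The bead is treated as a star polymer of functionality ``s`` (=2, a
    linear chain) with corona radius ``Rs = 0.65*Rg`` and screening
    parameter ``kappa ~ 1/Rg``, ``Rg = d/2``.  ``gamma`` is fixed by
    requiring the two branches to join with a continuous derivative at
    ``r = Rs``.
    """

    p: float
    s: float
    Rs: float
    kappa: float

    def __post_init__(self) -> None:
        if self.p < 0 or self.s <= 0 or self.Rs <= 0 or self.kappa <= 0:
            raise ValueError("invalid confinement parameters")

    @property
    def prefactor(self) -> float:
        """``p * s^(3/2)``."""
        return self.p * self.s**1.5

    @property
    def a(self) -> float:
        """``1 / (1 + 2 kappa^2 Rs^2)``."""
        return 1.0 / (1.0 + 2.0 * self.kappa**2 * self.Rs**2)

    @property
    def gamma(self) -> float:
        """``sqrt(pi) erfc(kRs) exp(k^2 Rs^2) / [kRs (1 + 2 k^2 Rs^2)]``."""
        x = self.kappa * self.Rs
        return math.sqrt(math.pi) * erfc(x) * math.exp(x**2) / (x * (1.0 + 2.0 * x**2))

    @classmethod
    def for_bead(cls, diameter: float, p: float = 4.0, s: float = 2.0,
                 rs_factor: float = 0.65) -> "ConfinementParams":
        rg = 0.5 * diameter
        return cls(p=p, s=s, Rs=rs_factor * rg, kappa=1.0 / rg)


def confinement_energy(r_wall, cp: ConfinementParams):
    """Wall potential at distance ``r_wall`` from the wall (must be > 0)."""
    r = np.asarray(r_wall, dtype=float)
    if np.any(r <= 0):
        raise WallPenetrationError()
    pre = cp.prefactor
    inner = pre * (
        -np.log(r / cp.Rs)
        - ((r / cp.Rs) ** 2 - 1.0) * (cp.a - 0.5)
        + cp.gamma
    )
    outer = pre * cp.gamma * erfc(cp.kappa * r) / erfc(cp.kappa * cp.Rs)
    return np.where(r <= cp.Rs, inner, outer)


def confinement_force(r_wall, cp: ConfinementParams):
    """Radial force ``-dE/dr_wall`` (positive: pushes the bead off the wall)."""
    r = np.asarray(r_wall, dtype=float)
    if np.any(r <= 0):
        raise WallPenetrationError()
    pre = cp.prefactor
    inner = pre * (1.0 / r + 2.0 * r / cp.Rs**2 * (cp.a - 0.5))
    outer = (
        pre
        * cp.gamma
        * 2.0
        * cp.kappa
        / math.sqrt(math.pi)
        * np.exp(-(cp.kappa * r) ** 2)
        / erfc(cp.kappa * cp.Rs)
    )
    return np.where(r <= cp.Rs, inner, outer)


# ---------------------------------------------------------------------------
# System totals (brute-force reference implementation)
# ---------------------------------------------------------------------------

def _pair_sign(i, j, species, bound):
    if species[i] == 0 and species[j] == 0 and bound:
        key = (min(i, j), max(i, j))
        state = bound.get(key)
        if state is not None:
            return state.sign
    return 1


def total_energy(positions, species, params, bound=None) -> float:
    """System potential energy, each pair interaction counted once.

    Brute-force O(N^2) reference used for validation; the production
    integrator carries its own cell-list implementation.

    Parameters
    ----------
    positions : (N, 3) array in l units.
    species : (N,) int array, 0 for A and 1 for B.
    params : :class:`~topochrom.model.ModelParams`
    bound : optional dict mapping (i, j) with i<j to :class:`PairState`.
    """
    pos = np.asarray(positions, dtype=float)
    spec = np.asarray(species)
    n = pos.shape[0]
    geom = params.geometry
    cutoff = params.cutoff
    e = 0.0
    # bonds
    if params.chain and n > 1:
        for i in range(n - 1):
            d = geom.separation(pos[i], pos[i + 1])
            r = float(np.linalg.norm(d))
            pp = params.pair(spec[i], spec[i + 1])
            if r >= pp.r0:
                raise OverstretchError(r, pp.r0, pair=(i, i + 1))
            e += float(fene_energy(r, pp.k, pp.r0))
    # nonbonded pairs
    bound = bound if bound is not None else {}
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = geom.separation(pos[i], pos[j])
            r = float(np.linalg.norm(d))
            if r > cutoff:
                continue
            pp = params.pair(spec[i], spec[j])
            sign = _pair_sign(i, j, spec, bound)
            if pp.eps_vex != 0.0 and sign != 0:
                e += sign * pp.eps_vex * math.exp(-pp.alpha_vex * r * r)
            if spec[i] == 1 and spec[j] == 1 and params.hc.eps_hc != 0.0:
                e += float(hc_energy(r, params.hc.eps_hc, params.hc.alpha_hc,
                                     params.hc.d_b, cutoff))
    # confinement (slab: both walls contribute)
    rw = geom.wall_distance(pos)
    if np.any(rw <= 0):
        raise WallPenetrationError(bead=int(np.argmin(rw)))
    for i in range(n):
        cp = params.confinement[int(spec[i])]
        if geom.kind == "sphere":
            e += float(confinement_energy(rw[i], cp))
        else:
            z = pos[i, 2]
            e += float(confinement_energy(z, cp))
            e += float(confinement_energy(geom.lz - z, cp))
    return e


def total_forces(positions, species, params, bound=None) -> np.ndarray:
    """Per-bead forces, minus the gradient of :func:`total_energy`."""
    pos = np.asarray(positions, dtype=float)
    spec = np.asarray(species)
    n = pos.shape[0]
    geom = params.geometry
    cutoff = params.cutoff
    f = np.zeros_like(pos)
    if params.chain and n > 1:
        for i in range(n - 1):
            d = geom.separation(pos[i], pos[i + 1])
            r = float(np.linalg.norm(d))
            pp = params.pair(spec[i], spec[i + 1])
            if r >= pp.r0:
                raise OverstretchError(r, pp.r0, pair=(i, i + 1))
            coef = -pp.k / (1.0 - (r / pp.r0) ** 2)
            f[i] += coef * d
            f[i + 1] -= coef * d
    bound = bound if bound is not None else {}
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = geom.separation(pos[i], pos[j])
            r2 = float(np.dot(d, d))
            if r2 > cutoff * cutoff:
                continue
            pp = params.pair(spec[i], spec[j])
            sign = _pair_sign(i, j, spec, bound)
            if pp.eps_vex != 0.0 and sign != 0:
                coef = sign * 2.0 * pp.eps_vex * pp.alpha_vex * math.exp(-pp.alpha_vex * r2)
                f[i] += coef * d
                f[j] -= coef * d
            if spec[i] == 1 and spec[j] == 1 and params.hc.eps_hc != 0.0:
                r = math.sqrt(r2)
                c = _hc_center(params.hc.alpha_hc, params.hc.d_b)
                coef = (
                    2.0
                    * params.hc.eps_hc
                    * math.exp(-params.hc.alpha_hc * (c - r) ** 2)
                    * (1.0 + params.hc.alpha_hc * r * (c - r))
                )
                f[i] += coef * d
                f[j] -= coef * d
    rw = geom.wall_distance(pos)
    if np.any(rw <= 0):
        raise WallPenetrationError(bead=int(np.argmin(rw)))
    for i in range(n):
        cp = params.confinement[int(spec[i])]
        if geom.kind == "sphere":
            rad = float(np.linalg.norm(pos[i]))
            if rad > 0:
                mag = float(confinement_force(rw[i], cp))
                f[i] += -mag * pos[i] / rad
        else:  # slab: walls at z=0 and z=lz both act
            z = pos[i, 2]
            f[i, 2] += float(confinement_force(z, cp))
            f[i, 2] -= float(confinement_force(geom.lz - z, cp))
    return f
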