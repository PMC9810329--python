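"""Simulation unit system and parameter derivations.

The simulator works in reduced units: length ``l`` (one twelfth of the
chromatin-territory cavity diameter), energy ``e`` (the thermal energy
``kB*T`` at physiological temperature) and time ``tau`` (the diffusive
time scale ``eta*l^3/e`` set by the nucleoplasmic viscosity).  This
module derives those units from printed physical constants, converts
bead sizes from base-pair content, and holds the Topoisomerase-II rate
bookkeeping (enzymatic activity, mean state dwell times) together with
the transcendental potential-matching constraint that fixes the width
of the Gaussian excluded-volume potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "KB_PN_NM_PER_K",
    "UnitSystem",
    "BeadSpec",
    "EnzymeRates",
    "PotentialMatchingError",
    "thermal_energy",
    "length_unit_from_cavity",
    "time_unit",
    "cavity_diameter",
    "bead_bp",
    "bead_diameter_from_bp",
    "activity",
    "dwell_means",
    "solve_alpha_vex",
]

#: Boltzmann constant in pN*nm per kelvin (1.380649e-23 J/K).
KB_PN_NM_PER_K = 1.380649e-2


def thermal_energy(temperature_K: float) -> float:
    """Thermal energy ``kB*T`` in pN*nm.

    Parameters
    ----------
    temperature_K:
        Absolute temperature in kelvin; must be positive.
    """
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return KB_PN_NM_PER_K * temperature_K


def length_unit_from_cavity(d_ct_nm: float, divisor: int = 12) -> float:
    """Length unit in nm from the cavity diameter, ``l = d_ct / divisor``."""
    if d_ct_nm <= 0:
        raise ValueError(f"cavity diameter must be positive, got {d_ct_nm}")
    if divisor < 1:
        raise ValueError(f"divisor must be >= 1, got {divisor}")
    return d_ct_nm / divisor


def time_unit(viscosity_cP: float, length_nm: float, energy_pNnm: float) -> float:
    """Simulation time unit ``tau = eta * l^3 / e`` in milliseconds.

    ``eta*l^3/e`` is the diffusive time over one length unit for a
    particle with friction ``eta*l``; with the nucleoplasmic viscosity
    1.5 cP, ``l`` = 117.6 nm and ``e`` = 4.28 pN*nm it evaluates to
    0.57 ms.
    """
    if viscosity_cP <= 0 or length_nm <= 0 or energy_pNnm <= 0:
        raise ValueError("viscosity, length and energy must all be positive")
    eta_SI = viscosity_cP * 1e-3          # Pa*s
    l_SI = length_nm * 1e-9               # m
    e_SI = energy_pNnm * 1e-21            # J
    return eta_SI * l_SI**3 / e_SI * 1e3  # s -> ms


def cavity_diameter(
    chromatin_bp: float,
    genome_bp: float = 6.2e9,
    nucleus_diameter_um: float = 7.0,
) -> float:
    """Chromatin-territory cavity diameter in micrometres.

    The cavity volume is the nuclear volume scaled by the fraction of
    the diploid genome the modelled chromatin represents, so the
    diameter scales with the cube root of the base-pair ratio.
    """
    if chromatin_bp <= 0 or genome_bp <= 0 or nucleus_diameter_um <= 0:
        raise ValueError("all arguments must be positive")
    return nucleus_diameter_um * (chromatin_bp / genome_bp) ** (1.0 / 3.0)


def bead_bp(total_bp: float, n_beads: int) -> float:
    """DNA content per bead (bp) for a chain of ``n_beads`` beads."""
    if n_beads < 1:
        raise ValueError(f"bead count must be >= 1, got {n_beads}")
    return total_bp / n_beads


def bead_diameter_from_bp(
    bp_per_bead: float,
    d_nucleosome_nm: float = 22.0,
    bp_per_nucleosome: float = 200.0,
) -> float:
    """Bead diameter (nm) from its DNA content.

    Assumes close compaction of nucleosomes (22 nm spheres holding
    200 bp each) inside the bead, so the bead volume is the summed
    nucleosome volume: ``d = d_nuc * (n_nucleosomes)^(1/3)``.
    """
    if bp_per_bead <= 0 or d_nucleosome_nm <= 0 or bp_per_nucleosome <= 0:
        raise ValueError("all arguments must be positive")
    return d_nucleosome_nm * (bp_per_bead / bp_per_nucleosome) ** (1.0 / 3.0)


@dataclass(frozen=True)
class UnitSystem:
    """The reduced unit system (length, energy, time) with its physical anchors.

    Attributes
    ----------
    length_unit_nm:
        ``l`` in nm (117.6 nm for the default cavity).
    energy_unit_pNnm:
        ``e = kB*T`` in pN*nm (4.28 at 310 K).
    time_unit_ms:
        ``tau = eta*l^3/e`` in ms (0.57 for 1.5 cP nucleoplasm).
    temperature_K, viscosity_cP:
        The physical conditions the units were derived from.
    """

    length_unit_nm: float
    energy_unit_pNnm: float
    time_unit_ms: float
    temperature_K: float
    viscosity_cP: float

    def __post_init__(self) -> None:
        for name in (
            "length_unit_nm",
            "energy_unit_pNnm",
            "time_unit_ms",
            "temperature_K",
            "viscosity_cP",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_conditions(
        cls,
        temperature_K: float = 310.0,
        cavity_diameter_nm: float = 1411.2,
        divisor: int = 12,
        viscosity_cP: float = 1.5,
    ) -> "UnitSystem":
        ell = length_unit_from_cavity(cavity_diameter_nm, divisor)
        e = thermal_energy(temperature_K)
        tau = time_unit(viscosity_cP, ell, e)
        return cls(
            length_unit_nm=ell,
            energy_unit_pNnm=e,
            time_unit_ms=tau,
            temperature_K=temperature_K,
            viscosity_cP=viscosity_cP,
        )

    def to_nm(self, length_l: float) -> float:
        return length_l * self.length_unit_nm

    def to_l(self, length_nm: float) -> float:
        return length_nm / self.length_unit_nm


@dataclass(frozen=True)
class BeadSpec:
    """One bead species: its diameter (both unit systems) and DNA content."""

    species: str
    diameter_l: float
    diameter_nm: float
    bp_content: float = math.nan

    def __post_init__(self) -> None:
        if self.species not in ("A", "B"):
            raise ValueError(f"species must be 'A' or 'B', got {self.species!r}")
        if self.diameter_l <= 0 or self.diameter_nm <= 0:
            raise ValueError("bead diameters must be strictly positive")

    @property
    def volume_l3(self) -> float:
        """Bead volume ``(pi/6) d^3`` in l^3."""
        return math.pi / 6.0 * self.diameter_l**3

    @classmethod
    def from_bp(
        cls,
        species: str,
        bp_per_bead: float,
        units: UnitSystem,
        d_nucleosome_nm: float = 22.0,
        bp_per_nucleosome: float = 200.0,
    ) -> "BeadSpec":
        d_nm = bead_diameter_from_bp(bp_per_bead, d_nucleosome_nm, bp_per_nucleosome)
        return cls(species, units.to_l(d_nm), d_nm, bp_per_bead)

    @classmethod
    def from_nm(cls, species: str, diameter_nm: float, units: UnitSystem) -> "BeadSpec":
        return cls(species, units.to_l(diameter_nm), diameter_nm)


@dataclass(frozen=True)
class EnzymeRates:
    """Topoisomerase-II transition rates (per tau).

    ``lambda_ra`` is the catch rate (repulsion -> attraction),
    ``lambda_an`` the attraction -> no-interaction rate and
    ``lambda_nr`` the release rate (no-interaction -> repulsion).
    """

    lambda_ra: float
    lambda_an: float = 16.7
    lambda_nr: float = 500.0

    def __post_init__(self) -> None:
        for name in ("lambda_ra", "lambda_an", "lambda_nr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def activity(self) -> float:
        """Enzymatic activity ``Lambda = lambda_ra*(1/lambda_an + 1/lambda_nr)``."""
        if self.lambda_an <= 0 or self.lambda_nr <= 0:
            raise ValueError("lambda_an and lambda_nr must be > 0 to define activity")
        return self.lambda_ra * (1.0 / self.lambda_an + 1.0 / self.lambda_nr)

    def dwell_means(self) -> tuple[float, float]:
        """Mean dwell times (tau) in the attraction and no-interaction states."""
        if self.lambda_an <= 0 or self.lambda_nr <= 0:
            raise ValueError("dwell means require strictly positive exit rates")
        return (1.0 / self.lambda_an, 1.0 / self.lambda_nr)

    @classmethod
    def from_activity(
        cls,
        activity: float,
        lambda_an: float = 16.7,
        lambda_nr: float = 500.0,
    ) -> "EnzymeRates":
        """Back out the catch rate from a target activity at fixed exit rates."""
        bound_time = 1.0 / lambda_an + 1.0 / lambda_nr
        return cls(activity / bound_time, lambda_an, lambda_nr)


def activity(rates: EnzymeRates) -> float:
    """Functional form of :attr:`EnzymeRates.activity`."""
    return rates.activity


def dwell_means(rates: EnzymeRates) -> tuple[float, float]:
    """Functional form of :meth:`EnzymeRates.dwell_means`."""
    return rates.dwell_means()


class PotentialMatchingError(ValueError):
    """The bead-sizing constraint has no real solution for the given parameters."""


def solve_alpha_vex(
    k: float,
    eps_vex: float,
    d_i: float,
    d_j: float,
    root: str = "larger",
) -> float:
    """Width of the Gaussian excluded-volume potential from the sizing criterion.

    The bead diameters are fixed by requiring the minimum of the bond
    potential plus the pair repulsion to sit at ``rm = (d_i + d_j)/2``,
    with the bond's maximum extension ``r0 = d_i + d_j``.  That gives

        ``k*rm^2 / (1 - rm^2/r0^2) = 2*eps_vex*alpha*rm^2*exp(-alpha*rm^2)``

    which, in ``x = alpha*rm^2``, reads ``x*exp(-x) = G/(2*eps_vex)`` and
    has two positive roots straddling the maximiser ``x = 1`` whenever
    the right-hand side stays below ``1/e``.  The larger root (narrower,
    steeper Gaussian) is the one tabulated for the production models.

    Parameters
    ----------
    k:
        Bond spring constant (e/l^2).
    eps_vex:
        Gaussian repulsion amplitude (e).
    d_i, d_j:
        Diameters of the two connected beads (l).
    root:
        ``"larger"`` (default) or ``"smaller"`` branch.

    Returns
    -------
    float
        ``alpha_vex`` in l^-2.
    """
    if k <= 0 or eps_vex <= 0 or d_i <= 0 or d_j <= 0:
        raise ValueError("k, eps_vex and the diameters must be positive")
    if root not in ("larger", "smaller"):
        raise ValueError(f"root must be 'larger' or 'smaller', got {root!r}")
    rm = 0.5 * (d_i + d_j)
    r0 = d_i + d_j
    G = k * rm**2 / (1.0 - (rm / r0) ** 2)
    target = G / (2.0 * eps_vex)  # value x*exp(-x) must reach
    max_attainable = 1.0 / math.e
    if target > max_attainable:
        raise PotentialMatchingError(
            "no real solution: the constraint requires "
            f"x*exp(-x) = {target:.6g} but its maximum is 1/e = {max_attainable:.6g} "
            f"(equivalently G = {G:.6g} exceeds 2*eps_vex/e = "
            f"{2.0 * eps_vex / math.e:.6g})"
        )

    def g(x: float) -> float:
        return x * math.exp(-x) - target

    if root == "smaller":
        lo = 1e-12
        x = brentq(g, lo, 1.0, xtol=1e-15, rtol=8.9e-16)
    else:
        hi = 2.0
        while g(hi) > 0.0:
            hi *= 2.0
        x = brentq(g, 1.0, hi, xtol=1e-15, rtol=8.9e-16)
    return x / rm**2
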