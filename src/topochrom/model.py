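"""Polymer construction and the complete per-run parameter set.

The chromatin fibre is a random multiblock copolymer: euchromatic (A)
and heterochromatic (B) beads appear in blocks of ``b`` beads whose
order along the chain is a uniformly random permutation.  The
composition ``phi_A`` is a volume fraction, so for the bidisperse model
the bead counts follow from the bead volumes.  :class:`ModelParams`
gathers everything a run needs: per-pair potential constants, the
heterochromatin affinity, wall confinement, enzyme rates, geometry,
model variant and the interaction cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Geometry, Sphere
from .potentials import ConfinementParams
from .units import EnzymeRates, UnitSystem

__all__ = [
    "PolymerSequence",
    "PairParams",
    "HCParams",
    "ModelParams",
    "VARIANTS",
    "generate_sequence",
    "composition",
    "bidisperse_counts",
    "composition_from_rdf",
    "monodisperse_params",
    "bidisperse_params",
    "scaled_cavity_diameter",
    "MONODISPERSE_TABLE",
    "BIDISPERSE_TABLE",
]

#: Supported dynamics variants.  RANR is the full three-state catch-and-release
#: scheme; RAR and RNR are its two-state reductions; PHANTOM switches off AA
#: steric repulsion permanently (equilibrium self-avoiding/phantom mixture);
#: NONTRANSIENT replaces the kinetics by the cycle-averaged static AA potential;
#: PASSIVE has no enzymatic activity at all.
VARIANTS = ("PASSIVE", "RANR", "RAR", "RNR", "PHANTOM", "NONTRANSIENT")

_SPECIES_CODE = {"A": 0, "B": 1}


@dataclass(frozen=True)
class PolymerSequence:
    """Ordered A/B species labels of the chain, with block metadata."""

    species: np.ndarray  # (N,) array of 'A'/'B'
    block_size: int

    def __post_init__(self) -> None:
        spec = np.asarray(self.species, dtype="<U1")
        object.__setattr__(self, "species", spec)
        if spec.ndim != 1 or spec.size == 0:
            raise ValueError("species must be a non-empty 1-D array")
        if not set(np.unique(spec)) <= {"A", "B"}:
            raise ValueError("species labels must be 'A' or 'B'")
        if self.block_size < 1 or spec.size % self.block_size:
            raise ValueError("N must be a positive multiple of the block size")

    @property
    def n_beads(self) -> int:
        return int(self.species.size)

    @property
    def codes(self) -> np.ndarray:
        """Integer codes (A=0, B=1)."""
        return (self.species == "B").astype(np.int8)

    def counts(self) -> tuple[int, int]:
        nb = int(np.count_nonzero(self.species == "B"))
        return self.n_beads - nb, nb

    def run_lengths(self) -> list[tuple[str, int]]:
        """Maximal same-species runs as (label, length) pairs."""
        out = []
        s = self.species
        start = 0
        for i in range(1, s.size + 1):
            if i == s.size or s[i] != s[start]:
                out.append((str(s[start]), i - start))
                start = i
        return out

    def check_block_structure(self) -> bool:
        """True iff every maximal run length is a multiple of the block size."""
        return all(length % self.block_size == 0 for _, length in self.run_lengths())


@dataclass(frozen=True)
class PairParams:
    """Potential constants for one species pair (e, l units)."""

    eps_vex: float
    alpha_vex: float
    k: float
    r0: float


@dataclass(frozen=True)
class HCParams:
    """Heterochromatin affinity constants; ``d_b`` locates the minimum."""

    eps_hc: float
    alpha_hc: float
    d_b: float


@dataclass(frozen=True)
class ModelParams:
    """Single source of truth for one simulation run."""

    pair_params: dict  # (si, sj) species-code tuple -> PairParams
    hc: HCParams
    confinement: dict  # species code -> ConfinementParams
    rates: EnzymeRates
    geometry: Geometry
    variant: str = "RANR"
    cutoff: float = 1.0
    phi_A: float = 0.5
    diameters: dict = field(default_factory=dict)  # species code -> diameter (l)
    exclude_neighbors: bool = True
    exclusive_binding: bool = False  # sensitivity flag: one bound pair per bead
    chain: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def pair(self, si: int, sj: int) -> PairParams:
        key = (min(int(si), int(sj)), max(int(si), int(sj)))
        return self.pair_params[key]

    @property
    def active(self) -> bool:
        """Whether the run carries live pair kinetics."""
        return self.variant in ("RANR", "RAR", "RNR") and self.rates.lambda_ra > 0

    def nontransient_eps(self) -> float:
        """Cycle-time-averaged AA amplitude for the NONTRANSIENT variant.

        The static stand-in for the three-state cycle weights each
        state's amplitude (+eps, -eps, 0) by its mean dwell time.
        """
        r = self.rates
        if r.lambda_ra <= 0:
            return self.pair(0, 0).eps_vex
        t_r, t_a, t_n = 1.0 / r.lambda_ra, 1.0 / r.lambda_an, 1.0 / r.lambda_nr
        eps = self.pair(0, 0).eps_vex
        return (t_r * eps - t_a * eps) / (t_r + t_a + t_n)

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Sequence generation and composition
# ---------------------------------------------------------------------------

def _best_block_split(n_blocks: int, b: int, phi_target: float, va: float, vb: float) -> int:
    """Number of A blocks whose volume composition is closest to the target.

    Exhaustive scan over all feasible splits; ties broken toward more A
    blocks (documented, arbitrary).
    """
    na = np.arange(n_blocks + 1)
    vol_a = na * b * va
    vol_b = (n_blocks - na) * b * vb
    comp = np.where(vol_a + vol_b > 0, vol_a / np.maximum(vol_a + vol_b, 1e-300), 0.0)
    err = np.abs(comp - phi_target)
    best = err.min()
    return int(np.max(na[np.isclose(err, best, rtol=0.0, atol=1e-15)]))


def generate_sequence(
    N: int,
    b: int,
    phi_A_target: float,
    volumes: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
) -> PolymerSequence:
    """Random multiblock sequence hitting the target volume composition.

    Block counts are chosen to minimise the deviation of the achieved
    volume composition from ``phi_A_target``; the block order is then a
    uniformly random permutation under ``seed``.
    """
    if N < 1 or N % b:
        raise ValueError(f"N={N} must be a positive multiple of block size b={b}")
    if not 0.0 < phi_A_target < 1.0:
        raise ValueError("phi_A_target must be in (0, 1)")
    va, vb = volumes
    n_blocks = N // b
    na_blocks = _best_block_split(n_blocks, b, phi_A_target, va, vb)
    labels = np.array(["A"] * na_blocks + ["B"] * (n_blocks - na_blocks))
    rng = np.random.default_rng(seed)
    labels = labels[rng.permutation(n_blocks)]
    return PolymerSequence(species=np.repeat(labels, b), block_size=b)


def composition(seq: PolymerSequence, volumes: tuple[float, float] = (1.0, 1.0)) -> float:
    """Volume fraction of A beads: total A volume over total bead volume."""
    na, nb = seq.counts()
    va, vb = volumes
    total = na * va + nb * vb
    if total <= 0:
        raise ValueError("total bead volume must be positive")
    return na * va / total


def bidisperse_counts(
    N: int = 17664,
    phi_A: float = 0.3544,
    dA: float = 46.0,
    dB: float = 61.0,
    b: int = 4,
) -> tuple[int, int]:
    """Bead counts (NA, NB) for the bidisperse preset.

    Counts are multiples of the block size summing to ``N`` whose volume
    composition ``NA VA / (NA VA + NB VB)`` is closest to ``phi_A``.
    """
    if N < 1 or N % b:
        raise ValueError(f"N={N} must be a positive multiple of b={b}")
    if not 0.0 <= phi_A <= 1.0:
        raise ValueError("phi_A must lie in [0, 1]")
    if phi_A == 0.0:
        return 0, N
    if phi_A == 1.0:
        return N, 0
    na_blocks = _best_block_split(N // b, b, phi_A, dA**3, dB**3)
    return na_blocks * b, N - na_blocks * b


def _weighted_integral(r: np.ndarray, g: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of 2*pi*r*g(r) over [lo, hi] with endpoint interpolation."""
    if lo < r[0] or hi > r[-1]:
        raise ValueError(
            f"integration domain [{lo}, {hi}] outside tabulated range [{r[0]}, {r[-1]}]"
        )
    if hi <= lo:
        raise ValueError("integration domain must have positive width")
    inside = (r > lo) & (r < hi)
    rr = np.concatenate(([lo], r[inside], [hi]))
    gg = np.concatenate(([np.interp(lo, r, g)], g[inside], [np.interp(hi, r, g)]))
    return float(np.trapezoid(2.0 * np.pi * rr * gg, rr))


def composition_from_rdf(
    r: np.ndarray,
    gA: np.ndarray,
    gB: np.ndarray,
    dA: float,
    dB: float,
    segment_domain: tuple[float, float],
) -> float:
    """Volume composition from radial distribution functions of the two marks.

    For each species, ``m = int_segment 2 pi r g dr / int_0^{d/2} 2 pi r g dr``
    estimates the number of core-sized clusters in the imaged segment;
    the composition is then ``phi_A = mA VA / (mA VA + mB VB)`` with
    ``V = (pi/6) d^3``.  The segment interval is caller-supplied.
    """
    r = np.asarray(r, dtype=float)
    gA = np.asarray(gA, dtype=float)
    gB = np.asarray(gB, dtype=float)
    if r.ndim != 1 or r.size < 2 or np.any(np.diff(r) <= 0):
        raise ValueError("r must be a strictly increasing 1-D grid")
    if r[0] < 0:
        raise ValueError("r grid must be non-negative")
    lo, hi = segment_domain
    mA = _weighted_integral(r, gA, lo, hi) / _weighted_integral(r, gA, r[0], dA / 2.0)
    mB = _weighted_integral(r, gB, lo, hi) / _weighted_integral(r, gB, r[0], dB / 2.0)
    vA = math.pi / 6.0 * dA**3
    vB = math.pi / 6.0 * dB**3
    return mA * vA / (mA * vA + mB * vB)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Tabulated potential constants (e, l units) for the monodisperse model.
MONODISPERSE_TABLE = {
    "k": 22.0,
    "eps_vex": 8.0,
    "alpha_vex": 7.9585,
    "alpha_hc": 100.0,
    "p": 4.0,
    "s": 2.0,
    "d_nm": 50.5086,
}

#: Tabulated per-pair constants for the bidisperse model (AA/BB/AB).
BIDISPERSE_TABLE = {
    "k": 22.0,
    "AA": {"eps_vex": 6.6539, "alpha_vex": 9.5686},
    "BB": {"eps_vex": 11.507, "alpha_vex": 5.5330},
    "AB": {"eps_vex": 8.9153, "alpha_vex": 7.1414},
    "alpha_hc": 100.0,
    "p": 4.0,
    "s": 2.0,
    "dA_nm": 46.0,
    "dB_nm": 61.0,
}

#: Reference chain length of the full-scale monodisperse run.
FULL_SCALE_N = 20992
#: Cavity diameter of the full-scale run, in l units.
FULL_SCALE_CAVITY_L = 12.0


def scaled_cavity_diameter(N: int, reference_N: int = FULL_SCALE_N,
                           reference_diameter: float = FULL_SCALE_CAVITY_L) -> float:
    """Cavity diameter (l) preserving the full-scale bead density at chain length N."""
    return reference_diameter * (N / reference_N) ** (1.0 / 3.0)


def _confinement_for(diameters: dict, p: float, s: float) -> dict:
    return {code: ConfinementParams.for_bead(d, p=p, s=s) for code, d in diameters.items()}


def monodisperse_params(
    N: int = FULL_SCALE_N,
    b: int = 4,
    phi_A: float = 0.5,
    eps_hc: float = 0.0,
    lambda_ra: float = 0.0,
    variant: str = "RANR",
    geometry: Geometry | None = None,
    units: UnitSystem | None = None,
    exclude_neighbors: bool = True,
) -> ModelParams:
    """Monodisperse preset (equal-sized A and B beads, Table constants).

    The cavity is scaled with ``N^(1/3)`` so any chain length runs at the
    full-scale bead density.
    """
    units = units or UnitSystem.from_conditions()
    t = MONODISPERSE_TABLE
    d = units.to_l(t["d_nm"])
    pp = PairParams(eps_vex=t["eps_vex"], alpha_vex=t["alpha_vex"], k=t["k"], r0=2 * d)
    diameters = {0: d, 1: d}
    if geometry is None:
        geometry = Sphere(diameter=scaled_cavity_diameter(N))
    return ModelParams(
        pair_params={(0, 0): pp, (0, 1): pp, (1, 1): pp},
        hc=HCParams(eps_hc=eps_hc, alpha_hc=t["alpha_hc"], d_b=d),
        confinement=_confinement_for(diameters, t["p"], t["s"]),
        rates=EnzymeRates(lambda_ra=lambda_ra),
        geometry=geometry,
        variant=variant,
        phi_A=phi_A,
        diameters=diameters,
        exclude_neighbors=exclude_neighbors,
    )


def bidisperse_params(
    N: int = 17664,
    b: int = 4,
    phi_A: float = 0.3544,
    eps_hc: float = 0.0,
    lambda_ra: float = 0.0,
    variant: str = "RANR",
    geometry: Geometry | None = None,
    units: UnitSystem | None = None,
    exclude_neighbors: bool = True,
) -> ModelParams:
    """Bidisperse preset: A beads 46 nm, B beads 61 nm, tabulated pair constants."""
    units = units or UnitSystem.from_conditions()
    t = BIDISPERSE_TABLE
    dA = units.to_l(t["dA_nm"])
    dB = units.to_l(t["dB_nm"])
    diameters = {0: dA, 1: dB}

    def pp(key: str, r0: float) -> PairParams:
        return PairParams(eps_vex=t[key]["eps_vex"], alpha_vex=t[key]["alpha_vex"],
                          k=t["k"], r0=r0)

    if geometry is None:
        geometry = Sphere(diameter=scaled_cavity_diameter(N, reference_N=17664))
    return ModelParams(
        pair_params={
            (0, 0): pp("AA", 2 * dA),
            (0, 1): pp("AB", dA + dB),
            (1, 1): pp("BB", 2 * dB),
        },
        hc=HCParams(eps_hc=eps_hc, alpha_hc=t["alpha_hc"], d_b=dB),
        confinement=_confinement_for(diameters, t["p"], t["s"]),
        rates=EnzymeRates(lambda_ra=lambda_ra),
        geometry=geometry,
        variant=variant,
        phi_A=phi_A,
        diameters=diameters,
        exclude_neighbors=exclude_neighbors,
    )


PRESETS = {"monodisperse": monodisperse_params, "bidisperse": bidisperse_params}
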