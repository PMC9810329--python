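"""Lattice mean-field model of a self-avoiding / phantom bead mixture.

A lattice of M sites holds self-avoiding B beads (volume fraction
Phi_B) and phantom A' beads.  Two A' beads may overlap into a doublet
(D), freeing an empty site (E); the doublet fraction is
alpha = (#D) / M_A' in [0, 1/2], so the species volume fractions are

    phi_A' = (1 - Phi_B)(1 - 2 alpha),  phi_D = phi_E = (1 - Phi_B) alpha.

With pairwise repulsions eps_BB = eps_A'B = eps_A'D = eps and
eps_DB = eps_DD = 2 eps (doublets carry two beads) and all other pairs
inert, the interaction part of the mean-field free energy density
collapses to

    f_int = eps [ c(alpha) Phi_B^2 - 2 c(alpha) Phi_B + c(alpha) + 1/2 ],
    c(alpha) = -alpha^2 + alpha - 1/2 < 0,

and the negative coefficient of Phi_B^2 is an effective attraction
between B beads induced purely by A' phantomness.  Minimising the full
free energy over alpha gives the critical doublet fraction
alpha*(Phi_B, eps); the reduced free energy f*(Phi_B) = f(Phi_B, alpha*)
turns from convex to concave as eps grows, signalling phase separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LatticeMF",
    "c_of_alpha",
    "free_energy",
    "interaction_energy",
    "interaction_energy_from_pairs",
    "alpha_star",
    "f_star_curve",
    "convexity_transition",
    "DEFAULT_PAIR_EPS",
]


def default_pair_eps(eps: float) -> dict:
    """The model's pair-repulsion table in units of ``eps``."""
    return {
        ("B", "B"): eps,
        ("A'", "B"): eps,
        ("D", "B"): 2.0 * eps,
        ("A'", "D"): eps,
        ("D", "D"): 2.0 * eps,
    }


DEFAULT_PAIR_EPS = default_pair_eps


@dataclass(frozen=True)
class LatticeMF:
    """One point of the lattice model: composition, doublet fraction, repulsion."""

    Phi_B: float
    alpha: float
    eps: float
    pair_eps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.Phi_B < 1.0:
            raise ValueError("Phi_B must lie in (0, 1)")
        if not 0.0 <= self.alpha <= 0.5:
            raise ValueError("alpha must lie in [0, 1/2]")
        if not self.pair_eps:
            object.__setattr__(self, "pair_eps", default_pair_eps(self.eps))

    def volume_fractions(self) -> dict:
        """Volume fractions of A', D, E and B; they sum to 1."""
        pa = (1.0 - self.Phi_B) * (1.0 - 2.0 * self.alpha)
        pd = (1.0 - self.Phi_B) * self.alpha
        return {"A'": pa, "D": pd, "E": pd, "B": self.Phi_B}


def c_of_alpha(alpha: float) -> float:
    """Interaction coefficient ``c = -alpha^2 + alpha - 1/2`` (negative on [0, 1/2])."""
    if not 0.0 <= alpha <= 0.5:
        raise ValueError(f"alpha must lie in [0, 1/2], got {alpha}")
    return -alpha * alpha + alpha - 0.5


def _xlogx(x: float) -> float:
    return 0.0 if x <= 0.0 else x * np.log(x)


def interaction_energy(Phi_B: float, alpha: float, eps: float) -> float:
    """Closed-form interaction free energy density (the quadratic in Phi_B)."""
    c = c_of_alpha(alpha)
    return eps * (c * Phi_B**2 - 2.0 * c * Phi_B + (c + 0.5))


def interaction_energy_from_pairs(Phi_B: float, alpha: float, eps: float) -> float:
    """Interaction energy rebuilt from the pair table.

    Mean-field pair counting: like pairs contribute ``(1/2) eps_xx phi_x^2``
    and unlike pairs ``eps_xy phi_x phi_y``.  Must agree with
    :func:`interaction_energy` identically — this anchors the closed form
    to the model's pair energies.
    """
    mf = LatticeMF(Phi_B=Phi_B, alpha=alpha, eps=eps)
    phi = mf.volume_fractions()
    names = list(phi)
    table = mf.pair_eps
    total = 0.0
    for a in names:
        total += 0.5 * table.get((a, a), 0.0) * phi[a] ** 2
    for ia, a in enumerate(names):
        for b in names[ia + 1:]:
            e = table.get((a, b), table.get((b, a), 0.0))
            total += e * phi[a] * phi[b]
    return total


def free_energy(Phi_B: float, alpha: float, eps: float) -> float:
    """Mean-field free energy density (kB T per site).

    Mixing entropy of B against everything else, internal entropy of the
    A'/doublet partition, plus the pair interaction term.  Boundary
    values of alpha use the ``x ln x -> 0`` limit.
    """
    if not 0.0 < Phi_B < 1.0:
        raise ValueError("Phi_B must lie in (0, 1)")
    if not 0.0 <= alpha <= 0.5:
        raise ValueError("alpha must lie in [0, 1/2]")
    entropy = (
        _xlogx(Phi_B)
        + _xlogx(1.0 - Phi_B)
        + (1.0 - Phi_B) * (2.0 * _xlogx(alpha) + _xlogx(1.0 - 2.0 * alpha))
    )
    return entropy + interaction_energy(Phi_B, alpha, eps)


def alpha_star(Phi_B: float, eps: float) -> float:
    """Critical doublet fraction: argmin over alpha of the free energy.

    Stationarity reads ``2 ln(alpha / (1 - 2 alpha)) + eps (1 - Phi_B)
    (1 - 2 alpha) = 0``; the root is bracketed and refined, with a grid
    search fallback if no interior root exists.
    """
    if not 0.0 < Phi_B < 1.0:
        raise ValueError("Phi_B must lie in (0, 1)")

    def g(a: float) -> float:
        return 2.0 * np.log(a / (1.0 - 2.0 * a)) + eps * (1.0 - Phi_B) * (1.0 - 2.0 * a)

    lo, hi = 1e-12, 0.5 - 1e-12
    glo, ghi = g(lo), g(hi)
    if glo < 0.0 < ghi:
        return float(brentq(g, lo, hi, xtol=1e-14))
    # fallback: refine a direct grid minimisation
    grid = np.linspace(1e-9, 0.5 - 1e-9, 2001)
    vals = [free_energy(Phi_B, a, eps) for a in grid]
    i = int(np.argmin(vals))
    a0, a1 = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    fine = np.linspace(a0, a1, 2001)
    vals = [free_energy(Phi_B, a, eps) for a in fine]
    return float(fine[int(np.argmin(vals))])


def f_star_curve(eps: float, Phi_grid: np.ndarray):
    """Reduced free energy f*(Phi_B) = f(Phi_B, alpha*) and its curvature.

    Returns ``(f_star, f_star_second)``; the second derivative is a
    Richardson-refined central difference on the supplied grid (NaN at
    the grid ends).
    """
    phi = np.asarray(Phi_grid, dtype=float)
    if phi.ndim != 1 or phi.size < 5:
        raise ValueError("Phi_grid must be a 1-D grid with at least 5 points")
    if phi.min() <= 0.0 or phi.max() >= 1.0:
        raise ValueError("grid must lie strictly inside (0, 1)")
    f = np.array([free_energy(p, alpha_star(p, eps), eps) for p in phi])
    h = phi[1] - phi[0]
    second = np.full_like(f, np.nan)
    # plain central difference
    d2 = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / h**2
    second[1:-1] = d2
    # Richardson refinement where the doubled stencil fits
    if f.size >= 5:
        wide = (f[4:] - 2.0 * f[2:-2] + f[:-4]) / (2.0 * h) ** 2
        second[2:-2] = (4.0 * d2[1:-1] - wide) / 3.0
    return f, second


def convexity_transition(eps_range: np.ndarray, Phi_grid: np.ndarray,
                         refine_tol: float = 1e-3):
    """Smallest eps in the scanned range whose f* has a concave region.

    Scans ``eps_range`` (increasing), then bisects between the last
    convex and first concave value.  Returns a dict with the transition
    eps and the Phi-interval where f*'' < 0 just above it, or
    ``{"found": False}`` when the whole range stays convex.
    """
    eps_range = np.asarray(eps_range, dtype=float)
    if np.any(np.diff(eps_range) <= 0):
        raise ValueError("eps_range must be strictly increasing")

    def min_curvature(e: float) -> float:
        _, second = f_star_curve(e, Phi_grid)
        return float(np.nanmin(second))

    prev = eps_range[0]
    if min_curvature(prev) < 0:
        lo, hi = None, prev
    else:
        lo = prev
        hi = None
        for e in eps_range[1:]:
            if min_curvature(e) < 0:
                hi = e
                break
            lo = e
        if hi is None:
            return {"found": False, "eps_max_scanned": float(eps_range[-1])}
    if lo is not None:
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            if min_curvature(mid) < 0:
                hi = mid
            else:
                lo = mid
    _, second = f_star_curve(hi, Phi_grid)
    concave = np.asarray(Phi_grid)[np.nan_to_num(second, nan=1.0) < 0]
    return {
        "found": True,
        "eps_transition": float(hi),
        "eps_last_convex": float(lo) if lo is not None else None,
        "concave_interval": (float(concave.min()), float(concave.max()))
        if concave.size else None,
    }
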