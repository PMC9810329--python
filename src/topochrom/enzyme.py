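"""Topoisomerase-II catch-and-release state machine.

A pair of A beads within the capture radius can be caught by an
(implicit) enzyme at rate ``lambda_ra``; the caught pair attracts
(locked-gate state), then loses all steric interaction at rate
``lambda_an`` (strand-passage window), and is finally released at rate
``lambda_nr``, returning to normal repulsion.  The two-state variants
RAR (no passage window) and RNR (no attraction) reduce the chain
accordingly.  A bound pair that drifts beyond the capture radius pauses
its clock and resumes on re-approach.  A bead belongs to at most one
bound pair (one enzyme clamps both segments).

This module is the readable reference implementation; the Brownian
dynamics engine mirrors the same transition rules inside its compiled
kernel and is cross-checked against this one in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .potentials import PairState
from .units import EnzymeRates

__all__ = [
    "BoundPair",
    "EnzymeConfig",
    "Registry",
    "find_eligible",
    "kinetics_step",
    "pair_state_of",
]


@dataclass
class BoundPair:
    """One enzyme-bound AA pair and its kinetic state."""

    i: int
    j: int
    state: PairState
    paused: bool = False
    bound_since: float = 0.0

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("bound pair must have i < j")
        if self.state not in (PairState.ATTRACTION, PairState.NONE):
            raise ValueError("a bound pair is in the ATTRACTION or NONE state")


@dataclass(frozen=True)
class EnzymeConfig:
    """Kinetic configuration.

    ``exclusive`` limits a bead to one bound pair at a time; the default
    is pair-based (non-exclusive) kinetics, under which every proximal
    AA pair undergoes the catch-and-release cycle independently — the
    regime in which enzymatic activity is strong enough to drive
    microphase separation.  The exclusive mode is kept for sensitivity
    checks.
    """

    rates: EnzymeRates
    variant: str = "RANR"
    exclude_neighbors: bool = True
    capture_radius: float = 1.0
    exclusive: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("RANR", "RAR", "RNR"):
            raise ValueError(f"unknown kinetic variant {self.variant!r}")
        if self.capture_radius <= 0:
            raise ValueError("capture radius must be positive")


@dataclass
class Registry:
    """Bound-pair registry with per-bead occupancy bookkeeping."""

    pairs: dict = field(default_factory=dict)   # (i, j) -> BoundPair
    _bead_count: dict = field(default_factory=dict)

    def add(self, pair: BoundPair, exclusive: bool = False) -> None:
        key = (pair.i, pair.j)
        if key in self.pairs:
            raise ValueError(f"pair {key} already bound")
        if exclusive and (self.contains_bead(pair.i) or self.contains_bead(pair.j)):
            raise ValueError(f"bead of pair {key} already in a bound pair")
        self.pairs[key] = pair
        self._bead_count[pair.i] = self._bead_count.get(pair.i, 0) + 1
        self._bead_count[pair.j] = self._bead_count.get(pair.j, 0) + 1

    def remove(self, i: int, j: int) -> BoundPair:
        pair = self.pairs.pop((i, j))
        for b in (i, j):
            self._bead_count[b] -= 1
            if self._bead_count[b] == 0:
                del self._bead_count[b]
        return pair

    def contains_bead(self, i: int) -> bool:
        return self._bead_count.get(i, 0) > 0

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs.values())

    def check_exclusivity(self) -> bool:
        seen: set[int] = set()
        for i, j in self.pairs:
            if i in seen or j in seen:
                return False
            seen.add(i)
            seen.add(j)
        return True


def find_eligible(
    positions: np.ndarray,
    species: np.ndarray,
    registry: Registry,
    cfg: EnzymeConfig,
) -> list[tuple[int, int]]:
    """All unbound AA pairs within the capture radius.

    Immediate chain neighbours are excluded when ``cfg.exclude_neighbors``
    (the enzyme is assumed not to clamp adjacent segments).  A pair that
    is already bound is never eligible; under ``cfg.exclusive`` any pair
    sharing a bead with a bound pair is also excluded.
    """
    pos = np.asarray(positions, dtype=float)
    spec = np.asarray(species)
    tree = cKDTree(pos)
    out = []
    for i, j in sorted(tree.query_pairs(r=cfg.capture_radius)):
        if spec[i] != 0 or spec[j] != 0:
            continue
        if cfg.exclude_neighbors and j - i == 1:
            continue
        if (i, j) in registry.pairs:
            continue
        if cfg.exclusive and (registry.contains_bead(i) or registry.contains_bead(j)):
            continue
        out.append((i, j))
    return out


def _transition_prob(rate: float, dt: float) -> float:
    # exact per-step probability of at least one Poisson event
    return -math.expm1(-rate * dt)


def kinetics_step(
    registry: Registry,
    eligible: list[tuple[int, int]],
    dt: float,
    rng: np.random.Generator,
    cfg: EnzymeConfig,
    positions: np.ndarray | None = None,
    time: float = 0.0,
) -> list[tuple[float, str, int, int]]:
    """One stochastic update of the registry over a step of length ``dt``.

    Bound pairs advance/unbind first, then eligible pairs bind; each
    transition fires with the exact Poisson probability ``1 - exp(-rate*dt)``.
    Bound pairs currently separated beyond the capture radius are paused.
    Returns the event list as ``(time, kind, i, j)`` tuples, where kind is
    ``bind``/``advance``/``unbind``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = cfg.rates
    p_ra = _transition_prob(rates.lambda_ra, dt)
    p_an = _transition_prob(rates.lambda_an, dt)
    p_nr = _transition_prob(rates.lambda_nr, dt)
    events: list[tuple[float, str, int, int]] = []

    pos = None if positions is None else np.asarray(positions, dtype=float)
    for key in list(registry.pairs):
        pair = registry.pairs[key]
        if pos is not None:
            r = float(np.linalg.norm(pos[pair.i] - pos[pair.j]))
            pair.paused = r > cfg.capture_radius
            if pair.paused:
                continue
        if cfg.variant == "RANR":
            if pair.state is PairState.ATTRACTION:
                if rng.random() < p_an:
                    pair.state = PairState.NONE
                    events.append((time, "advance", pair.i, pair.j))
            else:
                if rng.random() < p_nr:
                    registry.remove(pair.i, pair.j)
                    events.append((time, "unbind", pair.i, pair.j))
        elif cfg.variant == "RAR":
            if rng.random() < p_an:
                registry.remove(pair.i, pair.j)
                events.append((time, "unbind", pair.i, pair.j))
        else:  # RNR
            if rng.random() < p_nr:
                registry.remove(pair.i, pair.j)
                events.append((time, "unbind", pair.i, pair.j))

    entry_state = PairState.NONE if cfg.variant == "RNR" else PairState.ATTRACTION
    for i, j in eligible:
        if cfg.exclusive and (registry.contains_bead(i) or registry.contains_bead(j)):
            continue
        if (min(i, j), max(i, j)) in registry.pairs:
            continue
        if rng.random() < p_ra:
            registry.add(
                BoundPair(min(i, j), max(i, j), state=entry_state, bound_since=time),
                exclusive=cfg.exclusive,
            )
            events.append((time, "bind", min(i, j), max(i, j)))
    return events


def pair_state_of(i: int, j: int, registry: Registry, species: np.ndarray) -> PairState:
    """Interaction state of the (i, j) pair: bound state if registered, else REPULSION."""
    if i == j:
        raise ValueError("a pair needs two distinct beads")
    spec = np.asarray(species)
    if spec[i] != 0 or spec[j] != 0:
        return PairState.REPULSION  # AB and BB pairs always repel
    pair = registry.pairs.get((min(i, j), max(i, j)))
    return pair.state if pair is not None else PairState.REPULSION
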