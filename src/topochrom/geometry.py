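"""Confinement geometries: spherical cavity and periodic slab."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Sphere:
    """Spherical cavity of the given diameter (l units), centred at the origin."""

    diameter: float

    kind = "sphere"
    periodic = (False, False, False)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("cavity diameter must be positive")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def volume(self) -> float:
        return math.pi / 6.0 * self.diameter**3

    def wall_distance(self, positions: np.ndarray) -> np.ndarray:
        """Distance from each point to the cavity wall (negative if outside)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        return self.radius - np.linalg.norm(pos, axis=-1)

    def inside(self, positions: np.ndarray) -> np.ndarray:
        return self.wall_distance(positions) > 0.0

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.radius
        return np.array([-r, -r, -r]), np.array([r, r, r])

    def separation(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.asarray(a, dtype=float) - np.asarray(b, dtype=float)

    def random_point(self, rng: np.random.Generator, margin: float = 0.0) -> np.ndarray:
        r_max = self.radius - margin
        if r_max <= 0:
            raise ValueError("margin leaves no interior volume")
        while True:
            p = rng.uniform(-r_max, r_max, size=3)
            if np.linalg.norm(p) < r_max:
                return p

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        return positions

    def to_dict(self) -> dict:
        return {"kind": "sphere", "diameter": self.diameter}


@dataclass(frozen=True)
class Slab:
    """Slab between two parallel walls at z=0 and z=lz, periodic in x and y."""

    lx: float
    ly: float
    lz: float

    kind = "slab"
    periodic = (True, True, False)

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("slab dimensions must be positive")

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    def wall_distance(self, positions: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        z = pos[..., 2]
        return np.minimum(z, self.lz - z)

    def inside(self, positions: np.ndarray) -> np.ndarray:
        return self.wall_distance(positions) > 0.0

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros(3), np.array([self.lx, self.ly, self.lz])

    def separation(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image separation vector honouring the two periodic axes."""
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        d = np.atleast_2d(d).copy()
        d[..., 0] -= self.lx * np.round(d[..., 0] / self.lx)
        d[..., 1] -= self.ly * np.round(d[..., 1] / self.ly)
        return d.reshape(np.shape(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))

    def random_point(self, rng: np.random.Generator, margin: float = 0.0) -> np.ndarray:
        if margin >= self.lz / 2:
            raise ValueError("margin leaves no interior volume")
        return np.array(
            [
                rng.uniform(0.0, self.lx),
                rng.uniform(0.0, self.ly),
                rng.uniform(margin, self.lz - margin),
            ]
        )

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        out = np.array(positions, dtype=float, copy=True)
        out[..., 0] %= self.lx
        out[..., 1] %= self.ly
        return out

    def to_dict(self) -> dict:
        return {"kind": "slab", "lx": self.lx, "ly": self.ly, "lz": self.lz}


Geometry = Sphere | Slab


def geometry_from_dict(d: dict) -> Geometry:
    kind = d.get("kind")
    if kind == "sphere":
        return Sphere(diameter=float(d["diameter"]))
    if kind == "slab":
        return Slab(lx=float(d["lx"]), ly=float(d["ly"]), lz=float(d["lz"]))
    raise ValueError(f"unknown geometry kind: {kind!r}")
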