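"""Extended-XYZ trajectory I/O, JSON sidecars and run configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .geometry import Geometry, geometry_from_dict

__all__ = [
    "Frame",
    "write_xyz",
    "read_xyz",
    "write_sidecar",
    "RunConfig",
    "ConfigError",
]


@dataclass
class Frame:
    positions: np.ndarray
    species: np.ndarray
    info: dict


def _format_comment(info: dict) -> str:
    parts = ["Properties=species:S:1:pos:R:3"]
    for k, v in info.items():
        if isinstance(v, str) and (" " in v or "=" in v):
            parts.append(f'{k}="{v}"')
        else:
            parts.append(f"{k}={v}")
    return " ".join(parts)


def _parse_comment(line: str) -> dict:
    info: dict = {}
    token = ""
    in_quote = False
    tokens = []
    for ch in line:
        if ch == '"':
            in_quote = not in_quote
        elif ch == " " and not in_quote:
            if token:
                tokens.append(token)
            token = ""
        else:
            token += ch
    if token:
        tokens.append(token)
    for tok in tokens:
        if "=" not in tok:
            continue
        k, v = tok.split("=", 1)
        try:
            info[k] = int(v)
        except ValueError:
            try:
                info[k] = float(v)
            except ValueError:
                info[k] = v
    return info


def write_xyz(path, frames, species=None, times=None, geometry: Geometry | None = None,
              extra_info: dict | None = None) -> None:
    """Write frames as extended XYZ (species label + position per line).

    ``frames`` may be a Trajectory-like object (with ``positions``,
    ``species``, ``times`` and ``geometry``) or an (S, N, 3)/(N, 3)
    array with ``species`` given separately.
    """
    if hasattr(frames, "positions") and hasattr(frames, "species"):
        species = frames.species
        times = getattr(frames, "times", None)
        geometry = getattr(frames, "geometry", geometry)
        frames = frames.positions
    pos = np.asarray(frames, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if species is None:
        raise ValueError("species labels are required")
    species = np.asarray(species, dtype="<U1")
    with open(path, "w") as fh:
        for s in range(pos.shape[0]):
            info = {}
            if times is not None and len(times) > s:
                info["time"] = float(times[s])
            if geometry is not None:
                d = geometry.to_dict()
                if d["kind"] == "sphere":
                    info["geometry"] = f"sphere:{d['diameter']:.10g}"
                else:
                    info["geometry"] = (f"slab:{d['lx']:.10g}:{d['ly']:.10g}"
                                        f":{d['lz']:.10g}")
            if extra_info:
                info.update(extra_info)
            fh.write(f"{pos.shape[1]}\n")
            fh.write(_format_comment(info) + "\n")
            for i in range(pos.shape[1]):
                x, y, z = pos[s, i]
                fh.write(f"{species[i]} {x:.10g} {y:.10g} {z:.10g}\n")


def read_xyz(path) -> list[Frame]:
    """Read an extended-XYZ file; raises with the line number on malformed input."""
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError as exc:
            raise ValueError(f"line {ln + 1}: expected an atom count") from exc
        if ln + 1 + n >= len(lines) + 1 and n > 0:
            raise ValueError(f"line {ln + 1}: truncated frame (expected {n} atoms)")
        info = _parse_comment(lines[ln + 1].strip())
        if isinstance(info.get("geometry"), str):
            parts = info["geometry"].split(":")
            try:
                if parts[0] == "sphere":
                    info["geometry"] = geometry_from_dict(
                        {"kind": "sphere", "diameter": float(parts[1])})
                elif parts[0] == "slab":
                    info["geometry"] = geometry_from_dict(
                        {"kind": "slab", "lx": float(parts[1]),
                         "ly": float(parts[2]), "lz": float(parts[3])})
            except (IndexError, ValueError):
                pass
        pos = np.empty((n, 3))
        spec = np.empty(n, dtype="<U1")
        for i in range(n):
            parts = lines[ln + 2 + i].split()
            if len(parts) < 4:
                raise ValueError(f"line {ln + 3 + i}: expected 'species x y z'")
            if parts[0] not in ("A", "B"):
                raise ValueError(
                    f"line {ln + 3 + i}: species label must be A or B, got {parts[0]!r}"
                )
            spec[i] = parts[0]
            try:
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ValueError(f"line {ln + 3 + i}: malformed coordinates") from exc
        frames.append(Frame(positions=pos, species=spec, info=info))
        ln += 2 + n
    return frames


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    return obj


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(payload), sort_keys=True).encode()
    ).hexdigest()[:16]


def write_sidecar(path, payload: dict) -> None:
    """JSON sidecar with full provenance (resolved parameters, seed, version, hash)."""
    from . import __version__

    data = _jsonable(payload)
    data["package_version"] = __version__
    data["config_hash"] = config_hash(payload)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


class ConfigError(ValueError):
    """Invalid run configuration; lists the offending keys."""


_CONFIG_KEYS = {
    "preset", "n_beads", "block_size", "phi_a", "eps_hc", "lambda_ra",
    "activity", "variant", "geometry", "dt", "anneal_duration",
    "production_duration", "snapshot_interval", "seed", "out",
    "exclude_neighbors", "grid_cell", "n_bins", "shell_width",
    "foci_cutoff", "foci_min_size",
}


@dataclass
class RunConfig:
    """Serializable run description resolved against a preset."""

    preset: str = "monodisperse"
    n_beads: int = 20992
    block_size: int = 4
    phi_a: float = 0.5
    eps_hc: float = 0.0
    lambda_ra: float = 0.0
    variant: str = "RANR"
    dt: float = 1e-4
    anneal_duration: float = 2010.0
    production_duration: float = 2010.0
    snapshot_interval: float = 1.0
    seed: int = 0
    exclude_neighbors: bool = True
    out: str = "run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        bad = sorted(set(d) - _CONFIG_KEYS)
        if bad:
            raise ConfigError(f"unknown configuration keys: {', '.join(bad)}")
        kwargs = {f.name: d[f.name] for f in dataclasses.fields(cls) if f.name in d}
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
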