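"""Configuration statistics: order-parameter field, phase-separation
cumulants, local nematic order, heterochromatin foci and density profiles.

The central object is a cubic grid of linear size l over the cavity.
Each cell carries an accessible-volume weight ``v`` (fraction of the
cell inside the geometry, Monte-Carlo estimated once per grid) and, per
snapshot, bead tallies from which the local composition order parameter

    delta_phi = (nA VA - nB VB) / (nA VA + nB VB)

is formed.  The v-weighted distribution of delta_phi over cells,
averaged over snapshots, yields the Binder cumulant and the moment
coefficient of skewness that diagnose microphase separation.  Cells
containing no beads leave delta_phi undefined and are excluded with
weight renormalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import qmc

from .geometry import Geometry

__all__ = [
    "GridField",
    "OrderParamStats",
    "FociSet",
    "Focus",
    "build_grid",
    "delta_phi_field",
    "order_param_stats",
    "binder_cumulant",
    "moment_skewness",
    "local_nematic",
    "segment_foci",
    "surface_fraction",
    "radial_density",
    "density_cross_correlation",
]

_SOBOL_SEED = 170915  # fixed sub-seed: grids are deterministic by construction


@dataclass
class GridField:
    """Cubic partition of the cavity bounding box at resolution ``cell_size``."""

    origin: np.ndarray           # (3,)
    shape: tuple[int, int, int]
    cell_size: float
    v: np.ndarray                # accessible-volume fraction per cell, flat (M,)
    geometry: Geometry
    nA: np.ndarray | None = None
    nB: np.ndarray | None = None
    delta_phi: np.ndarray | None = None  # NaN where undefined

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def cell_indices(self, positions: np.ndarray) -> np.ndarray:
        """Flat cell index of each position (positions must lie in the box)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        idx = np.floor((pos - self.origin) / self.cell_size).astype(np.int64)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return np.ravel_multi_index(idx.T, self.shape)

    def cell_centers(self) -> np.ndarray:
        """(M, 3) coordinates of all cell centres."""
        axes = [
            self.origin[d] + (np.arange(self.shape[d]) + 0.5) * self.cell_size
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def build_grid(geometry: Geometry, cell_size: float = 1.0,
               mc_samples: int = 4096) -> GridField:
    """Grid skeleton with Monte-Carlo accessible-volume weights.

    ``v`` is estimated per cell as the fraction of a fixed scrambled
    Sobol point set (internal sub-seed, hence deterministic) that falls
    inside the geometry.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    lo, hi = geometry.bounding_box()
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / cell_size - 1e-9)) for d in range(3))
    sob = qmc.Sobol(d=3, scramble=True, seed=_SOBOL_SEED)
    m = int(np.ceil(np.log2(max(mc_samples, 2))))
    unit = sob.random_base2(m)  # shared across cells
    centers_lo = [lo[d] + np.arange(shape[d]) * cell_size for d in range(3)]
    v = np.empty(shape)
    for ix, x0 in enumerate(centers_lo[0]):
        for iy, y0 in enumerate(centers_lo[1]):
            for iz, z0 in enumerate(centers_lo[2]):
                pts = unit * cell_size + np.array([x0, y0, z0])
                v[ix, iy, iz] = float(np.mean(geometry.inside(pts)))
    return GridField(origin=np.asarray(lo, dtype=float), shape=shape,
                     cell_size=cell_size, v=v.ravel(), geometry=geometry)


def delta_phi_field(positions: np.ndarray, species: np.ndarray, grid: GridField,
                    VA: float, VB: float) -> GridField:
    """Per-cell composition order parameter for one snapshot.

    Returns a new :class:`GridField` sharing the skeleton, with bead
    tallies and ``delta_phi`` (NaN in cells holding no beads).
    """
    codes = _codes(species)
    idx = grid.cell_indices(positions)
    m = grid.n_cells
    nA = np.bincount(idx[codes == 0], minlength=m).astype(float)
    nB = np.bincount(idx[codes == 1], minlength=m).astype(float)
    denom = nA * VA + nB * VB
    with np.errstate(invalid="ignore", divide="ignore"):
        dphi = np.where(denom > 0, (nA * VA - nB * VB) / np.where(denom > 0, denom, 1.0),
                        np.nan)
    return GridField(origin=grid.origin, shape=grid.shape, cell_size=grid.cell_size,
                     v=grid.v, geometry=grid.geometry, nA=nA, nB=nB, delta_phi=dphi)


def _codes(species: np.ndarray) -> np.ndarray:
    spec = np.asarray(species)
    if spec.dtype.kind in "US":
        return (spec == "B").astype(np.int8)
    return spec.astype(np.int8)


def binder_cumulant(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """``1 - <x^4> / (3 <x^2>^2)`` under the (weighted) sample distribution.

    Zero for Gaussian fluctuations, 2/3 for a symmetric two-delta
    distribution.
    """
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    m2 = float(np.sum(w * x**2))
    m4 = float(np.sum(w * x**4))
    if m2 == 0:
        raise ValueError("second moment vanishes")
    return 1.0 - m4 / (3.0 * m2 * m2)


def moment_skewness(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Moment coefficient of skewness ``E[(x-mu)^3] / E[(x-mu)^2]^(3/2)``."""
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = float(np.sum(w * x))
    var = float(np.sum(w * (x - mu) ** 2))
    if var == 0:
        raise ValueError("variance vanishes")
    return float(np.sum(w * (x - mu) ** 3)) / var**1.5


@dataclass
class OrderParamStats:
    """Snapshot-averaged distribution of delta_phi and its shape statistics."""

    bin_edges: np.ndarray
    histogram: np.ndarray   # density: sum(histogram * bin_width) == 1
    binder: float
    skewness: float
    mean: float
    n_snapshots: int


def order_param_stats(trajectory, grid: GridField, VA: float, VB: float,
                      n_bins: int = 41) -> OrderParamStats:
    """Distribution of the order parameter over cells and snapshots.

    For each snapshot the defined cells' delta_phi values are weighted
    by the accessible volume ``v`` and normalised; the per-snapshot
    distributions are then averaged.  All moments are computed from the
    raw weighted samples, not from the histogram, so the result does not
    depend on the binning.
    """
    frames, species = _frames_and_species(trajectory)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    widths = np.diff(edges)
    hist = np.zeros(n_bins)
    sums = np.zeros(5)  # weighted moments 0..4 accumulated per snapshot
    n_used = 0
    for pos in frames:
        f = delta_phi_field(pos, species, grid, VA, VB)
        ok = ~np.isnan(f.delta_phi) & (grid.v > 0)
        if not np.any(ok):
            continue
        w = grid.v[ok] / grid.v[ok].sum()
        x = f.delta_phi[ok]
        h, _ = np.histogram(x, bins=edges, weights=w)
        hist += h / widths
        for k in range(5):
            sums[k] += float(np.sum(w * x**k))
        n_used += 1
    if n_used == 0:
        raise ValueError("no snapshot produced any occupied cell")
    hist /= n_used
    m = sums / n_used
    mu = m[1]
    var = m[2] - mu**2
    third = m[3] - 3 * mu * m[2] + 2 * mu**3
    binder = 1.0 - m[4] / (3.0 * m[2] ** 2)
    skew = third / var**1.5 if var > 0 else 0.0
    return OrderParamStats(bin_edges=edges, histogram=hist, binder=binder,
                           skewness=skew, mean=mu, n_snapshots=n_used)


# ---------------------------------------------------------------------------
# Local nematic order
# ---------------------------------------------------------------------------

def local_nematic(trajectory, grid: GridField, bond_species: str = "AA",
                  surface_width: float = 1.0):
    """Local nematic order of same-species bonds, cell by cell.

    Bonds ``u = x_{i+1} - x_i`` between consecutive beads of the
    requested species are normalised and assigned to the cell holding
    the bond midpoint.  Per cell, the nematic tensor
    ``Q = <(3 u u^T - I)/2>`` is diagonalised and the eigenvalue of
    largest magnitude is the local order parameter S.  The scalar mean
    is the bond-count-weighted average of S over cells whose centre lies
    deeper than ``surface_width`` from the wall (wall-induced alignment
    is excluded).

    Returns ``(S_cells, q_cells, mean_S)`` where the first two are flat
    per-cell arrays (NaN / 0 for empty cells).
    """
    if bond_species not in ("AA", "BB"):
        raise ValueError("bond_species must be 'AA' or 'BB'")
    target = 0 if bond_species == "AA" else 1
    frames, species = _frames_and_species(trajectory)
    codes = _codes(species)
    mask = (codes[:-1] == target) & (codes[1:] == target)
    if not np.any(mask):
        raise ValueError(f"no {bond_species} bonds in the sequence")
    m = grid.n_cells
    acc = np.zeros((m, 3, 3))
    q = np.zeros(m)
    for pos in frames:
        u = pos[1:][mask] - pos[:-1][mask]
        if any(grid.geometry.periodic):
            u = grid.geometry.separation(pos[1:][mask], pos[:-1][mask])
        norm = np.linalg.norm(u, axis=1)
        good = norm > 0
        u = u[good] / norm[good, None]
        mid = 0.5 * (pos[1:][mask][good] + pos[:-1][mask][good])
        idx = grid.cell_indices(grid.geometry.wrap(mid))
        outer = u[:, :, None] * u[:, None, :]
        np.add.at(acc, idx, outer)
        np.add.at(q, idx, 1.0)
    s_cells = np.full(m, np.nan)
    occupied = np.nonzero(q > 0)[0]
    eye = np.eye(3)
    for c in occupied:
        Q = 1.5 * acc[c] / q[c] - 0.5 * eye
        ev = np.linalg.eigvalsh(Q)
        s_cells[c] = ev[np.argmax(np.abs(ev))]
    centers = grid.cell_centers()
    interior = grid.geometry.wall_distance(centers) >= surface_width
    sel = interior & (q > 0)
    if not np.any(sel):
        raise ValueError("no occupied interior cell; grid too coarse or cavity too small")
    mean_s = float(np.sum(q[sel] * s_cells[sel]) / np.sum(q[sel]))
    return s_cells, q, mean_s


# ---------------------------------------------------------------------------
# Heterochromatin foci
# ---------------------------------------------------------------------------

@dataclass
class Focus:
    """One segmented heterochromatin focus and its gyration-tensor shape."""

    member_indices: np.ndarray
    size: int
    Rg: float
    shape_anisotropy: float   # kappa^2 in [0, 1]
    radial_position: float    # mean member radial coordinate
    eigenvalues: np.ndarray   # lambda_m^2, ascending


@dataclass
class FociSet:
    foci: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.foci)

    def __iter__(self):
        return iter(self.foci)

    def sizes(self) -> np.ndarray:
        return np.array([f.size for f in self.foci], dtype=int)


def segment_foci(positions_B: np.ndarray, cutoff: float,
                 min_size: int = 8) -> FociSet:
    """Single-linkage clustering of B beads into heterochromatin foci.

    Two B beads within ``cutoff`` (the B bead diameter, by convention)
    belong to the same cluster; clusters smaller than ``min_size``
    (2 x block size by default) are discarded as noise.  Each retained
    focus carries its gyration tensor ``G = (1/n) sum r r^T`` in the
    centre-of-mass frame, from which Rg, the relative shape anisotropy
    kappa^2 (0 for a sphere, 1 for a line) and the mean member radial
    coordinate are derived.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(positions_B, dtype=float)
    out = FociSet()
    if pos.size == 0:
        return out
    pos = np.atleast_2d(pos)
    n = pos.shape[0]
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    ) if len(pairs) else sparse.coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        if members.size < min_size:
            continue
        r = pos[members]
        rel = r - r.mean(axis=0)
        G = rel.T @ rel / members.size
        ev = np.linalg.eigvalsh(G)
        ev = np.clip(ev, 0.0, None)
        tr = float(ev.sum())
        kappa2 = 1.5 * float(np.sum(ev**2)) / tr**2 - 0.5 if tr > 0 else 0.0
        out.foci.append(Focus(
            member_indices=members,
            size=int(members.size),
            Rg=float(np.sqrt(tr)),
            shape_anisotropy=float(min(max(kappa2, 0.0), 1.0)),
            radial_position=float(np.mean(np.linalg.norm(r, axis=1))),
            eigenvalues=ev,
        ))
    out.foci.sort(key=lambda f: -f.size)
    return out


# ---------------------------------------------------------------------------
# Profiles and correlations
# ---------------------------------------------------------------------------

def surface_fraction(positions: np.ndarray, species: np.ndarray,
                     geometry: Geometry, shell_width: float = 1.0) -> float:
    """B enrichment in the wall shell: (B fraction in shell) / (global B fraction).

    Returns NaN when the shell is empty.  Raises if there are no B beads
    at all (the normalisation is undefined).
    """
    codes = _codes(species)
    phi_b = float(np.mean(codes == 1))
    if phi_b == 0:
        raise ValueError("no B beads: surface enrichment undefined")
    wall = geometry.wall_distance(positions)
    shell = wall < shell_width
    if not np.any(shell):
        return float("nan")
    frac = float(np.mean(codes[shell] == 1))
    return frac / phi_b


def radial_density(trajectory, species_filter: str | None = None,
                   n_shells: int = 12, geometry: Geometry | None = None):
    """Shell-volume-normalised radial density profile (sphere geometry).

    Returns ``(r_centers, density)`` with density in beads per l^3,
    averaged over snapshots.
    """
    frames, species = _frames_and_species(trajectory)
    if geometry is None:
        geometry = _geometry_of(trajectory)
    if geometry.kind != "sphere":
        raise ValueError("radial profiles require a spherical cavity")
    codes = _codes(species)
    if species_filter is None:
        sel = np.ones(codes.size, dtype=bool)
    else:
        sel = codes == (0 if species_filter == "A" else 1)
    edges = np.linspace(0.0, geometry.radius, n_shells + 1)
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    counts = np.zeros(n_shells)
    n_frames = 0
    for pos in frames:
        r = np.linalg.norm(pos[sel], axis=1)
        h, _ = np.histogram(r, bins=edges)
        counts += h
        n_frames += 1
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, counts / max(n_frames, 1) / vol


def density_cross_correlation(traj1, traj2, grid: GridField,
                              species_filter: str = "A") -> float:
    """Pearson correlation of per-cell densities between two runs.

    Snapshots are paired by production-time index; each pair contributes
    the correlation of its per-cell counts over cells with nonzero
    accessible volume, normalised symmetrically by both snapshots'
    standard deviations.  Pairs where either field has zero variance are
    excluded with a warning.
    """
    frames1, species1 = _frames_and_species(traj1)
    frames2, species2 = _frames_and_species(traj2)
    target = 0 if species_filter == "A" else 1
    ok = grid.v > 0
    vals = []
    for pos1, pos2 in zip(frames1, frames2):
        fields = []
        for pos, spec in ((pos1, species1), (pos2, species2)):
            codes = _codes(spec)
            idx = grid.cell_indices(pos[codes == target])
            counts = np.bincount(idx, minlength=grid.n_cells)[ok].astype(float)
            # density, not raw counts: normalise by the accessible cell volume
            fields.append(counts / (grid.v[ok] * grid.cell_size**3))
        s1, s2 = fields[0].std(), fields[1].std()
        if s1 == 0 or s2 == 0:
            warnings.warn("snapshot pair with zero density variance excluded")
            continue
        c1 = fields[0] - fields[0].mean()
        c2 = fields[1] - fields[1].mean()
        vals.append(float(np.mean(c1 * c2) / (s1 * s2)))
    if not vals:
        raise ValueError("no snapshot pair with nonzero variance")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Input adapters
# ---------------------------------------------------------------------------

def _frames_and_species(trajectory):
    """Accept a Trajectory, an (S,N,3)/(N,3) array + species tuple, or a list."""
    if hasattr(trajectory, "positions") and hasattr(trajectory, "species"):
        pos = np.asarray(trajectory.positions, dtype=float)
        frames = pos if pos.ndim == 3 else pos[None]
        return list(frames), trajectory.species
    if isinstance(trajectory, tuple) and len(trajectory) == 2:
        pos, species = trajectory
        pos = np.asarray(pos, dtype=float)
        frames = pos if pos.ndim == 3 else pos[None]
        return list(frames), species
    raise TypeError("expected a Trajectory or a (positions, species) tuple")


def _geometry_of(trajectory):
    if hasattr(trajectory, "geometry"):
        return trajectory.geometry
    raise TypeError("trajectory carries no geometry; pass a Trajectory")
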