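"""Grid-based cavity detection and pocket geometry.

A single, simple grid method: voxels inside any atom's van der Waals
sphere are protein; bulk solvent is everything a spherical probe can
reach from outside (erosion/dilation against the vdW surface); what is
neither protein nor probe-accessible is candidate cavity space.  A
burial filter (fraction of rays from each voxel that hit protein over a
fixed 14-direction set) prunes shallow surface pockets, and 26-connected
clusters above a minimum volume are reported sorted by volume.

Pocket "length" is the extent along the first principal axis of the
cluster's grid points, matching the longest-length convention used when
comparing the alternative 4'-PPant tunnel with the canonical CoA pocket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .coa_geometry import CoASplit, MastAxis
from .contact_analysis import VdwRadiiTable
from .errors import DegenerateGeometryError, EmptySelectionError, ParameterError
from .structure_io import StructureModel

#: Default cavity-detection parameters (Å where dimensional).
DEFAULT_SPACING = 1.0
DEFAULT_PROBE = 3.0
DEFAULT_BURIAL_FRACTION = 0.6
DEFAULT_MIN_VOLUME = 50.0

#: 14-direction ray set: 6 axis directions + 8 cube diagonals.
RAY_DIRECTIONS = np.array(
    [
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
        (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1),
    ],
    dtype=int,
)


@dataclass
class PocketModel:
    """A detected cavity as explicit grid points."""

    grid_points: np.ndarray  # (N, 3) Å
    spacing: float
    principal_axis: np.ndarray
    extent: float
    label: str = ""

    @property
    def volume(self) -> float:
        """Å³: grid-point count × spacing³."""
        return float(len(self.grid_points)) * self.spacing**3

    @property
    def centroid(self) -> np.ndarray:
        return self.grid_points.mean(axis=0)

    def to_pseudoatom_pdb(self, path) -> None:
        """One HETATM pseudo-atom per grid point, for visualisation."""
        lines = []
        for i, p in enumerate(self.grid_points, start=1):
            lines.append(
                f"HETATM{i % 100000:5d}  O   POC P{1:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'O':>2s}"
            )
        lines.append("END")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def summary(self) -> dict:
        return {
            "label": self.label,
            "n_grid_points": int(len(self.grid_points)),
            "spacing": self.spacing,
            "volume": round(self.volume, 3),
            "extent": round(self.extent, 3),
            "principal_axis": [round(x, 6) for x in self.principal_axis],
        }


@dataclass
class PocketAxisPair:
    """Two pocket axes and the unsigned angle between them."""

    axis_a: np.ndarray
    axis_b: np.ndarray
    angle: float


def _ball_offsets(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox))
    if r < 1:
        return np.zeros((1, 3), dtype=int)
    rng = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(rng, rng, rng, indexing="ij")
    mask = X**2 + Y**2 + Z**2 <= radius_vox**2
    return np.stack([X[mask], Y[mask], Z[mask]], axis=1)


def _binary_ball(radius_vox: float) -> np.ndarray:
    r = max(int(np.floor(radius_vox)), 1)
    rng = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(rng, rng, rng, indexing="ij")
    return (X**2 + Y**2 + Z**2) <= radius_vox**2


def _ray_blocked_fraction(occupied: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """For every voxel, the fraction of the 14 rays that encounter an
    occupied voxel before leaving the grid, computed by iterative shifts."""
    hit_count = np.zeros(occupied.shape, dtype=np.int16)
    max_steps = max(occupied.shape)
    for d in RAY_DIRECTIONS:
        # reach[v] = True if some occupied voxel lies along +d from v
        reach = occupied.copy()
        for _ in range(max_steps):
            shifted = np.zeros_like(reach)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            for ax, step in enumerate(d):
                if step == 1:
                    src[ax] = slice(1, None)
                    dst[ax] = slice(None, -1)
                elif step == -1:
                    src[ax] = slice(None, -1)
                    dst[ax] = slice(1, None)
            shifted[tuple(dst)] = reach[tuple(src)]
            new = reach | shifted | occupied
            if np.array_equal(new, reach):
                break
            reach = new
        hit_count += reach.astype(np.int16)
    return hit_count / float(len(RAY_DIRECTIONS))


def detect_cavities(
    atoms,
    radii: VdwRadiiTable | None = None,
    spacing: float = DEFAULT_SPACING,
    probe: float = DEFAULT_PROBE,
    burial_fraction: float = DEFAULT_BURIAL_FRACTION,
    min_volume: float = DEFAULT_MIN_VOLUME,
) -> list:
    """Detect buried cavities/tunnels in an atom set.

    Parameters
    ----------
    atoms : StructureModel or list of AtomRecord
    spacing : grid spacing, Å
    probe : solvent probe radius, Å — controls what counts as bulk solvent
    burial_fraction : minimum fraction of the 14 rays that must hit
        protein for a voxel to count as buried
    min_volume : clusters below this volume (Å³) are dropped

    Returns pockets sorted by volume, largest first.
    """
    if spacing <= 0 or probe <= 0:
        raise ParameterError("spacing and probe must be positive")
    if not (0 <= burial_fraction <= 1):
        raise ParameterError("burial_fraction must lie in [0, 1]")
    atom_list = list(atoms.atoms) if isinstance(atoms, StructureModel) else list(atoms)
    if not atom_list:
        raise EmptySelectionError("cavity detection requires a non-empty atom set")
    radii = radii or VdwRadiiTable.default()

    coords = np.array([a.xyz for a in atom_list], dtype=float)
    rvals = radii.radii_for(atom_list)
    rmax = float(rvals.max())

    margin = probe + rmax + 2 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    flat = grid.reshape(-1, 3)

    # protein voxels: inside some atom's vdW sphere
    tree = cKDTree(coords)
    occupied = np.zeros(len(flat), dtype=bool)
    neighbor_lists = tree.query_ball_point(flat, r=rmax)
    for i, nbrs in enumerate(neighbor_lists):
        if not nbrs:
            continue
        d = np.linalg.norm(coords[nbrs] - flat[i], axis=1)
        if np.any(d < rvals[nbrs]):
            occupied[i] = True
    occupied = occupied.reshape(shape)

    # bulk solvent: free space reachable by the probe from the boundary
    probe_vox = probe / spacing
    fattened = ndimage.binary_dilation(occupied, structure=_binary_ball(probe_vox))
    free_for_probe = ~fattened
    labels, _ = ndimage.label(free_for_probe, structure=np.ones((3, 3, 3), dtype=int))
    border_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :]))
    border_labels |= set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
    border_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    border_labels.discard(0)
    bulk_centers = np.isin(labels, sorted(border_labels))
    accessible = ndimage.binary_dilation(bulk_centers, structure=_binary_ball(probe_vox))

    candidate = ~occupied & ~accessible
    if not candidate.any():
        return []

    # burial filter on the candidates
    blocked_fraction = _ray_blocked_fraction(occupied, candidate)
    buried = candidate & (blocked_fraction >= burial_fraction)
    if not buried.any():
        return []

    clusters, n_clusters = ndimage.label(buried, structure=np.ones((3, 3, 3), dtype=int))
    pockets = []
    for lab in range(1, n_clusters + 1):
        mask = clusters == lab
        count = int(mask.sum())
        if count * spacing**3 < min_volume:
            continue
        points = grid[mask]
        axis, extent = _points_axis_extent(points)
        pockets.append(
            PocketModel(
                grid_points=points,
                spacing=spacing,
                principal_axis=axis,
                extent=extent,
                label=f"pocket_{lab}",
            )
        )
    pockets.sort(key=lambda p: p.volume, reverse=True)
    for i, p in enumerate(pockets, start=1):
        p.label = f"pocket_{i}"
    return pockets


def _points_axis_extent(points: np.ndarray):
    if points.shape[0] < 2:
        raise DegenerateGeometryError("pocket needs >= 2 grid points for an axis")
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    return axis, float(proj.max() - proj.min())


def pocket_axis(pocket: PocketModel):
    """(first principal axis, extent along it) of a pocket's grid points."""
    return _points_axis_extent(pocket.grid_points)


def canonical_pocket_axis(state, transplanted_coa: CoASplit) -> MastAxis:
    """Direction of the canonical CoA pocket, operationalised as the mast
    axis of a CoA transplanted into the structure's frame (the 4'-PPant is
    the pocket's physical occupant)."""
    return transplanted_coa.axis


def interpocket_angle(a, b) -> float:
    """Unsigned angle between two pocket axes in degrees, range [0, 90]
    (an axis and its negation are the same axis)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ParameterError("interpocket angle undefined for a zero vector")
    c = abs(float(np.dot(a, b)) / (na * nb))
    return float(np.degrees(np.arccos(min(c, 1.0))))
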