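"""Euclidean and topological distances between cross-linked residues.

The topological distance is the length of the shortest spatial path between
the two anchor atoms that does not pass through the protein volume — the
quantity a cross-linker of a given arm length actually has to span. It is
computed on a voxel occupancy grid: voxels whose centers lie within
(van der Waals radius + probe radius) of any retained atom are blocked, a
clearance sphere around each endpoint keeps link sites from being sealed in
by their own side chains, and an A* search over the 26-connected free voxels
(step costs spacing x {1, sqrt2, sqrt3}) returns the shortest path length.

If the straight segment between the anchors intersects no blocked voxel the
Euclidean distance is returned directly: the linker can take the direct route.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import StructureModel

SQRT3 = math.sqrt(3.0)

#: van der Waals radii (Å) by element; unknown elements fall back to carbon
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "FE": 1.40, "ZN": 1.39, "MG": 1.73, "CA": 1.97,
    "MN": 1.61, "CU": 1.40, "NA": 2.27, "K": 2.75,
}
DEFAULT_VDW = 1.70


class DistanceError(Exception):
    """Raised when an anchor atom or grid endpoint cannot be resolved."""


@dataclass(frozen=True)
class AnchorAtom:
    """The atom standing in for a linked residue in distance calculations."""

    chain_id: str
    auth_number: int
    insertion_code: str
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class DistanceResult:
    """Distances for one link on one chain-pair assignment.

    ``topological`` is None when no volume-avoiding path of length <= cap
    exists; ``capped`` marks searches abandoned at the cap rather than proven
    disconnected.
    """

    euclidean: float
    topological: Optional[float]
    chain_pair: Tuple[str, str]
    capped: bool = False
    residue_a: Optional[Tuple[int, str]] = None
    residue_b: Optional[Tuple[int, str]] = None

    @property
    def reachable(self) -> bool:
        return self.topological is not None


def anchor_atom(structure: StructureModel, chain_id: str, residue_key, mode: str = "cb") -> AnchorAtom:
    """Anchor atom of a residue: beta-carbon, alpha-carbon for glycine or
    when the beta-carbon is missing (``mode="ca"`` forces the alpha-carbon).
    """
    auth_number, insertion_code = residue_key
    chain = structure.chain(chain_id)
    residue = chain.residue(auth_number, insertion_code)
    if residue is None:
        raise DistanceError(
            f"{structure.structure_id}/{chain_id}: no residue {auth_number}{insertion_code}"
        )
    atom = None
    if mode == "cb":
        atom = residue.atom("CB") or residue.atom("CA")
    elif mode == "ca":
        atom = residue.atom("CA")
    else:
        raise ValueError(f"unknown anchor mode {mode!r}")
    if atom is None:
        raise DistanceError(
            f"{structure.structure_id}/{chain_id}/{auth_number}: residue has "
            f"neither CB nor CA"
        )
    return AnchorAtom(
        chain_id=chain_id,
        auth_number=auth_number,
        insertion_code=insertion_code,
        atom_name=atom.name,
        x=atom.x, y=atom.y, z=atom.z,
    )


def euclidean_distance(a: AnchorAtom, b: AnchorAtom) -> float:
    return float(np.linalg.norm(a.coords - b.coords))


@dataclass
class OccupancyGrid:
    """Boolean voxel grid marking the protein volume.

    ``blocked[i, j, k]`` is True when the voxel center lies inside the
    inflated (vdW + probe) volume of any retained atom. Voxel indices map to
    centers as ``origin + (index + 0.5) * spacing``.
    """

    origin: np.ndarray
    spacing: float
    blocked: np.ndarray

    @property
    def dimensions(self) -> Tuple[int, int, int]:
        return tuple(self.blocked.shape)

    def voxel_of(self, point) -> Tuple[int, int, int]:
        idx = np.floor((np.asarray(point, dtype=float) - self.origin) / self.spacing).astype(int)
        return (int(idx[0]), int(idx[1]), int(idx[2]))

    def in_bounds(self, voxel) -> bool:
        return all(0 <= voxel[d] < self.blocked.shape[d] for d in range(3))

    def center(self, voxel) -> np.ndarray:
        return self.origin + (np.asarray(voxel, dtype=float) + 0.5) * self.spacing

    def is_blocked(self, voxel) -> bool:
        return bool(self.blocked[voxel])

    def with_clearance(self, points: Sequence, radius: float) -> "OccupancyGrid":
        """Copy of the grid with a free sphere carved around each point."""
        blocked = self.blocked.copy()
        _carve_spheres(blocked, self.origin, self.spacing, points, radius)
        return OccupancyGrid(origin=self.origin, spacing=self.spacing, blocked=blocked)


def _atom_entries(structure: StructureModel, chain_ids: Optional[Iterable[str]]):
    wanted = None if chain_ids is None else set(chain_ids)
    coords: List[Tuple[float, float, float]] = []
    radii: List[float] = []
    for chain in structure.chains:
        if wanted is not None and chain.chain_id not in wanted:
            continue
        for res in chain.residues:
            for a in res.atoms:
                coords.append((a.x, a.y, a.z))
                radii.append(VDW_RADII.get(a.element, DEFAULT_VDW))
    # ligand/cofactor heteroatoms occupy volume too (waters were dropped at parse)
    if wanted is None:
        for a in structure.het_atoms:
            coords.append((a.x, a.y, a.z))
            radii.append(VDW_RADII.get(a.element, DEFAULT_VDW))
    return np.array(coords, dtype=float).reshape(-1, 3), np.array(radii, dtype=float)


def _mark_spheres(blocked: np.ndarray, origin: np.ndarray, spacing: float,
                  coords: np.ndarray, radii: np.ndarray, value: bool) -> None:
    shape = blocked.shape
    for (cx, cy, cz), r in zip(coords, radii):
        lo = np.floor((np.array([cx, cy, cz]) - r - origin) / spacing).astype(int)
        hi = np.floor((np.array([cx, cy, cz]) + r - origin) / spacing).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if np.any(lo >= hi):
            continue
        xs = origin[0] + (np.arange(lo[0], hi[0]) + 0.5) * spacing
        ys = origin[1] + (np.arange(lo[1], hi[1]) + 0.5) * spacing
        zs = origin[2] + (np.arange(lo[2], hi[2]) + 0.5) * spacing
        d2 = ((xs - cx) ** 2)[:, None, None] + ((ys - cy) ** 2)[None, :, None] + ((zs - cz) ** 2)[None, None, :]
        sub = blocked[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[d2 <= r * r] = value


def _carve_spheres(blocked, origin, spacing, points, radius) -> None:
    pts = np.array([np.asarray(p, dtype=float) for p in points]).reshape(-1, 3)
    _mark_spheres(blocked, origin, spacing, pts, np.full(len(pts), radius), False)


def build_base_grid(
    structure: StructureModel,
    config,
    chain_ids: Optional[Iterable[str]] = None,
) -> OccupancyGrid:
    """Occupancy grid for (a subset of chains of) a structure, no carve-outs.

    The grid covers the atoms' bounding box plus the configured padding, which
    defaults to the maximum linker length so capped path searches never leave
    the grid.
    """
    coords, radii = _atom_entries(structure, chain_ids)
    spacing = config.grid_spacing
    pad = config.effective_padding
    if len(coords) == 0:
        origin = np.zeros(3) - pad
        dims = (max(1, int(math.ceil(2 * pad / spacing))),) * 3
        return OccupancyGrid(origin=origin, spacing=spacing,
                             blocked=np.zeros(dims, dtype=bool))
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    blocked = np.zeros(tuple(dims), dtype=bool)
    inflated = radii + config.probe_radius
    _mark_spheres(blocked, lo, spacing, coords, inflated, True)
    return OccupancyGrid(origin=lo, spacing=spacing, blocked=blocked)


def build_occupancy_grid(
    structure: StructureModel,
    endpoints: Sequence,
    config,
    chain_ids: Optional[Iterable[str]] = None,
) -> OccupancyGrid:
    """Grid with endpoint clearance spheres carved free (see module docstring)."""
    grid = build_base_grid(structure, config, chain_ids)
    return grid.with_clearance(list(endpoints), config.clearance_radius)


def segment_is_free(grid: OccupancyGrid, a, b) -> bool:
    """True when the straight segment a-b touches no blocked voxel."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    length = float(np.linalg.norm(b - a))
    n_steps = max(2, int(math.ceil(length / (grid.spacing / 2.0))) + 1)
    for t in np.linspace(0.0, 1.0, n_steps):
        v = grid.voxel_of(a + t * (b - a))
        if grid.in_bounds(v) and grid.is_blocked(v):
            return False
    return True


_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_NEIGHBOR_COSTS = [math.sqrt(dx * dx + dy * dy + dz * dz) for dx, dy, dz in _NEIGHBOR_OFFSETS]


def grid_shortest_path(
    grid: OccupancyGrid,
    start_voxel: Tuple[int, int, int],
    goal_voxel: Tuple[int, int, int],
    cap: float = math.inf,
) -> Tuple[Optional[float], bool]:
    """Shortest 26-connected path length (Å) between two free voxels.

    A* with the Euclidean center-to-center heuristic, which is consistent
    because every step's cost equals the Euclidean length of the move; the
    result therefore equals a plain Dijkstra search on the same graph.
    Returns ``(length, capped)``; ``(None, capped)`` when unreachable within
    the cap.
    """
    for name, v in (("start", start_voxel), ("goal", goal_voxel)):
        if not grid.in_bounds(v):
            raise DistanceError(f"{name} voxel {v} outside grid {grid.dimensions}")
    if grid.is_blocked(start_voxel) or grid.is_blocked(goal_voxel):
        return None, False
    if start_voxel == goal_voxel:
        return 0.0, False

    spacing = grid.spacing
    goal = np.asarray(goal_voxel, dtype=float)
    blocked = grid.blocked
    shape = blocked.shape
    eps = 1e-9

    def heuristic(v) -> float:
        return spacing * float(np.linalg.norm(np.asarray(v, dtype=float) - goal))

    dist = {start_voxel: 0.0}
    heap = [(heuristic(start_voxel), 0.0, start_voxel)]
    capped = False
    while heap:
        f, g, v = heapq.heappop(heap)
        if v == goal_voxel:
            return g, False
        if g > dist.get(v, math.inf) + eps:
            continue
        vx, vy, vz = v
        for (dx, dy, dz), step in zip(_NEIGHBOR_OFFSETS, _NEIGHBOR_COSTS):
            w = (vx + dx, vy + dy, vz + dz)
            if not (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1] and 0 <= w[2] < shape[2]):
                continue
            if blocked[w]:
                continue
            ng = g + step * spacing
            h = heuristic(w)
            if ng + h > cap + eps:
                capped = True
                continue
            if ng < dist.get(w, math.inf) - eps:
                dist[w] = ng
                heapq.heappush(heap, (ng + h, ng, w))
    return None, capped


def topological_distance(
    grid: OccupancyGrid,
    a: AnchorAtom,
    b: AnchorAtom,
    cap: float = math.inf,
) -> Tuple[Optional[float], bool]:
    """Volume-avoiding shortest-path distance between two anchor atoms.

    Straight-line early exit: when the segment between the anchors crosses no
    blocked voxel, the Euclidean distance is the answer. Otherwise the voxel
    path length from :func:`grid_shortest_path` is returned. Returns
    ``(distance_or_None, capped)``.
    """
    va = grid.voxel_of(a.coords)
    vb = grid.voxel_of(b.coords)
    for name, v in (("a", va), ("b", vb)):
        if not grid.in_bounds(v):
            raise DistanceError(f"endpoint {name} at voxel {v} outside grid")
    if segment_is_free(grid, a.coords, b.coords):
        d = euclidean_distance(a, b)
        if d <= cap:
            return d, False
        return None, True
    return grid_shortest_path(grid, va, vb, cap)
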