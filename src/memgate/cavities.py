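"""Grid-based probe-accessible volume and tunnel detection.

A regular grid is laid over the structure and each node is assigned its
*clearance*: the distance to the nearest atom's van der Waals surface
(negative inside an atom). A probe of radius r can occupy exactly the
nodes with clearance ≥ r, and a tunnel is a path through such nodes whose
*bottleneck radius* — the smallest clearance met along the way — is as
large as possible (the maximin / "widest path" objective familiar from
channel-finding tools).

The maximin value is found exactly by bisecting over the sorted node
clearances with a 26-connectivity component labelling; the reported path
is then the shortest (true Euclidean edge lengths) path within the
above-threshold set, so among widest paths a shortest one is returned.
Identical inputs always give identical paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial import cKDTree

from .structio import Structure

__all__ = [
    "ClearanceGrid",
    "Tunnel",
    "clearance_grid",
    "find_tunnel",
    "path_exists",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

# offsets to the 26 neighbours, fixed order (lexicographic) for determinism
_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


@dataclass
class ClearanceGrid:
    """Per-node distance (Å) to the nearest atom surface; negative inside."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    clearance: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.dims = tuple(int(d) for d in self.dims)
        self.clearance = np.asarray(self.clearance, dtype=float)
        if self.clearance.shape != self.dims:
            raise ValueError("clearance shape does not match dims")

    def node_position(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def nearest_node(self, point) -> tuple[int, int, int]:
        idx = np.round((np.asarray(point, dtype=float) - self.origin) / self.spacing)
        idx = np.clip(idx, 0, np.array(self.dims) - 1).astype(int)
        return tuple(idx)

    def contains(self, point) -> bool:
        rel = (np.asarray(point, dtype=float) - self.origin) / self.spacing
        return bool((rel >= -0.5).all() and (rel <= np.array(self.dims) - 0.5).all())


@dataclass
class Tunnel:
    """An ordered node path with per-node clearances (Å)."""

    path: np.ndarray
    clearances: np.ndarray
    bottleneck_radius: float
    length: float

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        self.clearances = np.asarray(self.clearances, dtype=float)
        if abs(self.bottleneck_radius - self.clearances.min()) > 1e-9:
            raise ValueError("bottleneck_radius must equal min(clearances)")


def clearance_grid(
    structure: Structure,
    spacing: float = 0.5,
    padding: float = 3.0,
) -> ClearanceGrid:
    """Exact clearance at every grid node over the padded bounding box.

    Nearest-surface distances are computed with one KD-tree per distinct
    van der Waals radius, so varying radii are handled exactly rather than
    approximated by the nearest atom centre.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if structure.n_atoms == 0:
        raise ValueError("structure has no atoms")
    coords = structure.coords
    radii = np.array([a.vdw_radius for a in structure.atoms])
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = tuple(int(d) for d in np.floor((hi - lo) / spacing).astype(int) + 1)
    axes = [lo[a] + np.arange(dims[a]) * spacing for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    clearance = np.full(nodes.shape[0], np.inf)
    for r in np.unique(radii):
        tree = cKDTree(coords[radii == r])
        d, _ = tree.query(nodes, k=1)
        np.minimum(clearance, d - r, out=clearance)
    return ClearanceGrid(lo, float(spacing), dims, clearance.reshape(dims))


# ---------------------------------------------------------------------------
# graph utilities on the accessible-node set
# ---------------------------------------------------------------------------

def _snap_seed(grid: ClearanceGrid, point, probe_radius: float, what: str):
    point = np.asarray(point, dtype=float)
    if not grid.contains(point):
        raise ValueError(f"{what} {point.tolist()} lies outside the grid")
    idx = grid.nearest_node(point)
    if grid.clearance[idx] >= probe_radius:
        return idx
    # snap to the widest node within 3 Å (documented fallback)
    reach = int(np.ceil(3.0 / grid.spacing))
    slices = tuple(
        slice(max(0, idx[a] - reach), min(grid.dims[a], idx[a] + reach + 1))
        for a in range(3)
    )
    sub = grid.clearance[slices]
    ii, jj, kk = np.meshgrid(
        *[np.arange(s.start, s.stop) for s in slices], indexing="ij"
    )
    pos = grid.origin + np.stack([ii, jj, kk], axis=-1) * grid.spacing
    within = np.linalg.norm(pos - point, axis=-1) <= 3.0
    cand = np.where(within, sub, -np.inf)
    best = np.unravel_index(np.argmax(cand), cand.shape)
    if cand[best] < probe_radius:
        # the probe cannot fit anywhere near this point
        return None
    return (ii[best], jj[best], kk[best])


def _boundary_mask(dims: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(dims, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    return mask


def _maximin_threshold(
    clearance: np.ndarray,
    seed_idx: tuple[int, int, int],
    target_mask: np.ndarray,
    probe_radius: float,
) -> float | None:
    """Largest t ≥ probe such that seed reaches a target through {clearance ≥ t}.

    Exact: bisects the sorted distinct clearance values of the grid.
    """
    def reaches(t: float) -> bool:
        acc = clearance >= t
        if not acc[seed_idx]:
            return False
        labels, _ = ndimage.label(acc, structure=_CONN26)
        return bool((labels[target_mask & acc] == labels[seed_idx]).any())

    if not reaches(probe_radius):
        return None
    vals = np.unique(clearance[clearance >= probe_radius])
    lo, hi = 0, len(vals) - 1  # vals[lo] always reachable
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if reaches(vals[mid]):
            lo = mid
        else:
            hi = mid - 1
    return float(vals[lo])


def _shortest_path(
    grid: ClearanceGrid,
    accessible: np.ndarray,
    seed_idx: tuple[int, int, int],
    target_mask: np.ndarray,
):
    """Shortest Euclidean path within ``accessible`` from seed to targets.

    Returns the ordered list of node index triples, or None.
    """
    dims = grid.dims
    flat_acc = accessible.ravel()
    node_ids = np.flatnonzero(flat_acc)
    if node_ids.size == 0:
        return None
    remap = -np.ones(flat_acc.size, dtype=np.int64)
    remap[node_ids] = np.arange(node_ids.size)

    multi = np.array(np.unravel_index(node_ids, dims)).T  # M×3
    rows, cols, weights = [], [], []
    strides = np.array([dims[1] * dims[2], dims[2], 1])
    for off in _OFFSETS:
        nb = multi + off
        ok = ((nb >= 0) & (nb < np.array(dims))).all(axis=1)
        src = node_ids[ok]
        dst = (nb[ok] * strides).sum(axis=1)
        ok2 = flat_acc[dst]
        src, dst = src[ok2], dst[ok2]
        rows.append(remap[src])
        cols.append(remap[dst])
        weights.append(
            np.full(src.size, np.linalg.norm(off) * grid.spacing)
        )
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(node_ids.size, node_ids.size),
    ).tocsr()

    seed_flat = int(np.ravel_multi_index(seed_idx, dims))
    seed_node = int(remap[seed_flat])
    dist, pred = _csgraph_dijkstra(
        graph, directed=False, indices=seed_node, return_predecessors=True
    )
    target_flat = np.flatnonzero(target_mask.ravel() & flat_acc)
    target_nodes = remap[target_flat]
    finite = np.isfinite(dist[target_nodes])
    if not finite.any():
        return None
    cand = target_nodes[finite]
    # shortest distance first; break remaining ties on the flat node index
    order = np.lexsort((node_ids[cand], dist[cand]))
    end = int(cand[order[0]])
    chain = [end]
    while chain[-1] != seed_node:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    return [tuple(np.unravel_index(node_ids[c], dims)) for c in chain]


def _build_tunnel(grid: ClearanceGrid, idx_path) -> Tunnel:
    coords = np.array([grid.node_position(i) for i in idx_path])
    clear = np.array([grid.clearance[i] for i in idx_path])
    seg = np.diff(coords, axis=0)
    length = float(np.linalg.norm(seg, axis=1).sum()) if len(coords) > 1 else 0.0
    return Tunnel(coords, clear, float(clear.min()), length)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def find_tunnel(
    structure: Structure,
    seed_point,
    probe_radius: float = 1.4,
    spacing: float = 0.5,
    padding: float = 3.0,
    grid: ClearanceGrid | None = None,
) -> Tunnel | None:
    """Widest probe-accessible path from a seed to the grid boundary.

    Returns None when the probe cannot fit within 3 Å of the seed, or when
    the seed's accessible component never reaches the boundary (a closed
    cavity). The seed is snapped to the widest node within 3 Å if its own
    node is tighter than the probe. A seed outside the grid is an error.
    """
    if grid is None:
        grid = clearance_grid(structure, spacing=spacing, padding=padding)
    seed_idx = _snap_seed(grid, seed_point, probe_radius, "seed")
    if seed_idx is None:
        return None
    targets = _boundary_mask(grid.dims)
    bottleneck = _maximin_threshold(grid.clearance, seed_idx, targets, probe_radius)
    if bottleneck is None:
        return None
    accessible = grid.clearance >= bottleneck
    idx_path = _shortest_path(grid, accessible, seed_idx, targets)
    if idx_path is None:  # seed itself on the boundary
        idx_path = [seed_idx]
    return _build_tunnel(grid, idx_path)


def path_exists(
    structure: Structure,
    point_a,
    point_b,
    probe_radius: float = 1.4,
    spacing: float = 0.5,
    padding: float = 3.0,
    grid: ClearanceGrid | None = None,
) -> tuple[bool, Tunnel | None]:
    """Are two points in the same probe-accessible component?

    When they are, one widest path between them is returned alongside.
    """
    if grid is None:
        grid = clearance_grid(structure, spacing=spacing, padding=padding)
    ia = _snap_seed(grid, point_a, probe_radius, "point_a")
    ib = _snap_seed(grid, point_b, probe_radius, "point_b")
    if ia is None or ib is None:
        return False, None
    if ia == ib:
        return True, _build_tunnel(grid, [ia])
    target_mask = np.zeros(grid.dims, dtype=bool)
    target_mask[ib] = True
    bottleneck = _maximin_threshold(grid.clearance, ia, target_mask, probe_radius)
    if bottleneck is None:
        return False, None
    accessible = grid.clearance >= bottleneck
    idx_path = _shortest_path(grid, accessible, ia, target_mask)
    return True, _build_tunnel(grid, idx_path)
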