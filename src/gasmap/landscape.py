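"""Free-energy landscape analysis: basins, saddles, pathway networks, profiles.

The scalar grid is segmented by steepest-descent (watershed) tessellation:
every voxel follows repeated moves to its lowest-valued neighbour until it
reaches a local minimum, and all voxels draining to the same minimum form one
basin. The lowest point on the boundary between two adjacent basins is their
saddle; with the convention used here (boundary value = max of the two voxels
of a boundary pair) the saddle energy provably equals the minimax path energy
between the two minima over paths confined to the union of their basins.
Saddles below a construction cutoff become edges of the pathway network, whose
nodes are the minima; channel profiles are alternating minimum/saddle energy
sequences along a route, with forward barriers measured from the preceding
minimum.

Ties during descent are broken toward the smallest linearized (C-order) voxel
index — a stated, deterministic convention, so the whole analysis contains no
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import ScalarGrid3D, ValidationError

__all__ = [
    "neighbour_offsets",
    "BasinTessellation",
    "Saddle",
    "PathwayNetwork",
    "ChannelProfile",
    "BlockErrorReport",
    "tessellate",
    "find_saddles",
    "build_network",
    "extract_profile",
    "block_errors",
    "minimax_energy",
]


def neighbour_offsets(connectivity: int) -> np.ndarray:
    """Voxel-neighbour offsets for 6- (face), 18- (face+edge) or
    26-connectivity (face+edge+corner)."""
    if connectivity not in (6, 18, 26):
        raise ValidationError("connectivity: must be 6, 18 or 26")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs, int)


@dataclass(frozen=True)
class BasinTessellation:
    """Steepest-descent partition of a grid into catchment basins.

    ``labels`` assigns every voxel a basin id (−1 for voxels excluded by the
    energy cutoff); ``minima_index`` holds each basin's minimum as a flat
    C-order voxel index, ordered by that index. ``successors`` records each
    voxel's single steepest-descent step (its own index at minima, −1 when
    excluded) and is reused for path tracing.
    """

    labels: np.ndarray  # (nx, ny, nz) int, -1 = excluded
    minima_index: np.ndarray  # (n_basins,) flat voxel index
    minima_energy: np.ndarray  # (n_basins,)
    minima_position: np.ndarray  # (n_basins, 3) Å
    successors: np.ndarray  # (n_voxels,) flat successor index
    connectivity: int
    cutoff: float

    @property
    def n_basins(self) -> int:
        return len(self.minima_index)

    def basin_sizes(self) -> np.ndarray:
        return np.bincount(self.labels[self.labels >= 0].ravel(), minlength=self.n_basins)


def _flat_neighbour_tables(dims, connectivity):
    """For each neighbour offset: flat index shift and validity mask."""
    nx_, ny_, nz_ = dims
    idx = np.arange(nx_ * ny_ * nz_).reshape(dims)
    tables = []
    for d in neighbour_offsets(connectivity):
        sl_src = tuple(
            slice(max(0, -o), n - max(0, o)) for o, n in zip(d, dims)
        )
        sl_dst = tuple(
            slice(max(0, o), n - max(0, -o)) for o, n in zip(d, dims)
        )
        tables.append((idx[sl_src].ravel(), idx[sl_dst].ravel()))
    return tables


def tessellate(grid: ScalarGrid3D, connectivity: int = 26, cutoff: float = 20.0) -> BasinTessellation:
    """Steepest-descent (watershed) tessellation of an energy grid.

    Voxels with value strictly above ``cutoff`` are excluded. Every remaining
    voxel repeatedly steps to its lexicographically smallest ``(value, index)``
    neighbour while that is smaller than its own ``(value, index)``; the
    terminal voxel is the basin's minimum. The procedure is deterministic,
    including on plateaus, via the smallest-linearized-index tie rule.
    """
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff: must be finite")
    values = grid.values.ravel()
    n = values.size
    active = values <= cutoff
    if not active.any():
        raise ValidationError("tessellate: all voxels excluded by the cutoff")

    # masked values: excluded voxels can never be chosen as descent targets
    masked = np.where(active, values, np.inf)
    best_val = np.full(n, np.inf)
    best_idx = np.full(n, n, dtype=np.int64)
    for src, dst in _flat_neighbour_tables(grid.dims, connectivity):
        # dst is the neighbour of src at this offset
        nv = masked[dst]
        better = (nv < best_val[src]) | ((nv == best_val[src]) & (dst < best_idx[src]))
        upd = src[better]
        best_val[upd] = nv[better]
        best_idx[upd] = dst[better]

    own = np.arange(n, dtype=np.int64)
    move = (best_val < masked) | ((best_val == masked) & (best_idx < own))
    succ = np.where(active, np.where(move, best_idx, own), -1)

    # resolve descent chains by pointer doubling
    resolved = succ.copy()
    while True:
        act = resolved >= 0
        nxt = resolved.copy()
        nxt[act] = resolved[resolved[act]]
        if np.array_equal(nxt, resolved):
            break
        resolved = nxt

    roots = np.unique(resolved[resolved >= 0])
    basin_of_root = {int(r): i for i, r in enumerate(np.sort(roots))}
    labels = np.full(n, -1, dtype=np.int64)
    lut = np.full(n, -1, dtype=np.int64)
    for r, i in basin_of_root.items():
        lut[r] = i
    labels[resolved >= 0] = lut[resolved[resolved >= 0]]

    minima_index = np.sort(roots)
    minima_energy = values[minima_index]
    ijk = np.column_stack(np.unravel_index(minima_index, grid.dims))
    minima_position = grid.origin + grid.spacing * ijk
    return BasinTessellation(
        labels=labels.reshape(grid.dims),
        minima_index=minima_index,
        minima_energy=minima_energy,
        minima_position=minima_position,
        successors=succ,
        connectivity=connectivity,
        cutoff=float(cutoff),
    )


@dataclass(frozen=True)
class Saddle:
    """Lowest crossing between two adjacent basins."""

    basin_pair: tuple[int, int]
    voxel: tuple[int, int, int]
    free_energy: float
    path_indices: np.ndarray  # flat voxel indices, minimum A → saddle → minimum B
    path_positions: np.ndarray = field(repr=False, default=None)


def _descent_path(succ: np.ndarray, start: int) -> list[int]:
    path = [start]
    while succ[path[-1]] != path[-1]:
        path.append(int(succ[path[-1]]))
    return path


def find_saddles(
    grid: ScalarGrid3D, tess: BasinTessellation, connectivity: int | None = None
) -> list[Saddle]:
    """Locate the saddle point between every pair of adjacent basins.

    The boundary of a basin pair is the set of neighbouring voxel pairs with
    different labels; the saddle value is the minimum over the boundary of
    max(value(a), value(b)), attained at the higher-valued voxel of the
    achieving pair (ties broken toward the smallest linearized index).
    Steepest-descent paths are traced from both sides of the saddle to the two
    minima, giving a minimum→saddle→minimum polyline.
    """
    if connectivity is None:
        connectivity = tess.connectivity
    values = grid.values.ravel()
    labels = tess.labels.ravel()
    n = values.size

    pairs_a, pairs_b = [], []
    for src, dst in _flat_neighbour_tables(grid.dims, connectivity):
        la, lb = labels[src], labels[dst]
        m = (la >= 0) & (lb >= 0) & (la != lb) & (src < dst)  # each pair once
        pairs_a.append(src[m])
        pairs_b.append(dst[m])
    a = np.concatenate(pairs_a) if pairs_a else np.array([], int)
    b = np.concatenate(pairs_b) if pairs_b else np.array([], int)
    if a.size == 0:
        return []

    va, vb = values[a], values[b]
    # saddle voxel: higher-valued voxel of the pair; value ties -> smaller index
    hi_is_a = (va > vb) | ((va == vb) & (a < b))
    sv = np.where(hi_is_a, a, b)
    pv = np.where(hi_is_a, b, a)
    sval = np.maximum(va, vb)
    la, lb = labels[a], labels[b]
    pair_lo = np.minimum(la, lb)
    pair_hi = np.maximum(la, lb)
    pair_id = pair_lo * tess.n_basins + pair_hi

    order = np.lexsort((pv, sv, sval, pair_id))
    pair_sorted = pair_id[order]
    first = np.ones(len(order), bool)
    first[1:] = pair_sorted[1:] != pair_sorted[:-1]
    chosen = order[first]

    saddles = []
    for ci in chosen:
        s_flat, p_flat = int(sv[ci]), int(pv[ci])
        lo, hi = int(pair_lo[ci]), int(pair_hi[ci])
        path_s = _descent_path(tess.successors, s_flat)
        path_p = _descent_path(tess.successors, p_flat)
        # orient full path from the lower-id basin's minimum to the higher-id's
        side_s = int(labels[s_flat])
        if side_s == lo:
            full = path_s[::-1] + path_p
        else:
            full = path_p[::-1] + path_s
        full_idx = np.array(full, int)
        ijk_path = np.column_stack(np.unravel_index(full_idx, grid.dims))
        positions = grid.origin + grid.spacing * ijk_path
        ijk = tuple(int(x) for x in np.unravel_index(s_flat, grid.dims))
        saddles.append(
            Saddle(
                basin_pair=(lo, hi),
                voxel=ijk,
                free_energy=float(sval[ci]),
                path_indices=full_idx,
                path_positions=positions,
            )
        )
    return saddles


@dataclass(frozen=True)
class PathwayNetwork:
    """Graph of free-energy minima (nodes) connected through saddles (edges).

    Node attributes: ``position``, ``energy``, ``exterior`` (basin touches a
    grid face). Edge attributes: ``saddle_energy``, ``saddle_voxel``,
    ``barrier_forward`` (saddle − lower-id minimum), ``barrier_reverse``, and
    the traced ``path`` polyline.
    """

    graph: nx.Graph
    cutoff: float
    cutoff_mode: str

    @property
    def exterior_nodes(self) -> list[int]:
        return [u for u, d in self.graph.nodes(data=True) if d["exterior"]]

    def node_nearest(self, position) -> int:
        pos = np.asarray(position, float)
        nodes = list(self.graph.nodes)
        coords = np.array([self.graph.nodes[u]["position"] for u in nodes])
        return nodes[int(np.argmin(np.sum((coords - pos) ** 2, axis=1)))]


def _exterior_basins(labels: np.ndarray) -> set[int]:
    faces = [
        labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]
    ]
    out: set[int] = set()
    for f in faces:
        out.update(int(x) for x in np.unique(f) if x >= 0)
    return out


def build_network(
    grid: ScalarGrid3D,
    tess: BasinTessellation,
    saddles: list[Saddle],
    cutoff: float = 20.0,
    cutoff_mode: str = "voxel",
) -> PathwayNetwork:
    """Assemble the pathway network from minima and saddles.

    ``cutoff_mode`` selects how the construction cutoff is interpreted:
    "voxel" (default) assumes the tessellation already excluded voxels above
    the cutoff, so every surviving saddle is an edge; "saddle" keeps all
    voxels but only admits edges whose saddle energy is ≤ the cutoff. Both
    directional barriers are stored per edge; basins touching a face of the
    grid are flagged exterior.
    """
    if cutoff_mode not in ("voxel", "saddle"):
        raise ValidationError(f"cutoff_mode: unknown mode {cutoff_mode!r}")
    g = nx.Graph()
    exterior = _exterior_basins(tess.labels)
    for i in range(tess.n_basins):
        g.add_node(
            i,
            position=tess.minima_position[i],
            energy=float(tess.minima_energy[i]),
            exterior=i in exterior,
        )
    for s in saddles:
        if cutoff_mode == "saddle" and s.free_energy > cutoff:
            continue
        lo, hi = s.basin_pair
        g.add_edge(
            lo,
            hi,
            saddle_energy=s.free_energy,
            saddle_voxel=s.voxel,
            barrier_forward=s.free_energy - float(tess.minima_energy[lo]),
            barrier_reverse=s.free_energy - float(tess.minima_energy[hi]),
            path=s.path_positions,
        )
    return PathwayNetwork(graph=g, cutoff=float(cutoff), cutoff_mode=cutoff_mode)


@dataclass(frozen=True)
class ChannelProfile:
    """Alternating minimum/saddle free energies along a route of basins.

    ``forward_barriers[i]`` is the saddle between route nodes i and i+1 minus
    the energy of minimum i (the barrier climbed when moving forward along
    the route).
    """

    node_ids: list[int]
    minima_energies: np.ndarray
    saddle_energies: np.ndarray
    forward_barriers: np.ndarray
    minima_errors: np.ndarray | None = None  # NaN = uncomputable
    saddle_errors: np.ndarray | None = None

    def alternating_sequence(self) -> list[float]:
        seq = [float(self.minima_energies[0])]
        for s, m in zip(self.saddle_energies, self.minima_energies[1:]):
            seq.extend([float(s), float(m)])
        return seq


def extract_profile(network: PathwayNetwork, route: list[int]) -> ChannelProfile:
    """Energy profile along an ordered route of connected minima."""
    if len(route) < 2:
        raise ValidationError("route: need at least two nodes")
    g = network.graph
    minima = []
    saddles = []
    for u in route:
        if u not in g:
            raise ValidationError(f"route: node {u} not in network")
        minima.append(g.nodes[u]["energy"])
    for u, v in zip(route[:-1], route[1:]):
        if not g.has_edge(u, v):
            raise ValidationError(f"route: nodes {u} and {v} are not connected by a saddle")
        saddles.append(g.edges[u, v]["saddle_energy"])
    minima = np.array(minima)
    saddles = np.array(saddles)
    return ChannelProfile(
        node_ids=list(route),
        minima_energies=minima,
        saddle_energies=saddles,
        forward_barriers=saddles - minima[:-1],
    )


@dataclass(frozen=True)
class BlockErrorReport:
    """Half-difference errors between two data blocks.

    ``minima_errors``/``saddle_errors`` are |E_block1 − E_block2| / 2 for each
    matched feature of block 1; features without a counterpart within the
    matching radius are flagged uncomputable (NaN error, listed separately).
    """

    minima_errors: np.ndarray  # per block-1 minimum, NaN if unmatched
    minima_match: np.ndarray  # index into block-2 minima, -1 if unmatched
    saddle_errors: np.ndarray
    saddle_match: np.ndarray
    unmatched_minima: list[int]
    unmatched_saddles: list[int]


def _greedy_match(pos1: np.ndarray, pos2: np.ndarray, radius: float) -> np.ndarray:
    """Greedy nearest-pair matching within a radius; returns block-2 index per
    block-1 feature (−1 when unmatched)."""
    match = np.full(len(pos1), -1, int)
    if len(pos1) == 0 or len(pos2) == 0:
        return match
    d = np.sqrt(((pos1[:, None, :] - pos2[None, :, :]) ** 2).sum(-1))
    d = d.copy()
    while True:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if not np.isfinite(d[i, j]) or d[i, j] > radius:
            break
        match[i] = j
        d[i, :] = np.inf
        d[:, j] = np.inf
    return match


def block_errors(
    grid_block1: ScalarGrid3D,
    grid_block2: ScalarGrid3D,
    matching_radius: float = 2.0,
    connectivity: int = 26,
    cutoff: float = 20.0,
) -> BlockErrorReport:
    """Feature-wise uncertainty from two independent data blocks.

    The landscape analysis is run independently on each block's map; minima
    and saddles are matched greedily by nearest position within
    ``matching_radius`` (Å), and each matched feature's error is half the
    absolute energy difference between blocks. Features present in only one
    block are reported as error-uncomputable rather than zero.
    """
    if grid_block1.dims != grid_block2.dims or not np.allclose(
        grid_block1.origin, grid_block2.origin
    ) or not np.allclose(grid_block1.spacing, grid_block2.spacing):
        raise ValidationError("block grids must share dims, origin and spacing")

    t1 = tessellate(grid_block1, connectivity, cutoff)
    t2 = tessellate(grid_block2, connectivity, cutoff)
    s1 = find_saddles(grid_block1, t1)
    s2 = find_saddles(grid_block2, t2)

    mmatch = _greedy_match(t1.minima_position, t2.minima_position, matching_radius)
    merr = np.full(t1.n_basins, np.nan)
    for i, j in enumerate(mmatch):
        if j >= 0:
            merr[i] = 0.5 * abs(t1.minima_energy[i] - t2.minima_energy[j])

    def saddle_pos(grid, saddles):
        if not saddles:
            return np.zeros((0, 3))
        ijk = np.array([s.voxel for s in saddles], float)
        return grid.origin + grid.spacing * ijk

    sp1 = saddle_pos(grid_block1, s1)
    sp2 = saddle_pos(grid_block2, s2)
    smatch = _greedy_match(sp1, sp2, matching_radius)
    serr = np.full(len(s1), np.nan)
    for i, j in enumerate(smatch):
        if j >= 0:
            serr[i] = 0.5 * abs(s1[i].free_energy - s2[j].free_energy)

    return BlockErrorReport(
        minima_errors=merr,
        minima_match=mmatch,
        saddle_errors=serr,
        saddle_match=smatch,
        unmatched_minima=[i for i, j in enumerate(mmatch) if j < 0],
        unmatched_saddles=[i for i, j in enumerate(smatch) if j < 0],
    )


def minimax_energy(
    grid: ScalarGrid3D,
    position_a,
    position_b,
    connectivity: int = 26,
) -> float:
    """Lowest achievable maximum voxel value over all paths joining two points.

    Voxels enter in order of increasing value (union-find); the threshold at
    which the two endpoint voxels become connected is the minimax path energy —
    the height of the lowest pass between the two locations.
    """
    values = grid.values.ravel()
    n = values.size
    ia = np.ravel_multi_index(grid.index_of(position_a), grid.dims)
    ib = np.ravel_multi_index(grid.index_of(position_b), grid.dims)
    order = np.argsort(values, kind="stable")
    rank = np.empty(n, int)
    rank[order] = np.arange(n)

    parent = np.arange(n)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    tables = _flat_neighbour_tables(grid.dims, connectivity)
    neigh_src = np.concatenate([t[0] for t in tables])
    neigh_dst = np.concatenate([t[1] for t in tables])
    # group neighbour pairs by the later-activated endpoint
    later = np.where(rank[neigh_src] > rank[neigh_dst], neigh_src, neigh_dst)
    earlier = np.where(rank[neigh_src] > rank[neigh_dst], neigh_dst, neigh_src)
    by_later = np.argsort(rank[later], kind="stable")
    later, earlier = later[by_later], earlier[by_later]
    starts = np.searchsorted(rank[later], np.arange(n), side="left")
    ends = np.searchsorted(rank[later], np.arange(n), side="right")

    for r in range(n):
        v = order[r]
        for k in range(starts[r], ends[r]):
            assert later[k] == v
            parent[find(int(earlier[k]))] = find(int(v))
        if find(int(ia)) == find(int(ib)):
            return float(values[v])
    return np.inf
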