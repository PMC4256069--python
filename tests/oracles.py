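"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible — per-voxel Python loops,
explicit breadth-first searches — and shares no code with the package
internals it checks.
"""

from __future__ import annotations

import numpy as np


def offsets_for(connectivity: int):
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                o = abs(dx) + abs(dy) + abs(dz)
                if o == 0:
                    continue
                if connectivity == 6 and o > 1:
                    continue
                if connectivity == 18 and o > 2:
                    continue
                out.append((dx, dy, dz))
    return out


def brute_descend(values: np.ndarray, start_flat: int, connectivity: int, cutoff: float) -> int:
    """Follow lowest-(value, index) neighbours from one voxel to its minimum."""
    dims = values.shape
    flat = values.ravel()
    offs = offsets_for(connectivity)
    cur = int(start_flat)
    while True:
        ci = np.unravel_index(cur, dims)
        best = None
        for d in offs:
            n = tuple(c + o for c, o in zip(ci, d))
            if any(x < 0 or x >= s for x, s in zip(n, dims)):
                continue
            nf = int(np.ravel_multi_index(n, dims))
            if flat[nf] > cutoff:
                continue
            key = (flat[nf], nf)
            if best is None or key < best:
                best = key
        if best is not None and best < (flat[cur], cur):
            cur = best[1]
        else:
            return cur


def brute_tessellate(values: np.ndarray, connectivity: int, cutoff: float):
    """Per-voxel root indices (−1 excluded) by exhaustive descent."""
    flat = values.ravel()
    roots = np.full(flat.size, -1, int)
    for v in range(flat.size):
        if flat[v] > cutoff:
            continue
        roots[v] = brute_descend(values, v, connectivity, cutoff)
    return roots


def brute_saddles(values: np.ndarray, roots: np.ndarray, connectivity: int):
    """Saddle (energy, saddle voxel, partner voxel) per adjacent root pair."""
    dims = values.shape
    flat = values.ravel()
    offs = offsets_for(connectivity)
    best: dict[tuple[int, int], tuple] = {}
    for a in range(flat.size):
        if roots[a] < 0:
            continue
        ai = np.unravel_index(a, dims)
        for d in offs:
            n = tuple(c + o for c, o in zip(ai, d))
            if any(x < 0 or x >= s for x, s in zip(n, dims)):
                continue
            b = int(np.ravel_multi_index(n, dims))
            if roots[b] < 0 or roots[a] == roots[b] or a >= b:
                continue
            va, vb = flat[a], flat[b]
            if (va > vb) or (va == vb and a < b):
                sv, pv = a, b
            else:
                sv, pv = b, a
            key = tuple(sorted((int(roots[a]), int(roots[b]))))
            cand = (max(va, vb), sv, pv)
            if key not in best or cand < best[key]:
                best[key] = cand
    return best


def brute_minimax_within_union(
    values: np.ndarray, roots: np.ndarray, root_a: int, root_b: int, connectivity: int
) -> float:
    """Minimax path energy between two minima over their basins' union.

    Voxels of the two basins are admitted in order of increasing value; the
    threshold at which the two minima join (breadth-first search) is the
    minimax energy.
    """
    flat = values.ravel()
    dims = values.shape
    offs = offsets_for(connectivity)
    union = np.flatnonzero((roots == root_a) | (roots == root_b))
    levels = np.unique(flat[union])
    member = set(int(x) for x in union)
    for t in levels:
        allowed = {v for v in member if flat[v] <= t}
        if root_a not in allowed or root_b not in allowed:
            continue
        seen = {root_a}
        stack = [root_a]
        while stack:
            cur = stack.pop()
            ci = np.unravel_index(cur, dims)
            for d in offs:
                n = tuple(c + o for c, o in zip(ci, d))
                if any(x < 0 or x >= s for x, s in zip(n, dims)):
                    continue
                nf = int(np.ravel_multi_index(n, dims))
                if nf in allowed and nf not in seen:
                    seen.add(nf)
                    stack.append(nf)
        if root_b in seen:
            return float(t)
    return np.inf


def brute_components(mask: np.ndarray) -> int:
    """26-connected component count by explicit flood fill."""
    dims = mask.shape
    offs = offsets_for(26)
    seen = np.zeros(mask.shape, bool)
    count = 0
    for idx in np.argwhere(mask):
        t = tuple(idx)
        if seen[t]:
            continue
        count += 1
        stack = [t]
        seen[t] = True
        while stack:
            cur = stack.pop()
            for d in offs:
                n = tuple(c + o for c, o in zip(cur, d))
                if any(x < 0 or x >= s for x, s in zip(n, dims)):
                    continue
                if mask[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
    return count


def brute_pair_energy(pos1, eps1, sig1, pos2, eps2, sig2, cutoff) -> float:
    """Single 12-6 LJ pair with Lorentz-Berthelot combination."""
    r = float(np.linalg.norm(np.asarray(pos1, float) - np.asarray(pos2, float)))
    if r > cutoff:
        return 0.0
    eps = np.sqrt(eps1 * eps2)
    sig = 0.5 * (sig1 + sig2)
    return float(4.0 * eps * ((sig / r) ** 12 - (sig / r) ** 6))
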