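"""Sequential max-min reference solvers for fuzzy connectedness.

The connectedness of voxel c is the best (max) over all paths from the seed
set to c of the weakest (min) affinity along the path — the transitive
max-min closure of the pairwise affinity.  Computing it is a single-source
widest-path problem over the bottleneck semiring, solved here best-first
with a priority queue.  A literal simple-path enumeration oracle is provided
for tiny grids so the solver can be validated independently.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np

from .affinity import TINY, AffinityLUT
from .volume import FuzzyScene, SeedSet, Volume3D

__all__ = ["kfoe_reference", "brute_force_connectedness"]


def _flat_neighbors(shape: tuple[int, int, int]):
    """Per-voxel neighbor lists as flat indices (order -x,+x,-y,+y,-z,+z)."""
    nx, ny, nz = shape
    nyz = ny * nz
    nbrs: list[list[int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                vi = x * nyz + y * nz + z
                lst = []
                if x > 0:
                    lst.append(vi - nyz)
                if x < nx - 1:
                    lst.append(vi + nyz)
                if y > 0:
                    lst.append(vi - nz)
                if y < ny - 1:
                    lst.append(vi + nz)
                if z > 0:
                    lst.append(vi - 1)
                if z < nz - 1:
                    lst.append(vi + 1)
                nbrs.append(lst)
    return nbrs


def kfoe_reference(vol: Volume3D, seeds: SeedSet, lut: AffinityLUT,
                   tie_break_seed: int | None = None) -> FuzzyScene:
    """Best-first (descending-connectivity) computation of the fuzzy scene.

    Seeds start at 1; voxels are finalized in non-increasing connectivity
    order with lazy re-insertion.  Ties are broken FIFO by default; passing
    ``tie_break_seed`` randomizes tie-breaking instead, which must not (and
    does not) change the result — the max-min closure is unique.
    """
    seeds.check_bounds(vol)
    nx, ny, nz = vol.shape
    nyz = ny * nz
    inten = vol.data.ravel()
    sum_t = lut.sum_table
    diff_t = lut.diff_table
    if int(inten.max()) > lut.intensity_max:
        raise ValueError("volume intensities exceed LUT range")

    values = np.zeros(inten.size, dtype=np.float64)
    nbrs = _flat_neighbors(vol.shape)

    counter = itertools.count()
    rng = None if tie_break_seed is None else np.random.default_rng(tie_break_seed)

    def tiebreak() -> int:
        return int(rng.integers(1 << 30)) if rng is not None else next(counter)

    heap: list[tuple[float, int, int]] = []
    for (x, y, z) in seeds.coords:
        vi = x * nyz + y * nz + z
        values[vi] = 1.0
        heapq.heappush(heap, (-1.0, tiebreak(), vi))

    sqrt = np.sqrt
    while heap:
        negv, _, vi = heapq.heappop(heap)
        v = -negv
        if v < values[vi]:  # stale entry
            continue
        fv = inten[vi]
        for ni in nbrs[vi]:
            fn = inten[ni]
            g = sum_t[fv + fn] * diff_t[abs(int(fv) - int(fn))]
            aff = float(sqrt(g if g > TINY else TINY))
            cand = v if v < aff else aff
            if cand > values[ni]:
                values[ni] = cand
                heapq.heappush(heap, (-cand, tiebreak(), ni))

    return FuzzyScene(values.reshape(vol.shape), seeds)


def brute_force_connectedness(vol: Volume3D, seeds: SeedSet,
                              lut: AffinityLUT) -> FuzzyScene:
    """Exhaustive simple-path enumeration oracle for volumes of <= 32 voxels.

    Enumerates every simple path out of each seed by depth-first search and
    records, per voxel, the maximum over paths of the minimum affinity along
    the path.  No pruning is applied, so the cost is the number of
    self-avoiding walks — use only on tiny grids, in tests.
    """
    seeds.check_bounds(vol)
    n = int(np.prod(vol.shape))
    if n > 32:
        raise ValueError(f"brute-force oracle limited to <= 32 voxels, got {n}")
    nx, ny, nz = vol.shape
    nyz = ny * nz
    inten = vol.data.ravel()
    nbrs = _flat_neighbors(vol.shape)

    # Pairwise affinities up front; the graph has at most 3*n edges.
    aff = {}
    for vi in range(n):
        for ni in nbrs[vi]:
            g = lut.sum_table[inten[vi] + inten[ni]] * \
                lut.diff_table[abs(int(inten[vi]) - int(inten[ni]))]
            aff[(vi, ni)] = float(np.sqrt(g if g > TINY else TINY))

    best = np.zeros(n, dtype=np.float64)
    for (x, y, z) in seeds.coords:
        s = x * nyz + y * nz + z
        best[s] = 1.0
        stack = [(s, 1 << s, 1.0)]
        while stack:
            vi, visited, curmin = stack.pop()
            if curmin > best[vi]:
                best[vi] = curmin
            for ni in nbrs[vi]:
                if not (visited >> ni) & 1:
                    a = aff[(vi, ni)]
                    stack.append((ni, visited | (1 << ni),
                                  curmin if curmin < a else a))
    return FuzzyScene(best.reshape(vol.shape), seeds)
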