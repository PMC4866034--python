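"""Deterministic emulation of block-parallel fuzzy-connectedness propagation.

GPU implementations tile the volume into thread blocks and iterate a
flag-driven relaxation: active voxels push ``min(value, affinity)`` to their
six neighbors under an atomic-max write, newly improved voxels become active
for the next pass, and the loop stops when no voxel is active.  Blocks
execute with no mutual synchronization, so an improvement that crosses into
a block which has already run can be consumed stale — the improved value is
stored but its activation is lost and never re-propagates, leaving errors on
block faces.

This module reproduces that failure mode deterministically.  Blocks are
executed sequentially in a schedule-controlled order; under the asynchronous
policies a write into a block scheduled *earlier* in the current pass keeps
the value (atomic max) but drops the activation flag — the worst-case race.
The synchronous policy reads from a pass-start snapshot and never loses
flags, so it always reaches the exact closure.  Correction iterations then
re-activate block-face voxels (per face direction, 0..6 of them) and re-run
to quiescence, which provably drives any schedule to the exact sequential
result: lost activations can only sit on block faces, so a face-reactivated
round that changes nothing certifies the global fixpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .affinity import TINY, AffinityLUT, pair_affinity
from .volume import Coord, FuzzyScene, SeedSet, Volume3D

__all__ = [
    "Block", "BlockPartition", "BlockSchedule", "PropagationState",
    "partition", "init_state", "propagate_pass", "run_block_iterative",
    "enumerate_interleavings", "replay_events",
]

POLICIES = ("synchronous", "sequential_asynchronous", "adversarial")


@dataclass(frozen=True)
class Block:
    origin: Coord
    shape: Coord


@dataclass(frozen=True)
class BlockPartition:
    """Axis-aligned tiling of a volume into blocks.

    Blocks are ordered lexicographically by origin; edge blocks are clipped.
    Carries precomputed flat-index structures used by the propagation
    kernel: per-voxel block ids, per-block voxel lists, and per-direction
    block-face masks (face order -x, +x, -y, +y, -z, +z).
    """

    vol_shape: Coord
    block_shape: Coord
    blocks: tuple[Block, ...]
    block_of: np.ndarray = field(repr=False)       # int32, flat, len = n voxels
    blocks_flat: np.ndarray = field(repr=False)    # int64, concatenated voxel lists
    block_offsets: np.ndarray = field(repr=False)  # int64, len = n blocks + 1
    face_masks: np.ndarray = field(repr=False)     # bool, (6, n voxels)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def partition(vol: Volume3D, block_shape: Sequence[int]) -> BlockPartition:
    """Tile the volume with blocks of ``block_shape`` voxels."""
    bx, by, bz = (int(b) for b in block_shape)
    if min(bx, by, bz) < 1:
        raise ValueError(f"block shape components must be >= 1, got {block_shape}")
    nx, ny, nz = vol.shape
    nyz = ny * nz
    n = nx * nyz

    origins = [(ox, oy, oz)
               for ox in range(0, nx, bx)
               for oy in range(0, ny, by)
               for oz in range(0, nz, bz)]
    blocks = []
    block_of = np.empty(n, dtype=np.int32)
    voxel_lists = []
    face_masks = np.zeros((6, n), dtype=bool)
    for bid, (ox, oy, oz) in enumerate(origins):
        ex, ey, ez = min(ox + bx, nx), min(oy + by, ny), min(oz + bz, nz)
        blocks.append(Block(origin=(ox, oy, oz), shape=(ex - ox, ey - oy, ez - oz)))
        xs = np.arange(ox, ex)
        ys = np.arange(oy, ey)
        zs = np.arange(oz, ez)
        flat = (xs[:, None, None] * nyz + ys[None, :, None] * nz
                + zs[None, None, :]).ravel()
        block_of[flat] = bid
        voxel_lists.append(flat.astype(np.int64))
        grid = flat.reshape(ex - ox, ey - oy, ez - oz)
        face_masks[0, grid[0, :, :].ravel()] = True    # -x face
        face_masks[1, grid[-1, :, :].ravel()] = True   # +x face
        face_masks[2, grid[:, 0, :].ravel()] = True    # -y face
        face_masks[3, grid[:, -1, :].ravel()] = True   # +y face
        face_masks[4, grid[:, :, 0].ravel()] = True    # -z face
        face_masks[5, grid[:, :, -1].ravel()] = True   # +z face

    block_offsets = np.zeros(len(blocks) + 1, dtype=np.int64)
    np.cumsum([v.size for v in voxel_lists], out=block_offsets[1:])
    blocks_flat = np.concatenate(voxel_lists)
    return BlockPartition(
        vol_shape=(nx, ny, nz), block_shape=(bx, by, bz), blocks=tuple(blocks),
        block_of=block_of, blocks_flat=blocks_flat, block_offsets=block_offsets,
        face_masks=face_masks,
    )


@dataclass(frozen=True)
class BlockSchedule:
    """Block execution policy for one run.

    ``synchronous`` reads pass-start snapshots (no asynchrony errors);
    ``sequential_asynchronous`` executes blocks in lexicographic order with
    live reads; ``adversarial`` uses the explicit ``order`` if given, else a
    fresh random block permutation per pass seeded by ``rng_seed``.
    """

    policy: str = "sequential_asynchronous"
    rng_seed: int = 0
    order: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown schedule policy {self.policy!r}")
        if self.order is not None:
            object.__setattr__(self, "order", tuple(int(b) for b in self.order))

    def pass_order(self, part: BlockPartition, pass_index: int) -> np.ndarray:
        nb = part.n_blocks
        if self.policy == "adversarial":
            if self.order is not None:
                order = np.asarray(self.order, dtype=np.int64)
                if sorted(order.tolist()) != list(range(nb)):
                    raise ValueError("explicit order must be a permutation of blocks")
                return order
            rng = np.random.default_rng([int(self.rng_seed), int(pass_index)])
            return rng.permutation(nb).astype(np.int64)
        return np.arange(nb, dtype=np.int64)


@dataclass
class PropagationState:
    """Mutable solver state: connectivity values plus the two activity flag
    arrays (current pass / next pass) that drive the iteration."""

    fc: np.ndarray                 # float64, flat
    active_current: np.ndarray     # uint8, flat
    active_next: np.ndarray        # uint8, flat
    pass_count: int = 0
    last_updates: int = 0


def init_state(vol: Volume3D, seeds: SeedSet) -> PropagationState:
    seeds.check_bounds(vol)
    nx, ny, nz = vol.shape
    n = nx * ny * nz
    fc = np.zeros(n, dtype=np.float64)
    active = np.zeros(n, dtype=np.uint8)
    for (x, y, z) in seeds.coords:
        vi = (x * ny + y) * nz + z
        fc[vi] = 1.0
        active[vi] = 1
    return PropagationState(fc=fc, active_current=active,
                            active_next=np.zeros(n, dtype=np.uint8))


def _sweep(fc, read, act_cur, act_nxt, inten, sum_t, diff_t,
           block_of, block_rank, blocks_flat, block_off, order,
           lossy, nx, ny, nz):
    """One full pass over all blocks in ``order``.

    For each still-active voxel: clear its flag, push min(value, affinity)
    to each in-bounds face neighbor under an atomic-max write, and activate
    improved neighbors for the next pass — unless ``lossy`` and the neighbor
    belongs to a block ranked earlier in this pass, in which case the
    activation is dropped (the modeled inter-block race).  Returns the
    number of value improvements.
    """
    nyz = ny * nz
    nup = 0
    for oi in range(order.shape[0]):
        b = order[oi]
        for k in range(block_off[b], block_off[b + 1]):
            vi = blocks_flat[k]
            if act_cur[vi] == 0:
                continue
            act_cur[vi] = 0
            fcv = read[vi]
            x = vi // nyz
            rem = vi - x * nyz
            y = rem // nz
            z = rem - y * nz
            fv = inten[vi]
            for t in range(6):
                if t == 0:
                    if x == 0:
                        continue
                    ni = vi - nyz
                elif t == 1:
                    if x == nx - 1:
                        continue
                    ni = vi + nyz
                elif t == 2:
                    if y == 0:
                        continue
                    ni = vi - nz
                elif t == 3:
                    if y == ny - 1:
                        continue
                    ni = vi + nz
                elif t == 4:
                    if z == 0:
                        continue
                    ni = vi - 1
                else:
                    if z == nz - 1:
                        continue
                    ni = vi + 1
                fn = inten[ni]
                g = sum_t[fv + fn] * diff_t[abs(fv - fn)]
                if g < TINY:
                    g = TINY
                aff = math.sqrt(g)
                cand = fcv if fcv < aff else aff
                if cand > fc[ni]:
                    fc[ni] = cand
                    nup += 1
                    if lossy and block_rank[block_of[ni]] < oi:
                        pass  # activation lost to the inter-block race
                    else:
                        act_nxt[ni] = 1
    return nup


_sweep_py = _sweep
try:  # optional acceleration; the pure-Python function is the source of truth
    import numba

    _sweep = numba.njit(cache=False)(_sweep_py)
except ImportError:  # pragma: no cover
    pass


def propagate_pass(state: PropagationState, part: BlockPartition,
                   sched: BlockSchedule, lut: AffinityLUT,
                   vol: Volume3D) -> PropagationState:
    """Run one propagation pass in place and swap the flag arrays."""
    if state.fc.size != int(np.prod(vol.shape)):
        raise ValueError("state was initialized for a different volume")
    order = sched.pass_order(part, state.pass_count)
    block_rank = np.empty(part.n_blocks, dtype=np.int64)
    block_rank[order] = np.arange(part.n_blocks, dtype=np.int64)
    sync = sched.policy == "synchronous"
    read = state.fc.copy() if sync else state.fc
    nx, ny, nz = vol.shape
    state.last_updates = int(_sweep(
        state.fc, read, state.active_current, state.active_next,
        vol.data.ravel(), lut.sum_table, lut.diff_table,
        part.block_of, block_rank, part.blocks_flat, part.block_offsets,
        order, not sync, nx, ny, nz,
    ))
    state.active_current, state.active_next = state.active_next, state.active_current
    state.pass_count += 1
    return state


def _run_to_quiescence(state, part, sched, lut, vol) -> int:
    updates = 0
    while state.active_current.any():
        propagate_pass(state, part, sched, lut, vol)
        updates += state.last_updates
    return updates


def run_block_iterative(vol: Volume3D, seeds: SeedSet, lut: AffinityLUT,
                        part: BlockPartition, sched: BlockSchedule,
                        correction_directions: int = 6,
                        max_correction_rounds: int | None = None,
                        correction_scope: str = "faces",
                        stats: dict | None = None) -> FuzzyScene:
    """Block-iterative propagation followed by correction iterations.

    After the main loop quiesces, each correction round re-activates every
    voxel on a block face whose outward direction is among the first
    ``correction_directions`` of (-x, +x, -y, +y, -z, +z) and re-runs to
    quiescence.  By default rounds repeat until one changes no value: with
    all 6 directions a no-change round certifies the exact sequential
    closure (lost activations can only sit on block faces), and the loop
    always terminates because values ascend monotonically through a finite
    set.  ``max_correction_rounds`` optionally caps the rounds — a capped
    run may stop short of exactness on schedules with long stale chains.
    ``correction_scope`` may be set to ``"full"`` to re-activate the whole
    volume instead (debugging fallback).
    """
    if not (0 <= correction_directions <= 6):
        raise ValueError("correction_directions must be in [0, 6]")
    if correction_scope not in ("faces", "full"):
        raise ValueError("correction_scope must be 'faces' or 'full'")
    state = init_state(vol, seeds)
    _run_to_quiescence(state, part, sched, lut, vol)
    main_passes = state.pass_count

    if correction_scope == "full":
        react = np.ones(state.fc.size, dtype=bool)
    elif correction_directions > 0:
        react = part.face_masks[:correction_directions].any(axis=0)
    else:
        react = np.zeros(state.fc.size, dtype=bool)

    rounds = 0
    if react.any():
        while max_correction_rounds is None or rounds < max_correction_rounds:
            state.active_current[react] = 1
            changed = _run_to_quiescence(state, part, sched, lut, vol)
            rounds += 1
            if changed == 0:
                break
    if stats is not None:
        stats.update(main_passes=main_passes, total_passes=state.pass_count,
                     correction_rounds=rounds)
    return FuzzyScene(state.fc.reshape(vol.shape).copy(), seeds)


def enumerate_interleavings(events: Sequence, precede: Iterable[tuple] = ()) -> list[tuple]:
    """All admissible total orders of a small set of update events.

    ``events`` is a sequence of hashable update events and ``precede`` a set
    of ``(a, b)`` pairs meaning event ``a`` must run before event ``b``.
    Used in tests to replay every interleaving class of cross-block updates
    and classify which produce asynchrony errors.  Guarded to <= 10 events.
    """
    import networkx as nx

    events = list(events)
    if len(events) > 10:
        raise ValueError(f"interleaving enumeration limited to 10 events, got {len(events)}")
    if len(set(events)) != len(events):
        raise ValueError("events must be distinct")
    g = nx.DiGraph()
    g.add_nodes_from(events)
    for a, b in precede:
        if a not in g or b not in g:
            raise ValueError(f"precedence ({a!r}, {b!r}) references unknown event")
        g.add_edge(a, b)
    try:
        orders = [tuple(o) for o in nx.all_topological_sorts(g)]
    except nx.NetworkXUnfeasible as e:
        raise ValueError("precedence constraints contain a cycle") from e
    return sorted(orders, key=repr)


def replay_events(vol: Volume3D, lut: AffinityLUT, init: dict[Coord, float],
                  order: Sequence[tuple[Coord, Coord]]) -> np.ndarray:
    """Apply update events ``src -> dst`` in the given order.

    Each event performs the kernel's single update step,
    ``fc[dst] = max(fc[dst], min(fc[src], mu_k(src, dst)))``, on a value
    array initialized from ``init`` (unlisted voxels start at 0).  Returns
    the final value array; used to classify interleavings against the
    reference closure.
    """
    fc = np.zeros(vol.shape, dtype=np.float64)
    for c, v in init.items():
        fc[tuple(c)] = float(v)
    for src, dst in order:
        src = tuple(int(v) for v in src)
        dst = tuple(int(v) for v in dst)
        a = pair_affinity(lut, int(vol.data[src]), int(vol.data[dst]))
        cand = min(fc[src], a)
        if cand > fc[dst]:
            fc[dst] = cand
    return fc
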