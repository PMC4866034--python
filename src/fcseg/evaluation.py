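"""Scene comparison (error points), threshold segmentation, fixpoint checks.

"Error points" is the count of voxels whose connectivity differs between a
candidate solver and the sequential reference.  The default comparison is
exact (tolerance 0): both pipelines draw their values from the same finite
set of table-derived affinities combined only by min/max, so agreement, when
achieved, is bit-level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affinity import TINY, AffinityLUT
from .block_parallel import BlockPartition, BlockSchedule, run_block_iterative
from .reference import kfoe_reference
from .volume import FuzzyScene, SeedSet, Volume3D

__all__ = ["ComparisonReport", "error_points", "threshold_segment",
           "direction_sweep", "fixpoint_violations"]

_COORD_CAP = 1000


@dataclass(frozen=True)
class ComparisonReport:
    error_points: int
    max_abs_diff: float
    n_voxels: int
    differing_coords: tuple[tuple[int, int, int], ...] | None = None

    def to_dict(self) -> dict:
        return {
            "error_points": int(self.error_points),
            "max_abs_diff": float(self.max_abs_diff),
            "n_voxels": int(self.n_voxels),
        }


def _values(scene: FuzzyScene | np.ndarray) -> np.ndarray:
    return scene.values if isinstance(scene, FuzzyScene) else np.asarray(scene)


def error_points(ref: FuzzyScene | np.ndarray, test: FuzzyScene | np.ndarray,
                 tol: float = 0.0, collect_coords: bool = False) -> ComparisonReport:
    """Count voxels where ``|ref - test| > tol`` (default: exact comparison).

    Symmetric in its two scene arguments.  ``differing_coords`` is capped at
    1000 entries to bound report size.
    """
    a, b = _values(ref), _values(test)
    if a.shape != b.shape:
        raise ValueError(f"scene shape mismatch: {a.shape} vs {b.shape}")
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    diff = np.abs(a - b)
    bad = diff > tol
    coords = None
    if collect_coords:
        coords = tuple(tuple(int(v) for v in c)
                       for c in np.argwhere(bad)[:_COORD_CAP])
    return ComparisonReport(
        error_points=int(bad.sum()),
        max_abs_diff=float(diff.max()) if diff.size else 0.0,
        n_voxels=int(a.size),
        differing_coords=coords,
    )


def threshold_segment(scene: FuzzyScene | np.ndarray, theta: float) -> np.ndarray:
    """Binarize a fuzzy scene: ``mask[c] = scene[c] >= theta``."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {theta}")
    return _values(scene) >= theta


def fixpoint_violations(scene: FuzzyScene, vol: Volume3D, lut: AffinityLUT) -> int:
    """Count ordered adjacent pairs (c, d) violating the closure condition
    ``values[d] >= min(values[c], mu_k(c, d))``; 0 certifies a converged
    scene.  Seed values are checked by the FuzzyScene invariant itself."""
    vals = scene.values
    f = vol.data.astype(np.int64)
    if vals.shape != f.shape:
        raise ValueError("scene and volume shapes differ")
    total = 0
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        a, b = f[tuple(sl_lo)], f[tuple(sl_hi)]
        g = lut.sum_table[a + b] * lut.diff_table[np.abs(a - b)]
        aff = np.sqrt(np.maximum(g, TINY))
        va, vb = vals[tuple(sl_lo)], vals[tuple(sl_hi)]
        total += int((vb < np.minimum(va, aff)).sum())   # c -> d along +axis
        total += int((va < np.minimum(vb, aff)).sum())   # d -> c along -axis
    return total


def direction_sweep(vol: Volume3D, seeds: SeedSet, lut: AffinityLUT,
                    part: BlockPartition, sched: BlockSchedule,
                    max_correction_rounds: int | None = None) -> dict[int, int]:
    """Error points of the block-iterative solver against the sequential
    reference for every correction direction count 0..6."""
    ref = kfoe_reference(vol, seeds, lut)
    out: dict[int, int] = {}
    for k in range(7):
        scene = run_block_iterative(
            vol, seeds, lut, part, sched,
            correction_directions=k, max_correction_rounds=max_correction_rounds)
        out[k] = error_points(ref, scene).error_points
    return out
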