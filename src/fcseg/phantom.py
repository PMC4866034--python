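"""Synthetic tubular-vessel phantoms for testing the segmentation stack.

The generator emulates the intensity structure the affinity model assumes:
a bright tube (vessel) of Gaussian-distributed intensities over a darker
Gaussian background, as in contrast-enhanced CT of hepatic vasculature.
The ground-truth mask is geometric (distance to the centerline, pre-noise),
never intensity-derived.  All randomness is driven by a stored seed, so
identical specs yield bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .block_parallel import BlockPartition, BlockSchedule, partition
from .volume import SeedSet, Volume3D

__all__ = ["PhantomSpec", "generate_phantom", "make_fig2_fixture", "random_phantom_spec"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of a synthetic tube phantom.

    ``centerline`` is a polyline of control points in voxel units (a single
    point degenerates to a ball).  Foreground (tube) and background voxels
    draw Normal(fg_mean, fg_sd) and Normal(bg_mean, bg_sd) intensities,
    rounded to integers and clamped to ``[0, intensity_max]``.
    """

    shape: tuple[int, int, int]
    centerline: tuple[tuple[float, float, float], ...]
    radius: float = 2.0
    fg_mean: float = 180.0
    fg_sd: float = 10.0
    bg_mean: float = 60.0
    bg_sd: float = 10.0
    intensity_max: int = 255
    rng_seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        pts = tuple(tuple(float(v) for v in p) for p in self.centerline)
        if len(shape) != 3 or min(shape) < 1:
            raise ValueError(f"invalid phantom shape {self.shape}")
        if not pts:
            raise ValueError("centerline needs at least one control point")
        for p in pts:
            if not all(0 <= p[i] <= shape[i] - 1 for i in range(3)):
                raise ValueError(f"centerline point {p} outside volume {shape}")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.fg_mean == self.bg_mean:
            raise ValueError("fg_mean must differ from bg_mean")
        for m in (self.fg_mean, self.bg_mean):
            if not 0 <= m <= self.intensity_max:
                raise ValueError(f"mean {m} outside [0, {self.intensity_max}]")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "centerline", pts)


def _distance_to_polyline(shape: tuple[int, int, int],
                          pts: Sequence[Sequence[float]]) -> np.ndarray:
    """Euclidean distance (voxel units) from every voxel center to the
    polyline through ``pts``."""
    grid = np.stack(np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape),
                                indexing="ij"), axis=-1)   # (nx,ny,nz,3)
    pts = np.asarray(pts, dtype=np.float64)
    if len(pts) == 1:
        return np.linalg.norm(grid - pts[0], axis=-1)
    dist = np.full(shape, np.inf)
    for p, q in zip(pts[:-1], pts[1:]):
        seg = q - p
        L2 = float(seg @ seg)
        if L2 == 0.0:
            d = np.linalg.norm(grid - p, axis=-1)
        else:
            t = np.clip(((grid - p) @ seg) / L2, 0.0, 1.0)
            proj = p + t[..., None] * seg
            d = np.linalg.norm(grid - proj, axis=-1)
        np.minimum(dist, d, out=dist)
    return dist


def _polyline_midpoint(pts: Sequence[Sequence[float]]) -> np.ndarray:
    pts = np.asarray(pts, dtype=np.float64)
    if len(pts) == 1:
        return pts[0]
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg_len.sum())
    if total == 0.0:
        return pts[0]
    target = total / 2.0
    acc = 0.0
    for i, L in enumerate(seg_len):
        if acc + L >= target:
            t = (target - acc) / L if L > 0 else 0.0
            return pts[i] + t * (pts[i + 1] - pts[i])
        acc += L
    return pts[-1]


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, np.ndarray, SeedSet]:
    """Build (volume, ground-truth tube mask, suggested seed) from a spec.

    The suggested seed is the voxel nearest the centerline arc-length
    midpoint (snapped into the mask if rounding left it outside).
    """
    dist = _distance_to_polyline(spec.shape, spec.centerline)
    mask = dist <= spec.radius
    rng = np.random.default_rng(spec.rng_seed)
    fg = rng.normal(spec.fg_mean, spec.fg_sd, size=spec.shape)
    bg = rng.normal(spec.bg_mean, spec.bg_sd, size=spec.shape)
    data = np.where(mask, fg, bg)
    data = np.clip(np.rint(data), 0, spec.intensity_max).astype(np.int32)
    vol = Volume3D(data, intensity_max=spec.intensity_max)

    mid = _polyline_midpoint(spec.centerline)
    seed = tuple(int(v) for v in np.clip(np.rint(mid), 0,
                                         np.asarray(spec.shape) - 1))
    if not mask[seed]:  # rounding fell just outside the tube: snap to it
        tube = np.argwhere(mask)
        if tube.size == 0:
            raise ValueError("phantom tube mask is empty")
        nearest = tube[np.argmin(np.linalg.norm(tube - mid, axis=1))]
        seed = tuple(int(v) for v in nearest)
    return vol, mask, SeedSet((seed,))


def random_phantom_spec(rng: np.random.Generator,
                        shape: tuple[int, int, int] = (32, 32, 32),
                        n_points: int = 4) -> PhantomSpec:
    """Draw a randomized tube spec: a wandering polyline with margin from
    the volume border, used as the stress-test condition for the solvers."""
    shape = tuple(int(s) for s in shape)
    margin = 4.0
    pts = np.empty((n_points, 3))
    lo = np.full(3, margin)
    hi = np.asarray(shape, dtype=np.float64) - 1 - margin
    pts[0] = rng.uniform(lo, hi)
    for i in range(1, n_points):
        step = rng.uniform(-12.0, 12.0, size=3)
        pts[i] = np.clip(pts[i - 1] + step, lo, hi)
    return PhantomSpec(
        shape=shape,
        centerline=tuple(tuple(p) for p in pts),
        radius=float(rng.uniform(2.0, 3.0)),
        fg_mean=180.0, fg_sd=10.0, bg_mean=60.0, bg_sd=10.0,
        intensity_max=255,
        rng_seed=int(rng.integers(1 << 31)),
    )


def make_fig2_fixture() -> tuple[Volume3D, SeedSet, BlockPartition, BlockSchedule]:
    """Three-block corridor fixture exposing the inter-block asynchrony error.

    A 24x8x1 volume holds a bright corridor (intensity 200 over background
    40) running along x through three 8x8x1 blocks, seeded at the corridor's
    left end.  The returned adversarial schedule executes blocks right to
    left, so every improvement crossing a block boundary in +x lands in an
    already-executed block and its activation is lost: without correction
    the two downstream blocks never fill in, while one correction round per
    crossed boundary restores the exact scene.
    """
    data = np.full((24, 8, 1), 40, dtype=np.int32)
    data[:, 4, 0] = 200
    vol = Volume3D(data, intensity_max=255)
    seeds = SeedSet(((0, 4, 0),))
    part = partition(vol, (8, 8, 1))
    sched = BlockSchedule(policy="adversarial", order=(2, 1, 0))
    return vol, seeds, part, sched
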