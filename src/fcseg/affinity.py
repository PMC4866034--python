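"""Gaussian fuzzy spel affinity and its exact lookup-table backend.

The affinity between face-adjacent voxels c, d with intensities f(c), f(d) is

    mu_k(c, d) = mu_alpha(c, d) * sqrt( g1((f(c)+f(d))/2) * g2(|f(c)-f(d)|/2) )

where mu_alpha is the hard 6-adjacency indicator, g1 is a peak-normalized
Gaussian (mean m1, variance v1) on the pair mean, and g2 is a peak-normalized
zero-mean Gaussian (variance v2) on the half absolute difference.  Peak
normalization (max value 1, no 1/sqrt(2*pi*v) factor) is what keeps mu_k a
fuzzy relation bounded by 1.

Because intensities are integers, both Gaussian factors only ever get
evaluated at half-integers, so two 1-D tables indexed by the integer sum
``f(c)+f(d)`` and the integer absolute difference ``|f(c)-f(d)|`` reproduce
the direct evaluation bit-exactly in O(intensity_max) memory.  Every factor
and every product is floored at the smallest normal double so affinities are
strictly positive even when a Gaussian tail underflows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume import SeedSet, Volume3D

#: Positivity floor for Gaussian factors and their products (smallest normal
#: float64).  Keeps every affinity > 0 and makes direct and LUT evaluation
#: agree bit-for-bit even in the underflow regime.
TINY: float = float(np.finfo(np.float64).tiny)

#: Variance floor (intensity^2 units) applied when a seed region is constant.
VARIANCE_FLOOR: float = 1e-6


@dataclass(frozen=True)
class AffinityModel:
    """Parameters of the intensity affinity.

    ``m1``/``v1`` are the mean and variance of the pair-mean Gaussian g1
    (intensity and intensity^2 units); ``v2`` the variance of the zero-mean
    difference Gaussian g2.  Adjacency is fixed to the 6-face indicator.
    """

    m1: float
    v1: float
    v2: float
    adjacency: str = "face6"

    def __post_init__(self) -> None:
        if self.v1 <= 0 or self.v2 <= 0:
            raise ValueError("variances must be positive (floor them first)")
        if self.adjacency != "face6":
            raise ValueError(f"unsupported adjacency rule {self.adjacency!r}")

    def to_dict(self) -> dict:
        return {"m1": float(self.m1), "v1": float(self.v1), "v2": float(self.v2)}

    @classmethod
    def from_dict(cls, d: dict) -> "AffinityModel":
        return cls(m1=float(d["m1"]), v1=float(d["v1"]), v2=float(d["v2"]))


@dataclass(frozen=True)
class AffinityLUT:
    """Precomputed affinity tables.

    ``sum_table[s] = g1(s/2)`` for ``s in [0, 2*intensity_max]`` and
    ``diff_table[u] = g2(u/2)`` for ``u in [0, intensity_max]``; both floored
    at :data:`TINY` so all entries lie in ``(0, 1]``.
    """

    model: AffinityModel
    intensity_max: int
    sum_table: np.ndarray
    diff_table: np.ndarray


def estimate_model(vol: Volume3D, seeds: SeedSet, radius: int = 2,
                   sigma2_mode: str | float = "equal_v1") -> AffinityModel:
    """Estimate g1 from the intensities in boxes around the seeds.

    The sample region is the union of ``(2*radius+1)^3`` boxes centred on
    the seeds, clipped to the volume.  ``m1``/``v1`` are the sample mean and
    unbiased (n-1) sample variance, with ``v1`` floored at
    :data:`VARIANCE_FLOOR` for constant regions.  ``v2`` equals ``v1`` in
    the default ``"equal_v1"`` mode, or the given fixed value.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    seeds.check_bounds(vol)
    mask = np.zeros(vol.shape, dtype=bool)
    for (x, y, z) in seeds.coords:
        mask[max(0, x - radius):x + radius + 1,
             max(0, y - radius):y + radius + 1,
             max(0, z - radius):z + radius + 1] = True
    sample = vol.data[mask].astype(np.float64)
    if sample.size == 0:
        raise ValueError("empty seed sample region")
    m1 = float(sample.mean())
    v1 = VARIANCE_FLOOR if sample.size < 2 else float(sample.var(ddof=1))
    v1 = max(v1, VARIANCE_FLOOR)
    if sigma2_mode == "equal_v1":
        v2 = v1
    else:
        v2 = max(float(sigma2_mode), VARIANCE_FLOOR)
    return AffinityModel(m1=m1, v1=v1, v2=v2)


def _adjacent(c: Sequence[int], d: Sequence[int]) -> bool:
    diffs = [abs(int(c[i]) - int(d[i])) for i in range(3)]
    return sum(diffs) == 1 and max(diffs) == 1


def compute_affinity(model: AffinityModel, c: Sequence[int], d: Sequence[int],
                     vol: Volume3D) -> float:
    """Direct evaluation of mu_k(c, d): 1 on the diagonal, 0 off the
    6-neighborhood, else the Gaussian geometric mean of g1 and g2."""
    c = tuple(int(v) for v in c)
    d = tuple(int(v) for v in d)
    for p in (c, d):
        if not vol.contains(p):
            raise ValueError(f"coordinate {p} outside volume bounds {vol.shape}")
    if c == d:
        return 1.0
    if not _adjacent(c, d):
        return 0.0
    a = float(vol.data[c])
    b = float(vol.data[d])
    # Kept textually identical to the table-building expressions in
    # build_lut so both routes run the same float64 operations.
    g1 = np.exp(-(((a + b) / 2.0 - model.m1) ** 2) / (2.0 * model.v1))
    g2 = np.exp(-((abs(a - b) / 2.0) ** 2) / (2.0 * model.v2))
    g1 = max(float(g1), TINY)
    g2 = max(float(g2), TINY)
    return float(np.sqrt(max(g1 * g2, TINY)))


def build_lut(model: AffinityModel, intensity_max: int) -> AffinityLUT:
    """Tabulate g1 on integer sums and g2 on integer absolute differences."""
    if intensity_max < 1:
        raise ValueError("intensity_max must be >= 1")
    s = np.arange(2 * intensity_max + 1, dtype=np.float64)
    sum_table = np.exp(-((s / 2.0 - model.m1) ** 2) / (2.0 * model.v1))
    u = np.arange(intensity_max + 1, dtype=np.float64)
    diff_table = np.exp(-((u / 2.0) ** 2) / (2.0 * model.v2))
    np.maximum(sum_table, TINY, out=sum_table)
    np.maximum(diff_table, TINY, out=diff_table)
    return AffinityLUT(model=model, intensity_max=int(intensity_max),
                       sum_table=sum_table, diff_table=diff_table)


def pair_affinity(lut: AffinityLUT, fa: int, fb: int) -> float:
    """Affinity of an adjacent pair from its two integer intensities."""
    if not (0 <= fa <= lut.intensity_max and 0 <= fb <= lut.intensity_max):
        raise ValueError(
            f"intensity pair ({fa}, {fb}) exceeds LUT range [0, {lut.intensity_max}]"
        )
    g = lut.sum_table[fa + fb] * lut.diff_table[abs(fa - fb)]
    return float(np.sqrt(max(g, TINY)))


def lut_affinity(lut: AffinityLUT, c: Sequence[int], d: Sequence[int],
                 vol: Volume3D) -> float:
    """Table-backed mu_k(c, d); identical contract and bit-identical result
    to :func:`compute_affinity` for in-range integer intensities."""
    c = tuple(int(v) for v in c)
    d = tuple(int(v) for v in d)
    for p in (c, d):
        if not vol.contains(p):
            raise ValueError(f"coordinate {p} outside volume bounds {vol.shape}")
    if c == d:
        return 1.0
    if not _adjacent(c, d):
        return 0.0
    return pair_affinity(lut, int(vol.data[c]), int(vol.data[d]))
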