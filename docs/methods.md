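# Methods

## Model

A scene is a finite 3-D grid of non-negative integer intensities
f : C → {0, …, intensity_max} with 6-face adjacency.  Fuzzy connectedness
assigns each voxel the max-min path strength from a seed set S:

    FC(c) = max_{P: S→c} min_{(u,v)∈P} mu_k(u,v),      FC(s) = 1 for s ∈ S.

FC is the unique smallest fixpoint above the seed indicator of

    FC(d) ≥ min(FC(c), mu_k(c,d))   for every adjacent pair (c,d),

which is what `fcseg.evaluation.fixpoint_violations` certifies after any
solver run.

### Affinity

For adjacent voxels, `mu_k(c,d) = sqrt(g1((f(c)+f(d))/2) · g2(|f(c)−f(d)|/2))`,
with `g(x) = exp(−(x−m)²/2v)` *peak-normalized* (no 1/√(2πv) factor):
affinity must be a fuzzy relation in [0,1] with value 1 on the diagonal,
which fixes the normalization.  `g1` (mean m1, variance v1) scores object
brightness; `g2` (zero-mean, variance v2) scores homogeneity.  Defaults and
rationale:

- **m1, v1** — sample mean and unbiased (n−1) variance of the intensities
  in the union of (2r+1)³ boxes around the seeds, clipped to the volume;
  box radius r = 2 by default (a 5³ box stays inside a vessel of the
  phantom's calibre while giving n = 125 samples).
- **v2 = v1** by default (`sigma2_mode="equal_v1"`): the difference scale
  is not separately identifiable from a seed box, and tying it to the
  object variance makes the model one-parameter-family simple.  A fixed
  value may be passed instead.
- **Variance floor 10⁻⁶** (intensity²): constant seed regions otherwise
  give v = 0 and a degenerate Gaussian.
- **Positivity floor**: each Gaussian factor and each product is floored at
  the smallest normal float64 (≈ 2.2e−308), so affinities are strictly
  positive even deep in the tails.  Path strengths then distinguish
  "reachable only through the background" (≈ 1.5e−154 after the square
  root) from "unvisited" (0), and the block emulator's stalls are visible
  as exact zeros.

### Exact lookup table

Integer intensities mean g1 is only ever evaluated at s/2 for integer
s = f(c)+f(d) ∈ [0, 2·intensity_max] and g2 at u/2 for integer
u = |f(c)−f(d)| ∈ [0, intensity_max].  Two 1-D tables of those values
(floored as above) replace all transcendental work at solve time with two
loads, a multiply and a square root — O(intensity_max) memory rather than a
per-edge affinity volume.  The table build and the direct evaluation use
textually identical float64 expressions and the same ufuncs, so they agree
bit-for-bit over the whole integer range; the test suite checks all 256²
pairs exhaustively.

## Solvers

**Reference.**  Best-first search over the bottleneck semiring (the widest
path analogue of Dijkstra): pop the highest-connectivity voxel, relax its
six neighbors with `min(value, affinity)`, lazily re-insert improvements.
Ties are broken FIFO by default; a randomized tie-break mode exists purely
to demonstrate that the closure is unique and tie-order-independent.

**Oracle.**  Literal enumeration of every simple path out of each seed
(DFS with a visited bitmask, no pruning), taking per voxel the best path
minimum.  Cost is the number of self-avoiding walks, so it is guarded to
≤ 32 voxels; the randomized equivalence tests sample shapes of up to 18
voxels (3×3×2 and smaller), for which a volume enumerates in ≲ 0.03 s.
At that size a 200-volume battery covers chains, slabs and boxes with all
degenerate axis combinations.

**Block emulator.**  The volume is tiled into blocks (default 8³ — small
enough that 32³ phantoms contain 64 blocks and many inter-block faces).
State is the value array plus two activity flag arrays (current/next
pass).  One *pass* executes all blocks in a schedule-given order; each
still-active voxel clears its flag and relaxes its neighbors; an improved
neighbor is written under atomic-max semantics (concurrent candidates
resolve to their maximum — trivially true in sequential emulation, stated
as the contract any parallel backend must honor) and flagged for the next
pass.  Policies:

- `synchronous` — value reads come from a pass-start snapshot; flag writes
  are never lost.  Quiescence then implies the exact fixpoint.
- `sequential_asynchronous` — live reads, blocks in lexicographic order.
- `adversarial` — live reads, explicit or per-pass-randomized block order.

Under both asynchronous policies the emulator models the worst-case
inter-block race: an improvement written into a block ranked *earlier* in
the current pass keeps the value but **loses the activation flag**.  This
is a deliberate design choice, not a claim about any particular GPU
runtime: with reliable flags, any fair chaotic iteration converges to the
unique fixpoint and no asynchrony error can ever appear, so the race on
the flag arrays is precisely what the correction step exists to repair.
Making every race window fire deterministically gives reproducible worst
cases and makes the correction machinery testable.  The six classical
interleavings of two cross-boundary updates (and which of them corrupt the
downstream voxel) are reproduced by `enumerate_interleavings` +
`replay_events` rather than by luck of thread timing.

**Correction iterations.**  After the main loop quiesces, a correction
round re-activates every voxel on a block face whose outward direction is
among the first K of (−x, +x, −y, +y, −z, +z) — K is the "iteration
directions" dial, 0–6 — and re-runs passes to quiescence.  Rounds repeat
until one changes no value.  Two facts make this exact at K = 6:
lost activations can only sit on block-face voxels (interior voxels only
ever receive same-block writes, which are never lossy), and values ascend
monotonically through a finite set, so the loop terminates and a no-change
round certifies that no face voxel has unpropagated information — i.e. the
global fixpoint.  A `max_correction_rounds` cap is available but defaults
to off: under the worst-case race model, wandering high-affinity paths in
noisy 32³ phantoms needed up to ~20 rounds, and any fixed small cap can
stop short of exactness (the tests demonstrate this with a cap of 1 on the
corridor fixture).  A `correction_scope="full"` debugging fallback
re-activates the whole volume instead of faces only.

## Synthetic phantoms

`generate_phantom` emulates the intensity structure the affinity model
assumes: a tube of radius ~2–3 voxels around a polyline centerline, with
foreground intensities Normal(180, 10) against background Normal(60, 10)
on an 8-bit range — a bright-vessel/dark-parenchyma contrast with mild
noise, rounded to integers and clamped (rounding is explicit because the
lookup table requires integers).  The ground-truth mask is geometric
(distance to centerline ≤ radius, pre-noise), never intensity-derived.
The suggested seed is the voxel nearest the centerline's arc-length
midpoint.  All randomness flows from a stored seed; identical specs are
bit-identical.

What the phantom does *not* model: branching vessel trees, calibre
variation, partial-volume blur, beam hardening, or anisotropic spacing.
Passing tests therefore show the algorithms are exact on
Gaussian-two-class tubular scenes, not that the affinity model is adequate
for any particular clinical data.

The corridor fixture (`make_fig2_fixture`) is the minimal adversarial
case: a noise-free bright corridor crossing three blocks with the schedule
reversed against the propagation direction, so every boundary crossing
loses its flag.  Uncorrected it leaves exactly the 120 voxels beyond the
first boundary stale; one correction round per crossed boundary (3 rounds
total, including the final no-change round) restores exactness.

## Numerical choices

- All connectivity values are produced by min/max selections over the
  finite set of table-derived affinities, so solver agreement is asserted
  bit-exactly (tolerance 0) throughout; `error_points` takes a tolerance
  parameter only for comparing against third-party implementations with
  different float pipelines.
- Scenes are float64 in memory and written as 32-bit float volumes.
- Within a pass, a block's voxels are visited in ascending flat-index
  order; the neighbor order is fixed as (−x, +x, −y, +y, −z, +z).  Both
  orders are observationally irrelevant at convergence (unique fixpoint)
  but fixed for reproducible traces.
- Seeds always hold exactly 1.0 and are never overwritten (no candidate
  can exceed 1).

## Limitations

- The emulator is sequential; it reproduces interleaving *classes*, not
  true concurrency or memory-model effects, and wall-clock performance is
  out of scope.
- Single-object segmentation only: no relative/iterative-relative fuzzy
  connectedness, no multi-object competition.
- The affinity is isotropic; voxel spacing is carried through I/O but does
  not enter the affinity.
- Multi-seed runs treat seeds as one object (union); per-seed objects are
  not separated.
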