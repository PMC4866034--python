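"""Reproduce the inter-block asynchrony error and repair it.

The corridor fixture routes a bright path through three blocks while an
adversarial schedule executes the blocks right-to-left, so every update
crossing a block boundary lands in an already-executed block and its
activation flag is lost.  Without correction the downstream blocks never
fill in; face-reactivating correction iterations restore exact agreement
with the sequential reference.
"""

import fcseg as F

vol, seeds, part, sched = F.make_fig2_fixture()
model = F.estimate_model(vol, seeds, radius=0)
lut = F.build_lut(model, vol.intensity_max)
ref = F.kfoe_reference(vol, seeds, lut)

for k in (0, 6):
    stats = {}
    scene = F.run_block_iterative(vol, seeds, lut, part, sched,
                                  correction_directions=k, stats=stats)
    rep = F.error_points(ref, scene)
    print(f"correction_directions={k}: error points = {rep.error_points} "
          f"of {rep.n_voxels} voxels "
          f"({stats['total_passes']} passes, "
          f"{stats['correction_rounds']} correction rounds)")

table = F.direction_sweep(vol, seeds, lut, part, sched)
print("direction sweep 0..6:", [table[k] for k in range(7)])
# Error points fall monotonically as more block-face directions are
# re-activated, reaching zero with all six — the corrected block solver is
# bit-identical to the sequential algorithm.
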