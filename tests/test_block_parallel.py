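import numpy as np
import pytest

import fcseg as F
from fcseg.block_parallel import init_state, propagate_pass

MODEL = F.AffinityModel(m1=100.0, v1=100.0, v2=100.0)


def _uniform_vol(shape, value=100):
    return F.Volume3D(np.full(shape, value, dtype=np.int32), intensity_max=255)


class TestPartition:
    def test_exact_tiling_single_block(self):
        part = F.partition(_uniform_vol((8, 8, 8)), (8, 8, 8))
        assert part.n_blocks == 1
        assert part.blocks[0].shape == (8, 8, 8)

    def test_edge_block_is_clipped(self):
        part = F.partition(_uniform_vol((9, 8, 8)), (8, 8, 8))
        assert part.n_blocks == 2
        assert part.blocks[1].origin == (8, 0, 0)
        assert part.blocks[1].shape == (1, 8, 8)

    def test_block_larger_than_volume(self):
        part = F.partition(_uniform_vol((3, 3, 3)), (8, 8, 8))
        assert part.n_blocks == 1
        assert part.blocks[0].shape == (3, 3, 3)

    def test_blocks_disjointly_cover_volume(self):
        part = F.partition(_uniform_vol((9, 5, 3)), (4, 2, 2))
        sizes = [np.prod(b.shape) for b in part.blocks]
        assert sum(sizes) == 9 * 5 * 3
        counts = np.bincount(part.block_of, minlength=part.n_blocks)
        assert counts.tolist() == sizes

    def test_invalid_block_shape(self):
        with pytest.raises(ValueError, match=">= 1"):
            F.partition(_uniform_vol((4, 4, 4)), (0, 4, 4))


class TestPropagatePass:
    def test_one_pass_advances_chain_by_one_voxel(self):
        vol = _uniform_vol((3, 1, 1))
        lut = F.build_lut(MODEL, vol.intensity_max)
        part = F.partition(vol, (8, 8, 8))
        sched = F.BlockSchedule(policy="synchronous")
        state = init_state(vol, F.SeedSet(((0, 0, 0),)))
        propagate_pass(state, part, sched, lut, vol)
        assert state.fc.tolist() == [1.0, 1.0, 0.0]  # uniform: affinity 1
        assert state.active_current.tolist() == [0, 1, 0]

    def test_concurrent_writers_resolve_to_their_maximum(self):
        # the atomic-max contract: two active writers into one voxel in the
        # same pass leave the larger candidate
        vol = _uniform_vol((3, 1, 1))
        lut = F.build_lut(MODEL, vol.intensity_max)
        part = F.partition(vol, (8, 8, 8))
        sched = F.BlockSchedule(policy="synchronous")
        state = init_state(vol, F.SeedSet(((0, 0, 0),)))
        state.fc[:] = [0.9, 0.0, 0.7]
        state.active_current[:] = [1, 0, 1]
        propagate_pass(state, part, sched, lut, vol)
        assert state.fc[1] == 0.9

    def test_uninitialized_state_shape_mismatch(self):
        vol = _uniform_vol((3, 1, 1))
        lut = F.build_lut(MODEL, vol.intensity_max)
        part = F.partition(vol, (8, 8, 8))
        state = init_state(_uniform_vol((4, 1, 1)), F.SeedSet(((0, 0, 0),)))
        with pytest.raises(ValueError, match="different volume"):
            propagate_pass(state, part, F.BlockSchedule(), lut, vol)


class TestRunBlockIterative:
    @pytest.mark.parametrize("policy", F.block_parallel.POLICIES)
    def test_single_block_needs_no_correction(self, policy, tiny_case_factory):
        rng = np.random.default_rng(21)
        vol, seeds, lut = tiny_case_factory(rng, shape=(4, 4, 1))
        part = F.partition(vol, (8, 8, 8))
        ref = F.kfoe_reference(vol, seeds, lut)
        scene = F.run_block_iterative(vol, seeds, lut, part,
                                      F.BlockSchedule(policy=policy),
                                      correction_directions=0)
        assert np.array_equal(scene.values, ref.values)

    def test_synchronous_policy_reaches_fixpoint_without_correction(
            self, small_phantom_case):
        vol, seeds, lut, ref = small_phantom_case
        part = F.partition(vol, (4, 4, 4))
        scene = F.run_block_iterative(vol, seeds, lut, part,
                                      F.BlockSchedule(policy="synchronous"),
                                      correction_directions=0)
        assert np.array_equal(scene.values, ref.values)

    def test_adversarial_order_on_split_chain_loses_propagation(self):
        # two blocks, seed in the left one, right block scheduled first:
        # the crossing update's activation is lost, so the right half stalls
        vol = _uniform_vol((16, 1, 1))
        lut = F.build_lut(MODEL, vol.intensity_max)
        seeds = F.SeedSet(((0, 0, 0),))
        part = F.partition(vol, (8, 1, 1))
        sched = F.BlockSchedule(policy="adversarial", order=(1, 0))
        ref = F.kfoe_reference(vol, seeds, lut)
        bad = F.run_block_iterative(vol, seeds, lut, part, sched,
                                    correction_directions=0)
        assert F.error_points(ref, bad).error_points == 7  # x = 9..15 stall
        good = F.run_block_iterative(vol, seeds, lut, part, sched,
                                     correction_directions=6)
        assert np.array_equal(good.values, ref.values)

    def test_monotone_ascent_bounded_by_reference(self, small_phantom_case):
        vol, seeds, lut, ref = small_phantom_case
        part = F.partition(vol, (4, 4, 4))
        sched = F.BlockSchedule(policy="adversarial", rng_seed=3)
        state = init_state(vol, seeds)
        prev = state.fc.copy()
        bound = ref.values.ravel()
        while state.active_current.any():
            propagate_pass(state, part, sched, lut, vol)
            assert np.all(state.fc >= prev)       # values never decrease
            assert np.all(state.fc <= bound)      # never overshoot the closure
            prev = state.fc.copy()

    def test_full_volume_correction_scope_is_exact_too(self, fig2_case):
        vol, seeds, part, sched, lut = fig2_case
        ref = F.kfoe_reference(vol, seeds, lut)
        scene = F.run_block_iterative(vol, seeds, lut, part, sched,
                                      correction_directions=0,
                                      correction_scope="full")
        assert np.array_equal(scene.values, ref.values)

    def test_capped_correction_rounds_can_stop_short(self, fig2_case):
        # the corridor crosses two block boundaries; a single correction
        # round fixes only the first, so a cap of 1 leaves errors
        vol, seeds, part, sched, lut = fig2_case
        ref = F.kfoe_reference(vol, seeds, lut)
        capped = F.run_block_iterative(vol, seeds, lut, part, sched,
                                       correction_directions=6,
                                       max_correction_rounds=1)
        assert F.error_points(ref, capped).error_points > 0

    def test_invalid_parameters_rejected(self, fig2_case):
        vol, seeds, part, sched, lut = fig2_case
        with pytest.raises(ValueError, match="correction_directions"):
            F.run_block_iterative(vol, seeds, lut, part, sched,
                                  correction_directions=7)
        with pytest.raises(ValueError, match="permutation"):
            bad = F.BlockSchedule(policy="adversarial", order=(0, 0, 1))
            F.run_block_iterative(vol, seeds, lut, part, bad)
        with pytest.raises(ValueError, match="policy"):
            F.BlockSchedule(policy="chaotic")


class TestInterleavings:
    def test_empty_event_set_has_one_empty_order(self):
        assert F.enumerate_interleavings([]) == [()]

    def test_two_independent_events_have_two_orders(self):
        assert len(F.enumerate_interleavings(["a", "b"])) == 2

    def test_precedence_chain_forces_single_order(self):
        orders = F.enumerate_interleavings(
            ["a", "b", "c"], precede=[("a", "b"), ("b", "c")])
        assert orders == [("a", "b", "c")]

    def test_cycle_is_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            F.enumerate_interleavings(["a", "b"], precede=[("a", "b"), ("b", "a")])

    def test_guard_on_event_count(self):
        with pytest.raises(ValueError, match="10"):
            F.enumerate_interleavings(list(range(11)))

    def test_replay_classifies_which_interleavings_err(self):
        # square of pixels: 1=(0,0) holds the late upstream value, 2=(1,0)
        # and 3=(0,1) hold stale values, 5=(1,1) is downstream.  The update
        # events are 1->2, 1->3, 2->5, 3->5 in every admissible order;
        # pixel 5 ends correct iff some refreshed neighbor fires afterwards.
        vol = _uniform_vol((2, 2, 1))  # uniform at the model mean: affinity 1
        lut = F.build_lut(MODEL, vol.intensity_max)
        p1, p2, p3, p5 = (0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)
        init = {p1: 0.8, p2: 0.1, p3: 0.1}
        events = [(p1, p2), (p1, p3), (p2, p5), (p3, p5)]
        orders = F.enumerate_interleavings(events)
        assert len(orders) == 24
        outcomes = set()
        for order in orders:
            fc = F.replay_events(vol, lut, init, order)
            correct = (order.index((p1, p2)) < order.index((p2, p5))
                       or order.index((p1, p3)) < order.index((p3, p5)))
            assert fc[p5] == (0.8 if correct else 0.1)
            outcomes.add(fc[p5])
        assert outcomes == {0.8, 0.1}  # both healthy and erroneous orders exist
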