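"""Unwrapping engine: quality map, seeding, merging, residual growing."""

import itertools

import numpy as np
import pytest

from polyunwrap import (TWO_PI, UnwrapParams, WrappedVolume, build_partition,
                        compute_mcr, compute_quality_map, merge_all_blocks,
                        nearest_block, seed_state, select_fitting_voxels,
                        estimate_block_offset, unwrap, unwrap_residuals)
from polyunwrap.core import UnwrapState
from polyunwrap.partition import Block, RegionPartition


def _manual_partition(labels, counts=None, first=None, second=None,
                      subintervals=None):
    labels = np.asarray(labels, np.int32)
    ids = [int(i) for i in np.unique(labels) if i > 0]
    blocks = [Block(id=i,
                    subinterval=(subintervals or {}).get(i, 1),
                    count=int((labels == i).sum()) if counts is None
                    else counts[i])
              for i in ids]
    shape = labels.shape
    return RegionPartition(
        labels=labels, blocks=blocks,
        first_residual=first if first is not None else np.zeros(shape, bool),
        second_residual=second if second is not None else np.zeros(shape, bool),
        size_threshold=1)


class TestQualityMap:
    def test_constant_phase_scores_zero(self, constant_volume):
        q = compute_quality_map(constant_volume)
        assert np.allclose(q.quality[constant_volume.mask], 0.0)

    def test_outlier_is_local_maximum(self):
        phase = np.zeros((7, 7, 7))
        phase[3, 3, 3] = np.pi / 2
        q = compute_quality_map(WrappedVolume(phase)).quality
        assert q[3, 3, 3] == q.max()
        assert q[3, 3, 3] > q[3, 3, 4]

    def test_linear_ramp_interior_value(self):
        a = 0.3
        phase = a * np.arange(5.0)[:, None, None] * np.ones((5, 5, 5))
        q = compute_quality_map(WrappedVolume(phase)).quality
        # 26 neighbors: 9 at dx=+1 and 9 at dx=-1 contribute (a)^2 each
        expected = a * np.sqrt(18 / 26)
        assert q[2, 2, 2] == pytest.approx(expected, abs=1e-12)

    def test_isolated_masked_voxel_scores_worst(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = True
        q = compute_quality_map(WrappedVolume(np.zeros((5, 5, 5)), mask=mask))
        assert np.isfinite(q.quality[0, 0, 0])
        assert q.quality[0, 0, 0] > np.pi  # worse than any achievable RMS


class TestSeedState:
    def test_largest_block_seeds(self):
        labels = np.zeros((10, 10, 10), np.int32)
        labels[0:2] = 1    # 200
        labels[3:6] = 2    # 300
        labels[7:9] = 3    # 200
        part = _manual_partition(labels)
        vol = WrappedVolume(np.full((10, 10, 10), 0.2))
        st = seed_state(part, vol)
        assert st.done[4, 0, 0] and not st.done[0, 0, 0]
        np.testing.assert_array_equal(st.k[st.done], 0)

    def test_tie_breaks_to_smaller_id(self):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[0:2] = 2
        labels[4:6] = 1
        part = _manual_partition(labels)
        vol = WrappedVolume(np.zeros((8, 8, 8)))
        st = seed_state(part, vol)
        assert st.done[4, 0, 0] and not st.done[0, 0, 0]

    def test_no_blocks_rejected(self):
        part = _manual_partition(np.zeros((4, 4, 4), np.int32))
        with pytest.raises(ValueError):
            seed_state(part, WrappedVolume(np.zeros((4, 4, 4))))


class TestNearestBlock:
    def test_prefers_smaller_gap(self):
        labels = np.zeros((30, 5, 5), np.int32)
        labels[0:5] = 1      # seed
        labels[7:12] = 2     # gap 2
        labels[17:22] = 3    # gap 5 from block 2, farther from seed
        part = _manual_partition(labels)
        vol = WrappedVolume(np.zeros((30, 5, 5)))
        st = seed_state(part, vol)
        assert nearest_block(st, part) == 2

    def test_chain_merge_order_matches_hand_distances(self):
        # blocks at x in [0,3], [5,8], [13,16], [18,21]: from the seed the
        # nearest is at distance 2, then chain 13 (dist 5->2 after merge)...
        labels = np.zeros((24, 4, 4), np.int32)
        spans = {1: (0, 4), 2: (5, 9), 3: (13, 17), 4: (18, 22)}
        for i, (a, b) in spans.items():
            labels[a:b] = i
        part = _manual_partition(labels)
        vol = WrappedVolume(np.zeros((24, 4, 4)))
        st = seed_state(part, vol)  # block 1..4 equal size: id 1 seeds
        st, demoted, order = merge_all_blocks(
            st, part, vol, UnwrapParams(size_threshold=1, fitting_count=30,
                                        merge_max_distance=10.0))
        assert order == [2, 3, 4]
        assert not demoted.any()

    def test_adjacent_block_always_preferred(self):
        labels = np.zeros((20, 5, 5), np.int32)
        labels[0:5] = 1
        labels[5:8] = 2      # touching: distance 1
        labels[12:15] = 3    # gap
        part = _manual_partition(labels)
        vol = WrappedVolume(np.zeros((20, 5, 5)))
        st = seed_state(part, vol)
        assert nearest_block(st, part) == 2


class TestSelectFittingVoxels:
    def test_truncation_when_done_small(self):
        labels = np.zeros((10, 4, 4), np.int32)
        labels[0:2] = 1   # 32 voxels < fitting_count
        labels[5:8] = 2
        part = _manual_partition(labels)
        vol = WrappedVolume(np.zeros((10, 4, 4)))
        st = seed_state(part, vol)  # block 2 larger -> seeds
        fit_c, tgt_c = select_fitting_voxels(st, part.block_mask(1), 100)
        assert len(fit_c) == 48       # whole done set (block 2)
        assert len(tgt_c) == 32       # whole block 1

    def test_matches_brute_force_nearest_oracle(self, rng):
        done = np.zeros((12, 12, 12), bool)
        done[0:5] = True
        block = np.zeros((12, 12, 12), bool)
        block[7:12] = True
        st = UnwrapState.empty((12, 12, 12))
        st.done = done
        count = 40
        fit_c, tgt_c = select_fitting_voxels(st, block, count)
        dcoords = np.argwhere(done)
        bcoords = np.argwhere(block)
        d2 = ((dcoords[:, None, :] - bcoords[None, :, :]) ** 2).sum(-1)
        # oracle: done voxels by min distance to block (stable by index)
        key = np.sqrt(d2.min(axis=1))
        oracle_fit = dcoords[np.lexsort(
            (np.arange(len(dcoords)), key))][:count]
        np.testing.assert_array_equal(fit_c, oracle_fit)
        key_t = np.sqrt(d2.min(axis=0))
        oracle_tgt = bcoords[np.lexsort(
            (np.arange(len(bcoords)), key_t))][:count]
        np.testing.assert_array_equal(tgt_c, oracle_tgt)


class TestBlockOffset:
    def _ramp_halves(self, slope=0.38):
        """Smooth ramp whose second half lies one turn up: the stored
        (wrapped) representation of half B is displaced by -2*pi."""
        x, y, _ = np.meshgrid(*[np.arange(16.0)] * 3, indexing="ij")
        truth = 0.2 + slope * x + 0.02 * (y - 8) ** 2 / 8
        wrapped = np.pi - np.mod(np.pi - truth, TWO_PI)
        labels = np.zeros((16, 16, 16), np.int32)
        labels[:8] = 1    # truth < pi: wrap-free half, k = 0
        labels[8:] = 2    # truth in (pi, 3*pi): k = 1
        part = _manual_partition(labels)
        return truth, part, WrappedVolume(wrapped)

    def test_two_half_volumes_recover_displacement(self):
        truth, part, vol = self._ramp_halves()
        st = seed_state(part, vol)   # equal halves: block 1 seeds
        fit_c, tgt_c = select_fitting_voxels(st, part.block_mask(2), 100)
        k = estimate_block_offset(st, vol, fit_c, tgt_c, UnwrapParams())
        assert k == 1
        st, demoted, _ = merge_all_blocks(st, part, vol, UnwrapParams())
        np.testing.assert_allclose(st.unwrapped, truth, atol=1e-9)

    def test_identical_interface_gives_zero(self):
        phase = np.full((12, 12, 12), 0.4)
        labels = np.zeros((12, 12, 12), np.int32)
        labels[:6] = 1
        labels[6:] = 2
        part = _manual_partition(labels)
        vol = WrappedVolume(phase)
        st = seed_state(part, vol)
        fit_c, tgt_c = select_fitting_voxels(st, part.block_mask(2), 100)
        assert estimate_block_offset(st, vol, fit_c, tgt_c,
                                     UnwrapParams()) == 0

    def test_vote_method_constant_ks(self):
        # done half holds a steep exact ramp; every target voxel of the
        # growing half sits three turns up, so all per-voxel offsets are 3
        a = 2.2
        x, _, _ = np.meshgrid(*[np.arange(16.0)] * 3, indexing="ij")
        truth = a * x
        wrapped = np.pi - np.mod(np.pi - truth, TWO_PI)
        labels = np.zeros((16, 16, 16), np.int32)
        labels[:8] = 1
        labels[8:] = 2
        part = _manual_partition(labels)
        vol = WrappedVolume(wrapped)
        st = UnwrapState.empty((16, 16, 16))
        st.done = labels == 1
        st.unwrapped[st.done] = truth[st.done]
        st.k[st.done] = np.round(
            (truth - wrapped)[st.done] / TWO_PI).astype(np.int32)
        fit_c, tgt_c = select_fitting_voxels(st, part.block_mask(2), 100)
        expected = int(np.round((truth - wrapped)[8, 0, 0] / TWO_PI))
        assert expected == 3   # 2.2 * 8 = 17.6 rad is in (5*pi, 7*pi)
        k = estimate_block_offset(st, vol, fit_c, tgt_c,
                                  UnwrapParams(block_offset_method="vote"))
        assert k == expected


class TestMergeAllBlocks:
    def test_single_block_partition_unchanged(self, constant_volume):
        part = build_partition(constant_volume, size_threshold=100)
        st = seed_state(part, constant_volume)
        before = st.done.copy()
        st, demoted, order = merge_all_blocks(st, part, constant_volume,
                                              UnwrapParams())
        assert order == [] and not demoted.any()
        np.testing.assert_array_equal(st.done, before)

    def test_noiseless_phantom_equals_truth_up_to_global_turn(
            self, smooth_phantom):
        vol = WrappedVolume(smooth_phantom.wrapped_phase)
        state, _ = unwrap(vol)
        diff = state.unwrapped - smooth_phantom.true_phase
        g = np.round(np.median(diff) / TWO_PI)
        np.testing.assert_allclose(diff, TWO_PI * g, atol=1e-6)

    def test_ramp_blocks_match_exhaustive_oracle(self):
        # 1D ramp crossing several subintervals; per-block offsets must
        # match a brute-force search over k-combinations minimizing the
        # summed squared interface discontinuity
        a = 0.18
        phase = a * np.arange(26.0)[:, None, None] * np.ones((26, 8, 8))
        wrapped = np.pi - np.mod(np.pi - phase, TWO_PI)
        vol = WrappedVolume(wrapped)
        part = build_partition(vol, size_threshold=50)
        assert 3 <= part.n_blocks <= 5
        st = seed_state(part, vol)
        seed_id = int(part.labels[st.done & (part.labels > 0)][0])
        p = UnwrapParams(size_threshold=50)
        st, demoted, _ = merge_all_blocks(st, part, vol, p)
        assert not demoted.any()
        got = {b.id: int(np.unique(st.k[part.block_mask(b.id)])[0])
               for b in part.blocks}

        # interface statistics between 26-adjacent voxels of distinct
        # blocks: cost(k) = sum (dphi + 2*pi*(ki - kj))^2 decomposes into
        # n, sum(dphi), sum(dphi^2) per ordered block pair
        lab = part.labels
        stats = {}
        offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
        for p0 in map(tuple, np.argwhere(lab > 0)):
            i = int(lab[p0])
            for o in offs:
                p1 = tuple(np.add(p0, o))
                if not all(0 <= c < n for c, n in zip(p1, lab.shape)):
                    continue
                j = int(lab[p1])
                if j <= 0 or j == i:
                    continue
                d = wrapped[p0] - wrapped[p1]
                n_, s_, ss_ = stats.get((i, j), (0, 0.0, 0.0))
                stats[(i, j)] = (n_ + 1, s_ + d, ss_ + d * d)

        ids = sorted(b.id for b in part.blocks)
        free = [i for i in ids if i != seed_id]

        def cost(kmap):
            c = 0.0
            for (i, j), (n_, s_, ss_) in stats.items():
                step = TWO_PI * (kmap[i] - kmap[j])
                c += ss_ + 2 * step * s_ + n_ * step * step
            return c

        best, best_cost = None, np.inf
        for combo in itertools.product(range(-3, 4), repeat=len(free)):
            kmap = {seed_id: 0, **dict(zip(free, combo))}
            cc = cost(kmap)
            if cc < best_cost:
                best, best_cost = kmap, cc
        assert got == best


class TestResidualGrowing:
    def test_zero_residuals_noop(self, constant_volume):
        part = build_partition(constant_volume, size_threshold=100)
        # force everything into the single block for this check
        part.first_residual[:] = False
        part.labels[constant_volume.mask] = 1
        st = seed_state(part, constant_volume)
        st.done |= constant_volume.mask
        st.unwrapped[constant_volume.mask] = 0.1
        q = compute_quality_map(constant_volume)
        before = st.unwrapped.copy()
        st, n_unreached, order = unwrap_residuals(
            st, part, constant_volume, q, UnwrapParams())
        assert n_unreached == 0
        np.testing.assert_array_equal(st.unwrapped, before)
        assert (order == -1).all()

    def test_single_residual_voxel_offset_contract(self):
        # smooth quadratic done field with one hole; the grown value must be
        # within pi of the local fit, i.e. exactly on the true surface
        x, y, z = np.meshgrid(*[np.arange(13.0)] * 3, indexing="ij")
        truth = 4.0 + 0.1 * x + 0.04 * (y - 6) ** 2 - 0.05 * z
        wrapped = np.pi - np.mod(np.pi - truth, TWO_PI)
        vol = WrappedVolume(wrapped)
        labels = np.ones((13, 13, 13), np.int32)
        labels[6, 6, 6] = 0
        first = np.zeros((13, 13, 13), bool)
        first[6, 6, 6] = True
        part = _manual_partition(labels, first=first)
        st = UnwrapState.empty((13, 13, 13))
        st.done = labels > 0
        st.unwrapped[st.done] = truth[st.done]
        st.k[st.done] = np.round((truth - wrapped)[st.done] / TWO_PI)
        q = compute_quality_map(vol)
        st, n_unreached, _ = unwrap_residuals(st, part, vol, q, UnwrapParams())
        assert n_unreached == 0
        assert st.done[6, 6, 6]
        assert st.unwrapped[6, 6, 6] == pytest.approx(truth[6, 6, 6], abs=1e-9)

    def test_unreachable_island_reported(self):
        # residual voxels farther than one step from any done voxel and not
        # connected to the growing front stay not-done and are counted
        labels = np.zeros((20, 5, 5), np.int32)
        labels[0:5] = 1
        first = np.zeros((20, 5, 5), bool)
        first[15:17] = True   # island, 10 voxels away from the block
        mask = (labels > 0) | first
        vol = WrappedVolume(np.zeros((20, 5, 5)), mask=mask)
        part = _manual_partition(labels, first=first)
        st = seed_state(part, vol)
        q = compute_quality_map(vol)
        st, n_unreached, _ = unwrap_residuals(st, part, vol, q, UnwrapParams())
        assert n_unreached == first.sum()

    def test_growing_order_trace_deterministic(self, noisy_phantom):
        vol = WrappedVolume(noisy_phantom.wrapped_phase)
        runs = []
        for _ in range(2):
            part = build_partition(vol)
            st = seed_state(part, vol)
            p = UnwrapParams()
            st, demoted, _ = merge_all_blocks(st, part, vol, p)
            q = compute_quality_map(vol)
            st, _, order = unwrap_residuals(st, part, vol, q, p,
                                            demoted=demoted)
            runs.append((st.unwrapped.copy(), st.k.copy(), order.copy()))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])
        np.testing.assert_array_equal(runs[0][2], runs[1][2])


class TestUnwrapEndToEnd:
    def test_noiseless_phantom_mcr_zero(self, smooth_phantom):
        vol = WrappedVolume(smooth_phantom.wrapped_phase)
        state, report = unwrap(vol)
        rep = compute_mcr(state.unwrapped, smooth_phantom.reference_phase,
                          vol.mask, done=state.done)
        assert rep.mcr == 0.0
        assert report["n_unreached"] == 0

    def test_two_pi_consistency_everywhere(self, noisy_phantom):
        vol = WrappedVolume(noisy_phantom.wrapped_phase)
        state, _ = unwrap(vol)
        state.check_consistency(vol, atol=1e-9)

    def test_completeness_on_connected_roi(self, noisy_phantom):
        vol = WrappedVolume(noisy_phantom.wrapped_phase)
        state, _ = unwrap(vol)
        assert np.array_equal(state.done, vol.mask)

    def test_block_rigidity(self, noisy_phantom):
        vol = WrappedVolume(noisy_phantom.wrapped_phase)
        part = build_partition(vol)
        st = seed_state(part, vol)
        st, demoted, _ = merge_all_blocks(st, part, vol, UnwrapParams())
        for b in part.blocks:
            m = part.block_mask(b.id) & ~demoted
            if m.any():
                assert np.unique(st.k[m]).size == 1

    def test_wrap_free_input_identity(self):
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi / 3 + 1e-6, 0, (24, 24, 24))
        vol = WrappedVolume(phase)
        state, _ = unwrap(vol)
        offs = np.unique(state.k)
        assert offs.size == 1  # constant k: output = input up to a gauge
        np.testing.assert_allclose(state.unwrapped - TWO_PI * offs[0],
                                   phase, atol=1e-12)

    def test_gaussian_bump_property_suite(self):
        # random smooth bumps with gradient < pi: exact recovery each time
        rng = np.random.default_rng(99)
        for trial in range(3):
            peak = rng.uniform(5, 10)
            ds_shape = (28, 28, 28)
            from polyunwrap import simulate_gaussian_dataset
            ds = simulate_gaussian_dataset(
                shape=ds_shape, gaussian_sd=6.0, peak=peak, noise_sd=0.0,
                seed=trial)
            vol = WrappedVolume(ds.wrapped_phase)
            state, _ = unwrap(vol)
            rep = compute_mcr(state.unwrapped, ds.true_phase, vol.mask,
                              done=state.done)
            assert rep.mcr == 0.0, f"trial {trial} peak {peak}"
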