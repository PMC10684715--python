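"""Unwrapping engine: block merging and quality-guided residual growing.

The full procedure on a wrapped volume is

1. partition the ROI into blocks and residual voxels
   (:mod:`polyunwrap.partition`);
2. seed the unwrapped state from the largest block (its raw phase is
   wrap-free by construction, so its offset is the gauge origin ``k = 0``);
3. merge the remaining blocks nearest-first: fit the local polynomial to
   the done voxels closest to the growing block, predict the block's
   interface voxels, and apply the single modal integer offset to the whole
   block — block interiors are wrap-free, so one offset suffices;
4. unwrap residual voxels by quality-guided region growing (second
   residuals before first residuals), each voxel getting its own offset
   from a windowed local fit.

Everything is deterministic: ties are broken by block id or voxel index,
and there is no randomness anywhere in the engine.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import TWO_PI, WrappedVolume, UnwrapState
from .partition import RegionPartition, build_partition
from .polyfit import fit_local_polynomial

__all__ = [
    "UnwrapParams",
    "QualityMap",
    "DegenerateFitError",
    "compute_quality_map",
    "seed_state",
    "nearest_block",
    "select_fitting_voxels",
    "estimate_block_offset",
    "merge_all_blocks",
    "unwrap_residuals",
    "unwrap",
]

#: score assigned to masked voxels with no in-mask neighbor (worst possible;
#: the RMS of principal differences can never exceed pi)
WORST_QUALITY = 2.0 * np.pi


@dataclass
class UnwrapParams:
    """Tunable parameters of the unwrapping pipeline.

    Defaults follow the reference protocol: blocks need at least 100
    voxels, inter-block fits use the 100 nearest voxels on each side,
    residual fits use an 11-voxel cubic window, polynomial orders are
    (2, 2, 2) per axis, and connectivity is 26.

    The remaining knobs control robustness mechanisms.  ``window_cap``
    bounds the number of fitting voxels taken from a residual window (the
    nearest ones are kept); ``refine_band`` triggers a full-window refit
    when the offset fraction falls that close to the rounding boundary;
    ``block_offset_method``/``offset_search``/``joint_margin`` configure
    the inter-block offset search; ``merge_max_distance`` demotes blocks
    farther than that (in voxels) from the done set to residual growing;
    ``max_block_deferrals`` bounds retries of a block whose interface fit
    is degenerate; ``exclusion_criterion``/``exclusion_reach`` select the
    noisy-voxel exclusion reading (see
    :func:`polyunwrap.partition.exclude_noisy_voxels`).
    """

    size_threshold: int = 100
    fitting_count: int = 100
    window: int = 11
    orders: Tuple[int, int, int] = (2, 2, 2)
    connectivity: int = 26
    window_cap: int = 100
    max_block_deferrals: int = 2
    exclusion_criterion: str = "all"
    exclusion_reach: int = 3
    block_offset_method: str = "joint"
    offset_search: int = 3
    refine_band: float = 0.2
    joint_margin: float = 0.05
    merge_max_distance: float = 3.0
    front_band: float = 4.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.fitting_count < 1:
            raise ValueError("fitting_count must be >= 1")
        if self.size_threshold < 1:
            raise ValueError("size_threshold must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.window_cap < 1:
            raise ValueError("window_cap must be >= 1")
        if self.block_offset_method not in ("joint", "vote"):
            raise ValueError("block_offset_method must be 'joint' or 'vote'")


@dataclass
class QualityMap:
    """Per-voxel reliability score; lower = more reliable.

    Realized as the RMS of principal phase differences to in-mask
    26-neighbors (a phase-derivative magnitude): flat phase scores 0, noisy
    or rapidly varying phase scores high.
    """

    quality: np.ndarray


def compute_quality_map(vol: WrappedVolume) -> QualityMap:
    """Phase-derivative quality map over the ROI.

    For each masked voxel the score is the root-mean-square of the
    principal difference between its phase and each in-mask 26-neighbor's
    phase; out-of-mask neighbors are skipped, and a masked voxel with no
    in-mask neighbor receives the worst finite score.
    """
    phase = vol.phase
    mask = vol.mask
    ssq = np.zeros(phase.shape, dtype=np.float64)
    cnt = np.zeros(phase.shape, dtype=np.int32)
    shifts = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]
    for dx, dy, dz in shifts:
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, d in enumerate((dx, dy, dz)):
            n = phase.shape[ax]
            if d > 0:
                src[ax] = slice(d, None)
                dst[ax] = slice(None, n - d)
            elif d < 0:
                src[ax] = slice(None, n + d)
                dst[ax] = slice(-d, None)
        src, dst = tuple(src), tuple(dst)
        valid = mask[dst] & mask[src]
        d_phase = phase[src] - phase[dst]
        d_phase = np.pi - np.mod(np.pi - d_phase, TWO_PI)
        ssq[dst] += np.where(valid, d_phase ** 2, 0.0)
        cnt[dst] += valid
    quality = np.zeros(phase.shape, dtype=np.float64)
    has = cnt > 0
    quality[has] = np.sqrt(ssq[has] / cnt[has])
    quality[mask & ~has] = WORST_QUALITY
    quality[~mask] = WORST_QUALITY
    return QualityMap(quality=quality)


class DegenerateFitError(RuntimeError):
    """The inter-block interface fit produced a non-finite prediction."""


def seed_state(partition: RegionPartition, vol: WrappedVolume) -> UnwrapState:
    """Initialize the state from the largest block (ties: smallest id).

    The seed block's raw phase is wrap-free, so it is taken as the gauge
    origin with ``k = 0``.
    """
    if not partition.blocks:
        raise ValueError("cannot seed: partition has no blocks")
    best = max(partition.blocks, key=lambda b: (b.count, -b.id))
    state = UnwrapState.empty(vol.shape)
    m = partition.block_mask(best.id)
    state.done |= m
    state.unwrapped[m] = vol.phase[m]
    return state


def _block_distances(done: np.ndarray, partition: RegionPartition,
                     remaining) -> Dict[int, float]:
    """Min Euclidean distance from each remaining block to the done set."""
    edt = ndimage.distance_transform_edt(~done)
    ids = sorted(remaining)
    mins = ndimage.minimum(edt, labels=partition.labels, index=ids)
    return dict(zip(ids, np.atleast_1d(mins)))


def nearest_block(state: UnwrapState, partition: RegionPartition,
                  remaining=None) -> int:
    """Id of the undone block nearest (Euclidean) to the done set.

    Ties are broken toward the larger block, then the smaller id.
    """
    if remaining is None:
        remaining = [b.id for b in partition.blocks
                     if not state.done[partition.block_mask(b.id)].all()]
    if not remaining:
        raise ValueError("no remaining blocks")
    dists = _block_distances(state.done, partition, remaining)
    counts = {b.id: b.count for b in partition.blocks}
    return min(remaining, key=lambda i: (dists[i], -counts[i], i))


def select_fitting_voxels(state: UnwrapState, block_mask: np.ndarray,
                          fitting_count: int = 100):
    """Interface voxel sets for an inter-block fit.

    Returns ``(fit_coords, target_coords)``: the ``fitting_count`` done
    voxels nearest to the growing block, and the ``fitting_count`` block
    voxels nearest to the done set (fewer when a side is smaller).  Ties in
    distance are broken by voxel index, making the selection deterministic.
    """
    edt_to_block = ndimage.distance_transform_edt(~block_mask)
    fit_coords = _nearest_voxels(state.done, edt_to_block, fitting_count)
    edt_to_done = ndimage.distance_transform_edt(~state.done)
    target_coords = _nearest_voxels(block_mask, edt_to_done, fitting_count)
    return fit_coords, target_coords


def _nearest_voxels(from_mask: np.ndarray, dist: np.ndarray, count: int):
    idx = np.flatnonzero(from_mask.ravel())
    d = dist.ravel()[idx]
    order = np.lexsort((idx, d))[:count]
    sel = idx[order]
    return np.column_stack(np.unravel_index(sel, from_mask.shape))


def estimate_block_offset(state: UnwrapState, vol: WrappedVolume,
                          fit_coords: np.ndarray, target_coords: np.ndarray,
                          params: UnwrapParams) -> int:
    """Single integer 2*pi offset for a growing block.

    With the default ``method="joint"``, the offset is chosen so that one
    polynomial fitted *jointly* to the done-side unwrapped phases and the
    block-side phases shifted by ``2*pi*k`` has the smallest residual RMS:
    the correct offset places both interface patches on one smooth
    surface, while a wrong one introduces a 2*pi step no smooth polynomial
    can absorb.  Candidate offsets are searched around the rounded median
    of the one-sided per-voxel offsets.

    ``method="vote"`` instead fits only the done side, predicts each
    target voxel, and returns the modal rounded per-voxel offset (mean
    tie-break).  It is cheaper but fragile when the done-side voxels lie
    on a thin curved patch, where the polynomial is unconstrained along
    the patch normal and extrapolation can exceed pi.
    """
    phases_fit = state.unwrapped[tuple(fit_coords.T)]
    wrapped = vol.phase[tuple(target_coords.T)]

    if params.block_offset_method == "vote":
        fit = fit_local_polynomial(fit_coords, phases_fit, orders=params.orders)
        pred = fit.predict(target_coords)
        if not np.all(np.isfinite(pred)):
            raise DegenerateFitError("non-finite interface prediction")
        real_offsets = (pred - wrapped) / TWO_PI
        ks = np.round(real_offsets).astype(np.int64)
        vals, counts = np.unique(ks, return_counts=True)
        modes = vals[counts == counts.max()]
        if modes.size == 1:
            return int(modes[0])
        return int(np.round(real_offsets.mean()))

    # anchor the search at the nearest-neighbor interface difference: each
    # target is compared against the closest done-side voxel, a bounded,
    # extrapolation-free estimate of the local offset
    from scipy.spatial import cKDTree
    nn = cKDTree(fit_coords).query(target_coords, k=1)[1]
    k0 = int(np.round(np.median((phases_fit[nn] - wrapped) / TWO_PI)))
    pts = np.vstack([fit_coords, target_coords]).astype(float)
    rms = {}
    for k in range(k0 - params.offset_search, k0 + params.offset_search + 1):
        vals = np.concatenate([phases_fit, wrapped + TWO_PI * k])
        joint = fit_local_polynomial(pts, vals, orders=params.orders)
        if np.isfinite(joint.fit_rms):
            rms[k] = joint.fit_rms
    if not rms:
        raise DegenerateFitError("joint interface fit is degenerate")
    best_rms = min(rms.values())
    # hysteresis toward the anchor: a flexible polynomial can absorb much
    # of a 2*pi step across a wide interface gap (and a degenerate
    # two-plane interface absorbs any step exactly), so only leave the
    # nearest-neighbor estimate for a clearly smoother join
    cutoff = best_rms * (1.0 + params.joint_margin) + 1e-9
    close = [k for k, v in rms.items() if v <= cutoff]
    return min(close, key=lambda k: (abs(k - k0), k))


def merge_all_blocks(state: UnwrapState, partition: RegionPartition,
                     vol: WrappedVolume, params: UnwrapParams):
    """Merge every undone block into the state, nearest-first.

    Returns ``(state, demoted_mask, merge_order)`` where ``demoted_mask``
    marks voxels of blocks whose interface fit stayed degenerate after the
    allowed retries (they are handed to residual growing) and
    ``merge_order`` lists block ids in the order merged.
    """
    done_ids = set(np.unique(partition.labels[state.done]))
    remaining = [b.id for b in partition.blocks if b.id not in done_ids]
    counts = {b.id: b.count for b in partition.blocks}
    deferrals = {i: 0 for i in remaining}
    demoted = np.zeros(vol.shape, dtype=bool)
    merge_order = []
    while remaining:
        dists = _block_distances(state.done, partition, remaining)
        bid = min(remaining, key=lambda i: (dists[i], -counts[i], i))
        bmask = partition.block_mask(bid)
        if dists[bid] > params.merge_max_distance:
            # across a wide residual gap no local fit can discriminate the
            # integer offset reliably (the polynomial can absorb a full
            # turn); grow these voxels individually instead, where every
            # step has dense local context
            remaining.remove(bid)
            demoted |= bmask
            continue
        fit_coords, target_coords = select_fitting_voxels(
            state, bmask, params.fitting_count)
        try:
            k = estimate_block_offset(state, vol, fit_coords, target_coords, params)
        except DegenerateFitError:
            deferrals[bid] += 1
            if deferrals[bid] > params.max_block_deferrals:
                remaining.remove(bid)
                demoted |= bmask
            else:
                remaining.remove(bid)
                remaining.append(bid)  # retry later, after more context exists
            continue
        state.done |= bmask
        state.k[bmask] = k
        state.unwrapped[bmask] = vol.phase[bmask] + TWO_PI * k
        remaining.remove(bid)
        merge_order.append(bid)
    return state, demoted, merge_order


def unwrap_residuals(state: UnwrapState, partition: RegionPartition,
                     vol: WrappedVolume, quality: QualityMap,
                     params: UnwrapParams,
                     demoted: Optional[np.ndarray] = None):
    """Unwrap residual voxels by quality-guided growing.

    Pass 1 grows through the second residual voxels (members of
    sub-threshold regions, plus any demoted blocks), pass 2 through the
    first residual voxels (excised noisy connectors).  Because a voxel of
    one class can be walled in by the other, additional combined passes are
    run until no further voxel is reachable; truly unreachable voxels
    (isolated islands with no done voxel within reach) are reported and
    left not-done.  Returns ``(state, n_unreached, order)`` where ``order``
    holds each grown voxel's sequence number (-1 elsewhere) — a
    deterministic trace of the growing path.
    """
    from ._growing import grow_pass

    second = partition.second_residual.copy()
    if demoted is not None:
        second |= demoted
    first = partition.first_residual
    wrapped = np.ascontiguousarray(vol.phase)
    q = np.ascontiguousarray(quality.quality)
    L, M, N = params.orders
    order_out = np.full(vol.shape, -1, dtype=np.int64)
    n_grown = 0

    def run(candidates: np.ndarray) -> int:
        nonlocal n_grown
        cand = np.ascontiguousarray(candidates & vol.mask & ~state.done)
        if not cand.any():
            return 0
        if params.front_band > 0:
            # coarse concentric layers around the current done set; they
            # dominate the quality key (quality < 2*pi < 16) so fronts
            # from all anchors advance together
            edt = ndimage.distance_transform_edt(~state.done)
            band = 16.0 * np.floor(edt / params.front_band)
        else:
            band = np.zeros(vol.shape)
        band = np.ascontiguousarray(band, dtype=np.float64)
        n = int(grow_pass(wrapped, state.unwrapped, state.k, state.done,
                          cand, q, band, params.window, L, M, N,
                          params.window_cap, params.refine_band,
                          order_out, n_grown))
        n_grown += n
        return n

    run(second)
    run(first)
    # mop-up: alternate over the union until nothing moves
    while True:
        moved = run(second | first)
        if moved == 0:
            break
    n_unreached = int(((second | first) & ~state.done & vol.mask).sum())
    return state, n_unreached, order_out


def unwrap(vol: WrappedVolume, params: Optional[UnwrapParams] = None,
           partition: Optional[RegionPartition] = None):
    """Unwrap a wrapped volume end to end.

    Returns ``(state, report)``; the report is a JSON-serializable dict
    with block/residual counts, unreached-voxel count and per-stage
    timings.  The result is defined up to one global multiple of 2*pi.
    """
    if params is None:
        params = UnwrapParams()
    report: Dict = {"params": {
        "size_threshold": params.size_threshold,
        "fitting_count": params.fitting_count,
        "window": params.window,
        "orders": list(params.orders),
        "connectivity": params.connectivity,
        "window_cap": params.window_cap,
    }}
    t0 = time.perf_counter()
    if partition is None:
        partition = build_partition(
            vol, size_threshold=params.size_threshold,
            connectivity=params.connectivity, reach=params.exclusion_reach,
            criterion=params.exclusion_criterion)
    t1 = time.perf_counter()
    state = seed_state(partition, vol)
    state, demoted, merge_order = merge_all_blocks(state, partition, vol, params)
    t2 = time.perf_counter()
    quality = compute_quality_map(vol)
    state, n_unreached, _ = unwrap_residuals(state, partition, vol, quality,
                                             params, demoted=demoted)
    t3 = time.perf_counter()
    state.check_consistency(vol)
    report.update({
        "n_blocks": partition.n_blocks,
        "n_demoted_blocks_voxels": int(demoted.sum()),
        "n_first_residual": int(partition.first_residual.sum()),
        "n_second_residual": int(partition.second_residual.sum()),
        "n_unreached": n_unreached,
        "merge_order": merge_order,
        "timings_s": {
            "partition": round(t1 - t0, 3),
            "block_merge": round(t2 - t1, 3),
            "residual_growing": round(t3 - t2, 3),
        },
    })
    if n_unreached:
        report["warnings"] = [
            f"{n_unreached} residual voxels unreachable from any done voxel"
        ]
    return state, report
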