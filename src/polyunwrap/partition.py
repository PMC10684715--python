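"""Region partitioning: subinterval split, noisy-voxel exclusion, classification.

The wrapped-phase interval ``(-pi, pi]`` is divided into six equal
subintervals.  Voxels of one subinterval cannot hide a wrap (their raw
phases span less than 2*pi/3), so each connected component of a subinterval
mask is a candidate wrap-free region.  Components can however be *falsely*
connected through thin strands of noisy voxels while the areas they join
differ by a full turn — a hidden wrap.  Such connector voxels sit on the
region edge and have out-of-region neighbors within distance three on at
least two coordinate axes; they are excised before components are
re-identified.  Components are then classified by size: large ones become
rigid *blocks*, small ones contribute *second residual* voxels, and the
excised connectors are the *first residual* voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .core import WrappedVolume

__all__ = [
    "NoBlocksError",
    "Block",
    "RegionPartition",
    "partition_phase",
    "label_components",
    "exclude_noisy_voxels",
    "classify_regions",
    "build_partition",
]

N_SUBINTERVALS = 6
# upper edges of the five interior bin boundaries; bins are (a, b]
_BIN_EDGES = np.array([-2 * np.pi / 3, -np.pi / 3, 0.0, np.pi / 3, 2 * np.pi / 3])


class NoBlocksError(RuntimeError):
    """No region reached the block size threshold; merging cannot start."""


def connectivity_structure(connectivity: int) -> np.ndarray:
    """Binary 3x3x3 structuring element for 6-, 18- or 26-connectivity."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def partition_phase(vol: WrappedVolume) -> List[np.ndarray]:
    """Split the ROI into six boolean masks by phase subinterval.

    Bin ``b`` (1-based) holds voxels with phase in
    ``(-pi + (b-1)*pi/3, -pi + b*pi/3]`` — half-open bins closed at the
    upper end, so every boundary value belongs to exactly one bin.  The six
    masks are pairwise disjoint and their union equals the ROI mask.
    """
    if not np.any(vol.mask):
        raise ValueError("empty ROI mask")
    idx = np.digitize(vol.phase, _BIN_EDGES, right=True)
    return [(idx == b) & vol.mask for b in range(N_SUBINTERVALS)]


def subinterval_index(phase) -> np.ndarray:
    """1-based subinterval index of each phase value (same binning as above)."""
    return np.digitize(np.asarray(phase), _BIN_EDGES, right=True) + 1


def label_components(region_mask: np.ndarray, connectivity: int = 26):
    """Label connected components of a boolean mask.

    Returns ``(labels, n)`` with background 0 and components ``1..n`` under
    the requested voxel connectivity.
    """
    labels, n = ndimage.label(region_mask, structure=connectivity_structure(connectivity))
    return labels.astype(np.int32), int(n)


def _shifted_outside(outside: np.ndarray, axis: int, d: int) -> np.ndarray:
    """True where the neighbor at offset ``d`` along ``axis`` is outside the
    region; positions whose neighbor falls beyond the volume border count as
    outside."""
    out = np.ones_like(outside)
    n = outside.shape[axis]
    if abs(d) >= n:
        return out
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if d > 0:
        src[axis] = slice(d, None)
        dst[axis] = slice(None, n - d)
    else:
        src[axis] = slice(None, n + d)
        dst[axis] = slice(-d, None)
    out[tuple(dst)] = outside[tuple(src)]
    return out


def exclude_noisy_voxels(region_mask: np.ndarray, *, reach: int = 3,
                         criterion: str = "all", iterate: bool = False):
    """Excise noisy connector voxels from one subinterval's region mask.

    A voxel is excluded iff it

    (i)  lies on the region edge — at least one of its six face neighbors is
         outside ``region_mask`` — and
    (ii) has zero-valued (out-of-region) first, second and third neighbors
         along at least two of the three coordinate axes.

    ``criterion="all"`` (default) requires a full run of ``reach``
    consecutive out-of-region voxels on one side of an axis — the reading
    that excises thin connector strands while leaving voxels next to
    isolated speckle holes alone.  ``criterion="any"`` counts an axis as
    soon as *some* offset in ``±1..±reach`` leaves the region; under
    complex noise this excludes the bulk of the ROI (every speckle hole
    condemns its whole neighborhood) and is kept only for comparison.
    Neighbors beyond the volume border count as outside.  With
    ``iterate=True`` the exclusion is repeated until no voxel changes
    (default is the single pass used in the standard pipeline).

    Returns ``(cleaned_mask, excluded_mask)``.
    """
    if criterion not in ("any", "all"):
        raise ValueError("criterion must be 'any' or 'all'")
    region = np.asarray(region_mask, dtype=bool)
    excluded_total = np.zeros_like(region)
    while True:
        outside = ~region
        edge = np.zeros_like(region)
        for axis in range(3):
            for d in (-1, 1):
                edge |= _shifted_outside(outside, axis, d)
        edge &= region

        axis_hits = np.zeros(region.shape, dtype=np.int8)
        for axis in range(3):
            if criterion == "any":
                hit = np.zeros_like(region)
                for d in range(1, reach + 1):
                    hit |= _shifted_outside(outside, axis, d)
                    hit |= _shifted_outside(outside, axis, -d)
            else:
                pos = np.ones_like(region)
                neg = np.ones_like(region)
                for d in range(1, reach + 1):
                    pos &= _shifted_outside(outside, axis, d)
                    neg &= _shifted_outside(outside, axis, -d)
                hit = pos | neg
            axis_hits += hit.astype(np.int8)

        excluded = edge & (axis_hits >= 2)
        excluded_total |= excluded
        region = region & ~excluded
        if not iterate or not np.any(excluded):
            break
    return region, excluded_total


@dataclass
class Block:
    """One wrap-free region unwrapped rigidly by a single 2*pi offset."""

    id: int
    subinterval: int
    count: int


@dataclass
class RegionPartition:
    """Partition of the ROI into blocks and residual voxels.

    ``labels`` is 0 outside the ROI and on residual voxels, ``1..R`` on
    blocks.  ``first_residual`` marks excised noisy connectors,
    ``second_residual`` members of sub-threshold regions.  The three
    categories are pairwise disjoint and together cover the ROI exactly.
    """

    labels: np.ndarray
    blocks: List[Block]
    first_residual: np.ndarray
    second_residual: np.ndarray
    size_threshold: int = 100

    def block_mask(self, block_id: int) -> np.ndarray:
        return self.labels == block_id

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def check_partition(self, mask: np.ndarray) -> None:
        """Assert blocks + residuals tile the ROI exactly (raises on failure)."""
        in_block = self.labels > 0
        cats = in_block.astype(int) + self.first_residual + self.second_residual
        if not np.array_equal(cats > 0, np.asarray(mask, bool)):
            raise AssertionError("partition does not cover the ROI exactly")
        if cats.max(initial=0) > 1:
            raise AssertionError("partition categories overlap")

    def export_labels(self) -> np.ndarray:
        """Debug export: 0 background, 1..R blocks, -1 first, -2 second residual."""
        out = self.labels.astype(np.int32).copy()
        out[self.first_residual] = -1
        out[self.second_residual] = -2
        return out


def classify_regions(bin_labels, bin_counts, excluded, mask,
                     size_threshold: int = 100) -> RegionPartition:
    """Classify relabeled regions into blocks and second residual voxels.

    Parameters
    ----------
    bin_labels, bin_counts
        Per-subinterval component label volumes (after exclusion) and their
        component sizes, as produced by :func:`build_partition`.
    excluded
        Boolean volume of first-residual (excised) voxels.
    mask
        ROI mask.
    size_threshold
        Components with *fewer* voxels than this become second residual
        voxels; components at or above it become blocks.
    """
    if size_threshold < 1:
        raise ValueError("size_threshold must be >= 1")
    labels = np.zeros(mask.shape, dtype=np.int32)
    second = np.zeros(mask.shape, dtype=bool)
    blocks: List[Block] = []
    next_id = 1
    for b, (lab, counts) in enumerate(zip(bin_labels, bin_counts), start=1):
        if counts.size == 0:
            continue
        big_ids = np.flatnonzero(counts >= size_threshold) + 1  # component ids
        remap = np.zeros(counts.size + 1, dtype=np.int32)  # old label -> block id
        for cid in big_ids:
            remap[cid] = next_id
            blocks.append(Block(id=next_id, subinterval=b, count=int(counts[cid - 1])))
            next_id += 1
        new = remap[lab]
        labels += new
        second |= (lab > 0) & (new == 0)
    if not blocks:
        raise NoBlocksError(
            f"no region reached {size_threshold} voxels; lower size_threshold"
        )
    part = RegionPartition(labels=labels, blocks=blocks,
                           first_residual=np.asarray(excluded, bool),
                           second_residual=second, size_threshold=size_threshold)
    return part


def build_partition(vol: WrappedVolume, *, size_threshold: int = 100,
                    connectivity: int = 26, reach: int = 3,
                    criterion: str = "all", iterate: bool = False) -> RegionPartition:
    """Full partitioning pipeline for one wrapped volume.

    Composes subinterval split → per-subinterval component labeling →
    noisy-voxel exclusion → component re-identification → size
    classification, and returns a :class:`RegionPartition` whose categories
    tile the ROI.
    """
    masks = partition_phase(vol)
    bin_labels = []
    bin_counts = []
    excluded_total = np.zeros(vol.shape, dtype=bool)
    for m in masks:
        cleaned, excluded = exclude_noisy_voxels(m, reach=reach,
                                                 criterion=criterion, iterate=iterate)
        excluded_total |= excluded
        lab, n = label_components(cleaned, connectivity)
        counts = np.bincount(lab.ravel(), minlength=n + 1)[1:] if n else np.zeros(0, int)
        bin_labels.append(lab)
        bin_counts.append(counts)
    return classify_regions(bin_labels, bin_counts, excluded_total, vol.mask,
                            size_threshold=size_threshold)
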