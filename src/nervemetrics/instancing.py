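"""Instance segmentation of myelinated fibers from semantic maps.

Axon instances are trivial (connected components), but the myelin of
adjacent fibers is contiguous and must be split.  The split is done by
flooding a height map in which axon pixels sit at height 0, background at
height 1, and each myelin pixel is interpolated between its Euclidean
distance to the nearest axon pixel and to the nearest background pixel:

    height = d_axon / (d_axon + d_background)

A seeded watershed on this height map, restricted to tissue pixels and
seeded with the axon labels, assigns every myelin pixel to exactly one
axon.

Before instancing, the semantic map is cleaned: labels in excluded
regions, axons smaller than ``min_axon_px`` pixels, fibers whose axon
touches background (degenerated/hypomyelinated morphology is out of
scope), and orphan myelin are all removed, in that order.

Connectivity conventions: 8-connectivity for labeling axon/myelin
components; 4-adjacency for the axon-touches-background and
myelin-touches-axon tests.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from nervemetrics.types import (
    AXON,
    BACKGROUND,
    MYELIN,
    FascicleMask,
    FiberInstanceMap,
    HeightMap,
    SemanticMap,
)

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = ndimage.generate_binary_structure(2, 1)

DEFAULT_MIN_AXON_PX = 4


def _delete_components(labels: np.ndarray, doomed_ids: np.ndarray, classes: np.ndarray) -> None:
    if doomed_ids.size:
        classes[np.isin(labels, doomed_ids) & (labels > 0)] = BACKGROUND


def clean_semantic(
    semantic: SemanticMap, mask: FascicleMask, min_axon_px: int = DEFAULT_MIN_AXON_PX
) -> SemanticMap:
    """Apply the label-cleanup rules, returning a new SemanticMap.

    In order: (a) tissue outside the include mask is cleared — myelin
    pixel-wise, axons as whole components if any pixel falls outside;
    (b) axon components of area < ``min_axon_px`` are deleted; (c) axon
    components with any pixel 4-adjacent to background are deleted;
    (d) myelin components not 4-adjacent to any surviving axon are
    deleted.  Deleted pixels become background.  The operation is
    idempotent.
    """
    if semantic.shape != mask.shape:
        raise ValueError("semantic map and fascicle mask shapes differ")
    classes = semantic.classes.copy()
    include = mask.include

    # (a) exclusion regions
    classes[(classes == MYELIN) & ~include] = BACKGROUND
    axon_lab, _ = ndimage.label(classes == AXON, structure=_EIGHT)
    outside = np.unique(axon_lab[(axon_lab > 0) & ~include])
    _delete_components(axon_lab, outside, classes)

    # (b) minimum axon size
    axon_lab, n = ndimage.label(classes == AXON, structure=_EIGHT)
    if n:
        sizes = np.bincount(axon_lab.ravel())
        small = np.flatnonzero(sizes < min_axon_px)
        small = small[small > 0]
        _delete_components(axon_lab, small, classes)

    # (c) axon 4-adjacent to background
    axon_lab, n = ndimage.label(classes == AXON, structure=_EIGHT)
    if n:
        bg_halo = ndimage.binary_dilation(classes == BACKGROUND, structure=_FOUR)
        exposed = np.unique(axon_lab[(axon_lab > 0) & bg_halo])
        _delete_components(axon_lab, exposed, classes)

    # (d) orphan myelin
    my_lab, n = ndimage.label(classes == MYELIN, structure=_EIGHT)
    if n:
        axon_halo = ndimage.binary_dilation(classes == AXON, structure=_FOUR)
        attached = np.unique(my_lab[(my_lab > 0) & axon_halo])
        all_ids = np.arange(1, n + 1)
        orphans = np.setdiff1d(all_ids, attached, assume_unique=True)
        _delete_components(my_lab, orphans, classes)

    return SemanticMap(classes, semantic.resolution)


def build_height_map(semantic: SemanticMap) -> HeightMap:
    """Interpolated height map for watershed flooding.

    Heights: 0 on axon, 1 on background, and for myelin the ratio of the
    exact Euclidean distance to the nearest axon pixel over the sum of the
    distances to nearest axon and nearest background pixel.  If the map
    has no background pixels the background distance is +inf and myelin
    heights take the limiting value 0.
    """
    classes = semantic.classes
    axon = classes == AXON
    if not axon.any():
        raise ValueError("no axon pixels: cannot build a seeded height map")
    background = classes == BACKGROUND
    d_axon = ndimage.distance_transform_edt(~axon)
    height = np.ones(classes.shape, dtype=np.float64)
    height[axon] = 0.0
    myelin = classes == MYELIN
    if background.any():
        d_bg = ndimage.distance_transform_edt(~background)
        denom = d_axon[myelin] + d_bg[myelin]
        height[myelin] = d_axon[myelin] / denom
    else:
        height[myelin] = 0.0
    return HeightMap(height)


def label_axons(semantic: SemanticMap) -> np.ndarray:
    """8-connected axon component labels (int32, 0 = none)."""
    lab, _ = ndimage.label(semantic.classes == AXON, structure=_EIGHT)
    return lab.astype(np.int32)


def separate_myelin(height: HeightMap, semantic: SemanticMap) -> FiberInstanceMap:
    """Split contiguous myelin between fibers by seeded watershed.

    Flooding is restricted to tissue (axon ∪ myelin) pixels, seeded by the
    8-connected axon labels, ascending by height; ties resolve by
    insertion order in the priority queue, so the output is reproducible
    bit-for-bit.  Myelin pixels unreachable from any seed (possible only
    on maps that skipped cleanup) are left unlabeled with a warning.
    """
    classes = semantic.classes
    axon_labels = label_axons(semantic)
    tissue = classes != BACKGROUND
    filled = watershed(height.height, markers=axon_labels, mask=tissue, connectivity=1)
    myelin_labels = np.where(classes == MYELIN, filled, 0).astype(np.int32)

    warnings: list[str] = []
    unassigned = int(((classes == MYELIN) & (myelin_labels == 0)).sum())
    if unassigned:
        warnings.append(f"{unassigned} myelin px unreachable from any axon seed; left unlabeled")
    return FiberInstanceMap(axon_labels, myelin_labels, semantic.resolution, warnings=warnings)


def run_instancing(
    semantic: SemanticMap, mask: FascicleMask, min_axon_px: int = DEFAULT_MIN_AXON_PX
) -> tuple[SemanticMap, FiberInstanceMap]:
    """Cleanup → height map → watershed, returning (cleaned map, instances)."""
    cleaned = clean_semantic(semantic, mask, min_axon_px=min_axon_px)
    if not (cleaned.classes == AXON).any():
        return cleaned, FiberInstanceMap(
            np.zeros(cleaned.shape, np.int32),
            np.zeros(cleaned.shape, np.int32),
            cleaned.resolution,
            warnings=["no axons survive cleanup"],
        )
    height = build_height_map(cleaned)
    return cleaned, separate_myelin(height, cleaned)
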