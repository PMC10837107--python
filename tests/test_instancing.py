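"""Cleanup rules, height map vs brute-force distances, watershed vs a
Dijkstra minimax-path oracle, and pixel-conservation invariants."""

import heapq

import numpy as np
import pytest

from nervemetrics.instancing import (
    build_height_map,
    clean_semantic,
    label_axons,
    run_instancing,
    separate_myelin,
)
from nervemetrics.types import AXON, BACKGROUND, MYELIN, FascicleMask, SemanticMap
from tests.conftest import draw_annulus, single_fiber_map


def _map_from_codes(codes: np.ndarray, resolution=0.125):
    semantic = SemanticMap(np.asarray(codes, dtype=np.uint8), resolution)
    mask = FascicleMask(np.ones(semantic.shape, dtype=bool))
    return semantic, mask


# ---------------------------------------------------------------- cleanup


def test_small_axon_removed_with_its_myelin():
    """An axon of 3 px (under the 4-px filter) disappears with its myelin."""
    codes = np.zeros((20, 20), dtype=np.uint8)
    codes[5, 5:8] = AXON  # 3 px
    codes[4, 4:9] = MYELIN
    codes[6, 4:9] = MYELIN
    codes[5, 4] = MYELIN
    codes[5, 8] = MYELIN
    semantic, mask = _map_from_codes(codes)
    out = clean_semantic(semantic, mask)
    assert (out.classes == BACKGROUND).all()


def test_clean_is_identity_on_well_formed_map():
    semantic, mask = single_fiber_map()
    out = clean_semantic(semantic, mask)
    assert np.array_equal(out.classes, semantic.classes)


def test_axon_exposed_to_background_removed():
    """A 1-px myelin gap exposing the axon deletes the whole fiber;
    cross-checked against a brute-force 4-adjacency scan."""
    codes = np.zeros((20, 20), dtype=np.uint8)
    draw_annulus(codes, (10, 10), 4.0, 7.0)
    # carve a 1-px radial channel through the myelin above the axon
    channel = (codes[:, 10] == MYELIN) & (np.arange(20) < 10)
    codes[channel, 10] = BACKGROUND

    exposed = False  # brute-force oracle
    for r in range(20):
        for c in range(20):
            if codes[r, c] != AXON:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rn, cn = r + dr, c + dc
                if 0 <= rn < 20 and 0 <= cn < 20 and codes[rn, cn] == BACKGROUND:
                    exposed = True
    assert exposed

    semantic, mask = _map_from_codes(codes)
    out = clean_semantic(semantic, mask)
    assert (out.classes == BACKGROUND).all()


def test_fiber_outside_include_mask_removed():
    semantic, _ = single_fiber_map(shape=(64, 64))
    include = np.ones((64, 64), dtype=bool)
    include[:, 32:] = False  # mask boundary bisects the fiber
    out = clean_semantic(semantic, FascicleMask(include))
    assert (out.classes == BACKGROUND).all()


def test_orphan_myelin_removed():
    codes = np.zeros((30, 30), dtype=np.uint8)
    draw_annulus(codes, (10, 10), 4.0, 7.0)
    codes[22:26, 22:26] = MYELIN  # myelin blob with no axon
    semantic, mask = _map_from_codes(codes)
    out = clean_semantic(semantic, mask)
    assert (out.classes[20:, 20:] == BACKGROUND).all()
    assert (out.classes == AXON).sum() == (codes == AXON).sum()


def test_clean_idempotent(small_phantom):
    semantic, mask, _, _ = small_phantom
    once = clean_semantic(semantic, mask)
    twice = clean_semantic(once, mask)
    assert np.array_equal(once.classes, twice.classes)


def test_shape_mismatch_rejected():
    semantic, _ = single_fiber_map()
    with pytest.raises(ValueError):
        clean_semantic(semantic, FascicleMask(np.ones((10, 10), dtype=bool)))


# ---------------------------------------------------------------- height map


def test_height_values_at_known_distances():
    """Equidistant myelin pixel -> 0.5; d_a=1, d_b=3 -> 0.25."""
    codes = np.zeros((5, 8), dtype=np.uint8)
    codes[:, 0:2] = AXON
    codes[:, 2:5] = MYELIN  # cols 2..4; background from col 5
    h = build_height_map(SemanticMap(codes)).height
    assert h[2, 2] == pytest.approx(1 / 4)  # d_a = 1, d_b = 3
    assert h[2, 3] == pytest.approx(0.5)  # equidistant, d_a = d_b = 2
    assert h[2, 4] == pytest.approx(3 / 4)  # d_a = 3, d_b = 1


def test_height_map_matches_all_pairs_oracle():
    """Full 15x15 raster equals brute-force nearest-neighbour distances."""
    rng = np.random.default_rng(0)
    codes = np.zeros((15, 15), dtype=np.uint8)
    draw_annulus(codes, (7, 7), 3.0, 6.0)
    # roughen the annulus so distances are nontrivial
    flip = rng.random(codes.shape) < 0.05
    codes[flip & (codes == MYELIN)] = BACKGROUND
    semantic = SemanticMap(codes)
    if not (codes == AXON).any():
        pytest.skip("degenerate draw")
    h = build_height_map(semantic).height

    ax = np.argwhere(codes == AXON)
    bg = np.argwhere(codes == BACKGROUND)
    for r in range(15):
        for c in range(15):
            if codes[r, c] == AXON:
                assert h[r, c] == 0.0
            elif codes[r, c] == BACKGROUND:
                assert h[r, c] == 1.0
            else:
                da = np.sqrt(((ax - (r, c)) ** 2).sum(axis=1).min())
                db = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1).min())
                assert h[r, c] == pytest.approx(da / (da + db), abs=1e-12)


def test_height_bounds_and_error_cases():
    codes = np.zeros((8, 8), dtype=np.uint8)
    with pytest.raises(ValueError):
        build_height_map(SemanticMap(codes))  # no axon seeds
    codes[:, :4] = AXON
    codes[:, 4:] = MYELIN  # no background at all
    h = build_height_map(SemanticMap(codes)).height
    assert (h[:, 4:] == 0.0).all()  # limiting value when d_bg = +inf


# ---------------------------------------------------------------- watershed


def _minimax_oracle(height: np.ndarray, seeds: np.ndarray, tissue: np.ndarray):
    """Multi-source Dijkstra on the 4-connected pixel graph with path cost
    max(height along path); returns (best cost per seed label, labels)."""
    labels = np.unique(seeds)
    labels = labels[labels > 0]
    costs = {lab: np.full(height.shape, np.inf) for lab in labels}
    for lab in labels:
        cost = costs[lab]
        heap = []
        for r, c in np.argwhere(seeds == lab):
            cost[r, c] = height[r, c]
            heapq.heappush(heap, (height[r, c], r, c))
        while heap:
            d, r, c = heapq.heappop(heap)
            if d > cost[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rn, cn = r + dr, c + dc
                if 0 <= rn < height.shape[0] and 0 <= cn < height.shape[1] and tissue[rn, cn]:
                    nd = max(d, height[rn, cn])
                    if nd < cost[rn, cn]:
                        cost[rn, cn] = nd
                        heapq.heappush(heap, (nd, rn, cn))
    return costs


def test_single_fiber_myelin_takes_lone_axon_id():
    semantic, mask = single_fiber_map()
    cleaned = clean_semantic(semantic, mask)
    inst = separate_myelin(build_height_map(cleaned), cleaned)
    assert len(inst.fiber_ids) == 1
    fid = inst.fiber_ids[0]
    assert np.array_equal(inst.myelin_labels > 0, cleaned.classes == MYELIN)
    assert set(np.unique(inst.myelin_labels)) == {0, fid}


def test_symmetric_pair_splits_evenly():
    """Two identical axons sharing contiguous myelin split at the ridge."""
    codes = np.zeros((40, 64), dtype=np.uint8)
    draw_annulus(codes, (20, 22), 6.0, 11.0)
    draw_annulus(codes, (20, 42), 6.0, 11.0)
    semantic, mask = _map_from_codes(codes)
    cleaned = clean_semantic(semantic, mask)
    inst = separate_myelin(build_height_map(cleaned), cleaned)
    assert len(inst.fiber_ids) == 2
    counts = np.bincount(inst.myelin_labels.ravel())[1:]
    # equal halves within one ridge row of pixels
    ridge_allowance = codes.shape[0]
    assert abs(int(counts[0]) - int(counts[1])) <= ridge_allowance


def test_watershed_matches_dijkstra_minimax_oracle():
    """Asymmetric touching pair: wherever the minimax cost strictly
    separates the two seeds, the watershed assignment agrees."""
    codes = np.zeros((128, 128), dtype=np.uint8)
    draw_annulus(codes, (64, 40), 8.0, 14.0)
    draw_annulus(codes, (64, 70), 16.0, 26.0)  # r_a 16 px, touching myelin
    semantic, mask = _map_from_codes(codes)
    cleaned = clean_semantic(semantic, mask)
    height = build_height_map(cleaned)
    inst = separate_myelin(height, cleaned)
    assert len(inst.fiber_ids) == 2

    seeds = label_axons(cleaned)
    tissue = cleaned.classes != BACKGROUND
    costs = _minimax_oracle(height.height, seeds, tissue)
    labs = sorted(costs)
    c1, c2 = costs[labs[0]], costs[labs[1]]
    myelin = cleaned.classes == MYELIN
    strict1 = myelin & (c1 < c2 - 1e-12)
    strict2 = myelin & (c2 < c1 - 1e-12)
    assert strict1.sum() > 0 and strict2.sum() > 0
    assert (inst.myelin_labels[strict1] == labs[0]).all()
    assert (inst.myelin_labels[strict2] == labs[1]).all()
    assert (inst.myelin_labels[myelin] > 0).all()  # every myelin pixel assigned


# ---------------------------------------------------------------- invariants


def test_pixel_conservation_and_attachment(small_phantom):
    semantic, mask, truth, instances = small_phantom
    cleaned = clean_semantic(semantic, mask)
    assert (cleaned.classes == MYELIN).sum() == (instances.myelin_labels > 0).sum()
    # every fiber's myelin 4-touches its own axon
    from scipy import ndimage

    four = ndimage.generate_binary_structure(2, 1)
    for fid in instances.fiber_ids:
        my = instances.myelin_labels == fid
        ax = instances.axon_labels == fid
        assert (ndimage.binary_dilation(ax, four) & my).any()
        # axon ∪ myelin is one connected component
        lab, n = ndimage.label(my | ax, structure=np.ones((3, 3), bool))
        assert n == 1


def test_phantom_fiber_count_recovered(recovery_phantom):
    semantic, mask, truth = recovery_phantom
    _, instances = run_instancing(semantic, mask)
    assert len(instances.fiber_ids) == len(truth.fibers)
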