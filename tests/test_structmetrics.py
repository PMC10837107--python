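"""Window metrics: fractional counting, quadrat rule, fascicle-area
denominator, conservation, and the exact pixel-wise engine."""

import numpy as np
import pytest

from nervemetrics.structmetrics import (
    WindowSpec,
    cellwise_metrics,
    make_context,
    partition_anchors,
    pixelwise_metrics,
    quadrat_metrics,
    window_bounds,
    window_metrics,
)
from nervemetrics.types import FascicleMask, FiberInstanceMap


def _toy_instances(shape=(64, 64), resolution=0.125):
    """Hand-placed rectangular 'fibers' with exactly known pixel counts."""
    axon = np.zeros(shape, dtype=np.int32)
    myelin = np.zeros(shape, dtype=np.int32)
    # fiber 1: 4x4 axon ringed by myelin -> fully inside window later
    axon[10:14, 10:14] = 1
    myelin[8:16, 8:16] = 1
    myelin[10:14, 10:14] = 0
    # fiber 2: same geometry elsewhere
    axon[10:14, 30:34] = 2
    myelin[8:16, 28:36] = 2
    myelin[10:14, 30:34] = 0
    # fiber 3: straddles the window edge
    axon[40:44, 20:24] = 3
    myelin[38:46, 18:26] = 3
    myelin[40:44, 20:24] = 0
    return FiberInstanceMap(axon, myelin, resolution)


def test_window_bounds_conventions():
    # odd side: symmetric
    assert window_bounds((10, 10), 5, (64, 64)) == (8, 13, 8, 13)
    # even side: anchor at top-left of the central 2x2 block
    assert window_bounds((10, 10), 4, (64, 64)) == (9, 13, 9, 13)
    # clipping at borders
    assert window_bounds((0, 0), 5, (64, 64)) == (0, 3, 0, 3)


def test_fractional_density_known_case():
    """2 whole fibers + exactly half a third over 0.04 mm² -> 62.5 /mm²."""
    inst = _toy_instances()
    # mask such that fascicle area inside the window is exactly 0.04 mm²:
    # 0.04 mm² = 4e4 µm² -> at 1 µm/px that is 200x200 px; use resolution 1.0
    inst = FiberInstanceMap(inst.axon_labels, inst.myelin_labels, 1.0)
    shape = (256, 256)
    axon = np.zeros(shape, dtype=np.int32)
    myelin = np.zeros(shape, dtype=np.int32)
    axon[:64, :64] = inst.axon_labels
    myelin[:64, :64] = inst.myelin_labels
    # shift fiber 3 so exactly half its 48 px fall inside rows < 200
    axon[:, :] = 0
    myelin[:, :] = 0
    axon[10:14, 10:14] = 1
    myelin[8:16, 8:16] = 1
    myelin[10:14, 10:14] = 0
    axon[30:34, 30:34] = 2
    myelin[28:36, 28:36] = 2
    myelin[30:34, 30:34] = 0
    # fiber 3: an 8x8 block half inside the window column range [0, 200)
    myelin[100:108, 196:204] = 3
    axon[102:106, 198:202] = 3  # embedded; fiber pixels = the 8x8 block
    inst = FiberInstanceMap(axon, myelin, 1.0)
    mask = FascicleMask(np.ones(shape, dtype=bool))
    win = WindowSpec(200.0)
    anchor = (99, 99)  # window [0,200) x [0,200)
    assert window_bounds(anchor, 200, shape) == (0, 200, 0, 200)
    rec = window_metrics(inst, mask, win, anchor)
    assert rec.fiber_count == pytest.approx(2.5, abs=1e-12)
    assert rec.fascicle_area_um2 == pytest.approx(4e4)
    assert rec.fiber_density_per_mm2 == pytest.approx(62.5, rel=1e-12)


def test_empty_fascicle_region_and_zero_mask():
    shape = (64, 64)
    inst = FiberInstanceMap(np.zeros(shape, np.int32), np.zeros(shape, np.int32), 1.0)
    mask = FascicleMask(np.ones(shape, dtype=bool))
    rec = window_metrics(inst, mask, WindowSpec(16.0), (32, 32))
    assert rec.fiber_count == 0 and rec.fiber_density_per_mm2 == 0
    assert rec.axon_packing == 0 and rec.myelin_packing == 0
    # zero fascicle pixels -> missing metrics, no division error
    rec2 = window_metrics(inst, FascicleMask(np.zeros(shape, bool)), WindowSpec(16.0), (32, 32))
    assert np.isnan(rec2.fiber_density_per_mm2) and np.isnan(rec2.axon_packing)


def test_quadrat_exclusion_rule():
    """Fiber touching the top row or left column is excluded; one crossing
    only the right border counts as 1; the count is an integer."""
    inst = _toy_instances(resolution=1.0)
    mask = FascicleMask(np.ones(inst.shape, dtype=bool))
    win = WindowSpec(32.0)  # 32 px window
    # window [4,36) x [4,36): fiber 1 fully inside, fiber 2 crosses the
    # right border only, fiber 3 outside
    anchor = (19, 19)
    assert window_bounds(anchor, 32, inst.shape) == (4, 36, 4, 36)
    rec = quadrat_metrics(inst, mask, win, anchor)
    assert rec.fiber_count == 2.0  # right-border fiber included
    # shift so fiber 1 touches the top edge row -> excluded
    anchor2 = (23, 19)  # window rows [8, 40): fiber 1's top myelin row = 8
    rec2 = quadrat_metrics(inst, mask, win, anchor2)
    assert rec2.fiber_count == 1.0
    assert float(rec2.fiber_count).is_integer()


def test_fractional_vs_quadrat_denominators():
    """Fascicle-area density >= window-area density when the window
    overlaps non-fascicle area."""
    inst = _toy_instances(resolution=1.0)
    include = np.ones(inst.shape, dtype=bool)
    include[:, 40:] = False  # fascicle border inside the window
    mask = FascicleMask(include)
    win = WindowSpec(48.0)
    ctx = make_context(inst, mask)
    rec = window_metrics(inst, mask, win, (32, 32), ctx=ctx)
    window_area_mm2 = (48 * 1.0) ** 2 / 1e6
    density_window_denom = rec.fiber_count / window_area_mm2
    assert rec.fiber_density_per_mm2 >= density_window_denom


def test_partition_conservation(small_phantom):
    """Fractional counts over a window partition sum to the fiber count."""
    _, mask, _, instances = small_phantom
    ctx = make_context(instances, mask)
    win = WindowSpec(40 * instances.resolution)  # 40 px windows tile 160 px
    total = 0.0
    for anchor in partition_anchors(instances.shape, 40):
        total += window_metrics(instances, mask, win, anchor, ctx=ctx).fiber_count
    n = len(instances.fiber_ids)
    assert total == pytest.approx(n, abs=1e-9 * max(n, 1))


def test_cellwise_cardinality_and_uniformity(small_phantom):
    _, mask, truth, instances = small_phantom
    win = WindowSpec(15.0)
    table = cellwise_metrics(instances, mask, win)
    assert len(table) == len(instances.fiber_ids)
    # uniform phantom: cell-wise densities scatter around the global density
    fasc = truth.fascicles.iloc[0]
    med = np.median(table.fiber_density_per_mm2)
    assert med == pytest.approx(fasc.density_per_mm2, rel=0.35)


def test_pixelwise_equals_bruteforce_and_chunk_invariant(small_phantom):
    """Engine output bit-identical to looping the single-window routine
    over every fascicle pixel, for two chunk sizes."""
    _, mask, _, instances = small_phantom
    win = WindowSpec(8.0)
    d64, a64, m64 = pixelwise_metrics(instances, mask, win, chunk=64)
    d256, a256, m256 = pixelwise_metrics(instances, mask, win, chunk=256)
    assert np.array_equal(d64, d256, equal_nan=True)
    assert np.array_equal(a64, a256, equal_nan=True)
    assert np.array_equal(m64, m256, equal_nan=True)

    ctx = make_context(instances, mask)
    rs, cs = np.where(mask.include)
    rng = np.random.default_rng(0)
    sel = rng.choice(len(rs), size=500, replace=False)
    for i in sel:
        r, c = int(rs[i]), int(cs[i])
        rec = window_metrics(instances, mask, win, (r, c), ctx=ctx)
        assert rec.fiber_density_per_mm2 == d64[r, c]
        assert rec.axon_packing == a64[r, c]
        assert rec.myelin_packing == m64[r, c]
    assert np.isnan(d64[~mask.include]).all()


def test_pixelwise_mean_recovers_truth():
    """Mean pixel-wise density over the fascicle interior within 5% of
    ground truth.  Fibers are small relative to the fascicle so the
    placement depletion rim at the boundary is negligible."""
    from scipy import ndimage

    from nervemetrics.instancing import run_instancing
    from nervemetrics.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(image_shape=(320, 320), seed=4, target_packing=0.45,
                       median_fiber_diameter_um=1.5, fiber_diameter_log_sd=0.15)
    semantic, mask, truth = generate_phantom(spec)
    _, instances = run_instancing(semantic, mask)
    win = WindowSpec(8.0)
    d, _, _ = pixelwise_metrics(instances, mask, win)
    half = win.side_px(spec.resolution) // 2
    interior = ndimage.binary_erosion(mask.include, iterations=half + 8)
    est = np.nanmean(d[interior])
    assert est == pytest.approx(truth.fascicles.density_per_mm2.iloc[0], rel=0.05)


def test_window_under_two_px_rejected():
    with pytest.raises(ValueError):
        WindowSpec(0.1).side_px(0.125)
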