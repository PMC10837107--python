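"""Synthetic nerve-phantom generator.

Emulates toluidine-blue-derived semantic segmentations of peripheral-nerve
cross-sections at light-microscopy resolution (default 0.125 µm/px):
circle-packed myelinated fibers (axon disk + concentric myelin annulus)
placed by dart throwing inside elliptical fascicles, with log-normal fiber
diameters, a bounded g-ratio distribution, optional excluded (poor-fixation)
regions, and group-level effects — a surgery effect shared by all implanted
samples and a stimulation effect that scales monotonically with the
Shannon-k stimulation intensity — so the regression stages have recoverable
structure and every downstream stage can be validated against exact ground
truth.

Rasterization rule: a pixel belongs to a shape iff its center lies strictly
inside — simple, and it makes an exact pixel-count oracle possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from nervemetrics.types import AXON, BACKGROUND, MYELIN, FascicleMask, SemanticMap


@dataclass
class Ellipse:
    """Fascicle outline: center (row, col) px, semi-axes (a, b) px, rotation rad."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    @property
    def area_px(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def contains(self, rows: np.ndarray, cols: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Vectorized point-in-ellipse test with an optional inward margin (px)."""
        a, b = self.semi_axes
        if a - margin <= 0 or b - margin <= 0:
            return np.zeros(np.broadcast(rows, cols).shape, dtype=bool)
        dr = np.asarray(rows, dtype=float) - self.center[0]
        dc = np.asarray(cols, dtype=float) - self.center[1]
        ct, st = np.cos(self.rotation), np.sin(self.rotation)
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        return (u / (a - margin)) ** 2 + (v / (b - margin)) ** 2 < 1.0


@dataclass
class EffectModel:
    """Group-level effects applied at generation time.

    Implanted samples (sham and stim) lose a fraction of fibers and have
    thinner myelin than controls; stimulated samples additionally lose
    fibers and myelin thickness monotonically with Shannon k above the
    sham baseline.  Multipliers of 1.0 and slopes of 0.0 give a null study
    in which the three groups are statistically exchangeable.
    """

    surgery_density_mult: float = 0.85
    surgery_myelin_mult: float = 0.90
    stim_density_per_k: float = 0.06
    stim_myelin_per_k: float = 0.04
    sham_k: float = -4.0

    def density_mult(self, group: str, shannon_k: float | None) -> float:
        if group == "control":
            return 1.0
        m = self.surgery_density_mult
        if group == "stim":
            m *= float(np.exp(-self.stim_density_per_k * max(shannon_k - self.sham_k, 0.0)))
        return m

    def myelin_mult(self, group: str, shannon_k: float | None) -> float:
        if group == "control":
            return 1.0
        m = self.surgery_myelin_mult
        if group == "stim":
            m *= float(np.exp(-self.stim_myelin_per_k * max(shannon_k - self.sham_k, 0.0)))
        return m


@dataclass
class PhantomSpec:
    """Full description of one synthetic sample.

    Fiber diameters are log-normal (median `median_fiber_diameter_um`,
    log-sd `fiber_diameter_log_sd`) — positive and right-skewed, as nerve
    fiber calibers are; a two-component mixture is available through
    `diameter_mixture` = (second median µm, mixture weight) for bimodal
    caliber spectra.  The g-ratio is truncated-normal on `gratio_bounds`,
    strictly inside (0, 1).
    """

    image_shape: tuple[int, int] = (512, 512)
    resolution: float = 0.125
    fascicles: list[Ellipse] | None = None
    median_fiber_diameter_um: float = 6.0
    fiber_diameter_log_sd: float = 0.35
    diameter_mixture: tuple[float, float] | None = None
    gratio_mean: float = 0.60
    gratio_sd: float = 0.06
    gratio_bounds: tuple[float, float] = (0.30, 0.90)
    target_packing: float = 0.55
    min_gap_px: float = 0.0
    exclusion_regions: list[np.ndarray] = field(default_factory=list)
    group: str = "control"
    shannon_k: float | None = None
    effects: EffectModel = field(default_factory=EffectModel)
    seed: int = 0
    max_attempts: int = 200_000
    max_consecutive_failures: int = 4_000

    def __post_init__(self) -> None:
        if self.fascicles is None:
            r0, c0 = self.image_shape[0] / 2, self.image_shape[1] / 2
            self.fascicles = [Ellipse((r0, c0), (0.44 * self.image_shape[0], 0.40 * self.image_shape[1]))]
        self.validate()

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (µm/px)")
        if not 0 < self.target_packing < 1:
            raise ValueError("target_packing must be in (0, 1)")
        lo, hi = self.gratio_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("g-ratio support must lie strictly inside (0, 1)")
        if self.group not in ("control", "sham", "stim"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "stim" and self.shannon_k is None:
            raise ValueError("stim samples require a Shannon k")
        nr, nc = self.image_shape
        for ell in self.fascicles:
            a, b = ell.semi_axes
            if a <= 0 or b <= 0:
                raise ValueError("zero-area fascicle ellipse")
            r = max(a, b)
            if not (0 <= ell.center[0] - r and ell.center[0] + r <= nr - 1
                    and 0 <= ell.center[1] - r and ell.center[1] + r <= nc - 1):
                raise ValueError("fascicle ellipse extends beyond image bounds")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class PhantomGroundTruth:
    """Exact pre-rasterization geometry of a rendered phantom.

    `fibers`: one row per rendered fiber (fiber_id, center_row, center_col,
    axon_radius_um, fiber_radius_um, g_ratio, fascicle).
    `fascicles`: per-fascicle true fiber density (fibers/mm²), true axon and
    myelin packing computed from the exact disk areas.
    """

    fibers: pd.DataFrame
    fascicles: pd.DataFrame
    achieved_packing: float


class _GratioSampler:
    """Buffered truncated-normal g-ratio draws (frozen dist, batch rvs)."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator, batch: int = 2048):
        lo, hi = spec.gratio_bounds
        a = (lo - spec.gratio_mean) / spec.gratio_sd
        b = (hi - spec.gratio_mean) / spec.gratio_sd
        self._dist = stats.truncnorm(a, b, loc=spec.gratio_mean, scale=spec.gratio_sd)
        self._rng = rng
        self._batch = batch
        self._buf = np.empty(0)
        self._i = 0

    def draw(self) -> float:
        if self._i >= len(self._buf):
            self._buf = self._dist.rvs(size=self._batch, random_state=self._rng)
            self._i = 0
        v = float(self._buf[self._i])
        self._i += 1
        return v


def _sample_fiber_diameter_um(spec: PhantomSpec, rng: np.random.Generator) -> float:
    median = spec.median_fiber_diameter_um
    if spec.diameter_mixture is not None:
        median2, weight = spec.diameter_mixture
        if rng.random() < weight:
            median = median2
    return float(median * np.exp(rng.normal(0.0, spec.fiber_diameter_log_sd)))


def _circle_inside_ellipse(ell: Ellipse, row: float, col: float, radius: float) -> bool:
    """Whether a disk lies fully inside the ellipse (boundary sampling test)."""
    theta = np.linspace(0.0, 2 * np.pi, 72, endpoint=False)
    rr = row + radius * np.cos(theta)
    cc = col + radius * np.sin(theta)
    return bool(ell.contains(rr, cc).all())


def _place_fibers(spec: PhantomSpec, ell: Ellipse, rng: np.random.Generator):
    """Dart-throwing (random sequential adsorption) of non-overlapping disks.

    Returns (centers (n,2) px, axon radii px, fiber radii px).  Stops when
    the placed fiber area reaches the packing target or the attempt budget
    is exhausted — an unreachable target yields a partial render, never an
    exception.
    """
    myelin_mult = spec.effects.myelin_mult(spec.group, spec.shannon_k)
    target_area = spec.target_packing * ell.area_px
    gap = spec.min_gap_px
    gratio = _GratioSampler(spec, rng)

    centers: list[tuple[float, float]] = []
    r_fib: list[float] = []
    r_ax: list[float] = []
    placed_area = 0.0
    c_arr = np.empty((0, 2))
    r_arr = np.empty(0)
    consecutive_failures = 0

    for _ in range(spec.max_attempts):
        if placed_area >= target_area or consecutive_failures >= spec.max_consecutive_failures:
            break
        d_um = _sample_fiber_diameter_um(spec, rng)
        rf = d_um / 2.0 / spec.resolution
        g = gratio.draw()
        ra = g * rf
        rf_eff = ra + (rf - ra) * myelin_mult  # thinner myelin under stimulation/surgery
        if rf_eff < 2.0:  # sub-resolvable caliber; resample
            continue
        # uniform point in the ellipse, with the fiber's own radius as margin
        u = rng.random()
        t = rng.random() * 2 * np.pi
        a, b = ell.semi_axes
        s = np.sqrt(u)
        dr = s * np.cos(t) * max(a - rf_eff, 0.0)
        dc = s * np.sin(t) * max(b - rf_eff, 0.0)
        ct, st = np.cos(ell.rotation), np.sin(ell.rotation)
        row = ell.center[0] + dr * ct - dc * st
        col = ell.center[1] + dr * st + dc * ct
        if not _circle_inside_ellipse(ell, row, col, rf_eff):
            consecutive_failures += 1
            continue
        if len(centers):
            d = np.hypot(c_arr[:, 0] - row, c_arr[:, 1] - col)
            if np.any(d < r_arr + rf_eff + gap):
                consecutive_failures += 1
                continue
        centers.append((row, col))
        r_fib.append(rf_eff)
        r_ax.append(ra)
        placed_area += np.pi * rf_eff**2
        c_arr = np.asarray(centers)
        r_arr = np.asarray(r_fib)
        consecutive_failures = 0

    # group-level fiber loss: drop a random subset of exactly the right size,
    # so the retained count is monotone in the density multiplier
    keep_p = spec.effects.density_mult(spec.group, spec.shannon_k)
    if keep_p < 1.0 and len(centers):
        keep_n = int(round(keep_p * len(centers)))
        keep = np.sort(rng.permutation(len(centers))[:keep_n])
        c_arr = c_arr[keep]
        r_arr = r_arr[keep]
        r_ax = list(np.asarray(r_ax)[keep])
    return c_arr.reshape(-1, 2), np.asarray(r_ax, dtype=float), np.asarray(r_arr, dtype=float).reshape(-1)


def _rasterize_fiber(classes: np.ndarray, row: float, col: float, ra: float, rf: float) -> None:
    r0 = max(int(np.floor(row - rf)) - 1, 0)
    r1 = min(int(np.ceil(row + rf)) + 2, classes.shape[0])
    c0 = max(int(np.floor(col - rf)) - 1, 0)
    c1 = min(int(np.ceil(col + rf)) + 2, classes.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    patch = classes[r0:r1, c0:c1]
    patch[(d2 < rf**2) & (patch == BACKGROUND)] = MYELIN
    patch[d2 < ra**2] = AXON


def _rasterize_polygon(shape: tuple[int, int], vertices: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon

    vertices = np.asarray(vertices, dtype=float)
    rr, cc = polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[SemanticMap, FascicleMask, PhantomGroundTruth]:
    """Render one synthetic semantic map with its fascicle mask and ground truth.

    Identical (spec, seed) pairs reproduce bit-identical rasters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    classes = np.zeros(shape, dtype=np.uint8)
    include = np.zeros(shape, dtype=bool)

    fiber_rows = []
    fasc_rows = []
    total_fiber_area_px = 0.0
    total_fascicle_area_px = 0.0
    next_id = 1

    rr_full, cc_full = np.mgrid[0:shape[0], 0:shape[1]]
    for fi, ell in enumerate(spec.fascicles):
        inside = ell.contains(rr_full, cc_full)
        include |= inside
        fascicle_area_px = int(inside.sum())
        if fascicle_area_px == 0:
            raise ValueError("fascicle rasterizes to zero area")

        centers, r_ax, r_fib = _place_fibers(spec, ell, rng)
        axon_area_um2 = 0.0
        myelin_area_um2 = 0.0
        for k in range(len(centers)):
            _rasterize_fiber(classes, centers[k, 0], centers[k, 1], r_ax[k], r_fib[k])
            fiber_rows.append(
                dict(
                    fiber_id=next_id,
                    center_row=centers[k, 0],
                    center_col=centers[k, 1],
                    axon_radius_um=r_ax[k] * spec.resolution,
                    fiber_radius_um=r_fib[k] * spec.resolution,
                    g_ratio=r_ax[k] / r_fib[k],
                    fascicle=fi,
                )
            )
            axon_area_um2 += np.pi * (r_ax[k] * spec.resolution) ** 2
            myelin_area_um2 += np.pi * ((r_fib[k] ** 2 - r_ax[k] ** 2) * spec.resolution**2)
            next_id += 1

        area_um2 = fascicle_area_px * spec.resolution**2
        fasc_rows.append(
            dict(
                fascicle=fi,
                n_fibers=len(centers),
                fascicle_area_um2=area_um2,
                density_per_mm2=len(centers) / (area_um2 / 1e6),
                axon_packing=axon_area_um2 / area_um2,
                myelin_packing=myelin_area_um2 / area_um2,
            )
        )
        total_fiber_area_px += float(np.sum(np.pi * r_fib**2))
        total_fascicle_area_px += fascicle_area_px

    for poly in spec.exclusion_regions:
        include &= ~_rasterize_polygon(shape, poly)

    truth = PhantomGroundTruth(
        fibers=pd.DataFrame(
            fiber_rows,
            columns=["fiber_id", "center_row", "center_col", "axon_radius_um",
                     "fiber_radius_um", "g_ratio", "fascicle"],
        ),
        fascicles=pd.DataFrame(fasc_rows),
        achieved_packing=total_fiber_area_px / total_fascicle_area_px if total_fascicle_area_px else 0.0,
    )
    return (
        SemanticMap(classes, spec.resolution),
        FascicleMask(include, provenance="phantom"),
        truth,
    )


@dataclass
class SampleMetadata:
    """Per-sample study metadata consumed by the regression stage."""

    sample_id: str
    group: str
    shannon_k: float | None = None
    stim_current_ma: float | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "sham", "stim"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "stim" and self.shannon_k is None:
            raise ValueError("stim samples must carry a Shannon k")
        if self.group == "control" and self.shannon_k is not None:
            raise ValueError("control samples carry no Shannon k")


@dataclass
class StudySample:
    sample_id: str
    semantic: SemanticMap
    mask: FascicleMask
    metadata: SampleMetadata
    truth: PhantomGroundTruth
    spec: PhantomSpec


def generate_study(
    n_control: int,
    n_sham: int,
    stim_levels: list[float],
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    packing_jitter_sd: float = 0.015,
    diameter_jitter_log_sd: float = 0.03,
) -> list[StudySample]:
    """Generate a full synthetic study: controls, shams, and one stimulated
    sample per Shannon-k level.

    Per-sample seeds are derived from the master seed by a counter-based
    scheme (`numpy.random.SeedSequence(seed).spawn`); mild between-sample
    jitter of packing and median caliber provides within-group biological
    variability.  Sham samples differ from controls by the surgery effect;
    stimulated samples additionally express fiber loss and myelin thinning
    monotone in Shannon k.
    """
    if n_control < 1 or n_sham < 1 or len(stim_levels) < 1:
        raise ValueError("each group needs at least one sample")
    base_spec = base_spec if base_spec is not None else PhantomSpec()

    plan: list[tuple[str, str, float | None]] = []
    plan += [(f"control-{i + 1}", "control", None) for i in range(n_control)]
    plan += [(f"sham-{i + 1}", "sham", base_spec.effects.sham_k) for i in range(n_sham)]
    plan += [(f"stim-{i + 1}", "stim", float(k)) for i, k in enumerate(stim_levels)]

    children = np.random.SeedSequence(seed).spawn(len(plan))
    samples: list[StudySample] = []
    for (sample_id, group, k), child in zip(plan, children):
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        jit = np.random.default_rng(child_seed + 1)
        packing = float(np.clip(base_spec.target_packing + jit.normal(0.0, packing_jitter_sd), 0.05, 0.95))
        median_d = float(base_spec.median_fiber_diameter_um * np.exp(jit.normal(0.0, diameter_jitter_log_sd)))
        spec = base_spec.replace(
            group=group,
            shannon_k=k,
            seed=child_seed,
            target_packing=packing,
            median_fiber_diameter_um=median_d,
        )
        semantic, mask, truth = generate_phantom(spec)
        meta = SampleMetadata(sample_id=sample_id, group=group, shannon_k=k)
        samples.append(StudySample(sample_id, semantic, mask, meta, truth, spec))
    return samples
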