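"""2-D kernel-density summaries of per-sample regression outputs.

Each sample's cloud of (surgery value, stimulation value) points is
summarized by a Gaussian-product-kernel density estimate computed by FFT
convolution of linearly binned point mass, with per-dimension bandwidths
from Scott's rule for two dimensions,

    h_i = sigma_i * n^(-1/6),

and by its highest-density regions (HDR) at 68% ("1 sigma") and 95%
("2 sigma") probability mass — the smallest density superlevel sets
holding at least that mass.  Multimodal clouds legitimately produce
multiple disjoint contour loops; all are drawn.

Grid: 256×256 over the data bounding box padded by 4 bandwidths per side
(kernel truncation error is then far below the estimator's accuracy);
the per-sample density is renormalized to unit mass on the grid after
padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

GRID_SIZE = 256
PAD_BANDWIDTHS = 4.0
DEFAULT_MASSES = (0.68, 0.95)


@dataclass
class Density2D:
    """Normalized density on a regular grid, with its HDR thresholds."""

    x: np.ndarray  # grid centers, first dimension (n_x,)
    y: np.ndarray  # grid centers, second dimension (n_y,)
    density: np.ndarray  # (n_x, n_y), integrates to 1 over the grid
    bandwidths: tuple[float, float]
    levels: dict = field(default_factory=dict)  # mass -> density threshold

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


def scott_bandwidths(points: np.ndarray) -> tuple[float, float]:
    """Scott's rule for d = 2: per-dimension sample SD times n^(-1/6)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    s = pts.std(axis=0, ddof=1)
    factor = n ** (-1.0 / 6.0)
    return float(s[0] * factor), float(s[1] * factor)


def _linear_bin(points: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear assignment of unit point masses to the 4 surrounding nodes."""
    dx = x[1] - x[0]
    dy = y[1] - y[0]
    fx = (points[:, 0] - x[0]) / dx
    fy = (points[:, 1] - y[0]) / dy
    ix = np.clip(np.floor(fx).astype(int), 0, len(x) - 2)
    iy = np.clip(np.floor(fy).astype(int), 0, len(y) - 2)
    rx = np.clip(fx - ix, 0.0, 1.0)
    ry = np.clip(fy - iy, 0.0, 1.0)
    grid = np.zeros((len(x), len(y)))
    np.add.at(grid, (ix, iy), (1 - rx) * (1 - ry))
    np.add.at(grid, (ix + 1, iy), rx * (1 - ry))
    np.add.at(grid, (ix, iy + 1), (1 - rx) * ry)
    np.add.at(grid, (ix + 1, iy + 1), rx * ry)
    return grid


def kde2d(points: np.ndarray, grid_size: int = GRID_SIZE) -> Density2D:
    """FFT kernel density estimate of a 2-D point cloud.

    Gaussian product kernel, Scott's-rule bandwidths, linear binning on a
    `grid_size`² lattice padded by 4 bandwidths per side, FFT convolution,
    then renormalization to unit mass on the grid.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a density estimate")
    sd = pts.std(axis=0, ddof=1)
    if not (sd > 0).all():
        raise ValueError("degenerate (constant) dimension: plot the points directly")

    hx, hy = scott_bandwidths(pts)
    x = np.linspace(pts[:, 0].min() - PAD_BANDWIDTHS * hx,
                    pts[:, 0].max() + PAD_BANDWIDTHS * hx, grid_size)
    y = np.linspace(pts[:, 1].min() - PAD_BANDWIDTHS * hy,
                    pts[:, 1].max() + PAD_BANDWIDTHS * hy, grid_size)
    grid = _linear_bin(pts, x, y)

    dx = x[1] - x[0]
    dy = y[1] - y[0]
    kx = np.arange(-(grid_size - 1), grid_size) * dx
    ky = np.arange(-(grid_size - 1), grid_size) * dy
    gauss_x = np.exp(-0.5 * (kx / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    gauss_y = np.exp(-0.5 * (ky / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    kernel = np.outer(gauss_x, gauss_y)
    density = fftconvolve(grid, kernel, mode="valid")
    density = np.clip(density, 0.0, None)

    mass = density.sum() * dx * dy
    density /= mass
    d = Density2D(x=x, y=y, density=density, bandwidths=(hx, hy))
    d.levels = hdr_levels(d, DEFAULT_MASSES)
    return d


def hdr_levels(density: Density2D, masses: Sequence[float] = DEFAULT_MASSES) -> dict:
    """Highest-density-region thresholds for the requested masses.

    For each target mass, the density threshold t such that grid cells
    with density ≥ t hold the smallest mass ≥ target (sort-and-accumulate
    over cells).  Larger target mass gives a lower threshold.
    """
    flat = np.sort(density.density.ravel())[::-1]
    cum = np.cumsum(flat) * density.cell_area
    out = {}
    for m in masses:
        if not 0.0 < m < 1.0:
            raise ValueError("target mass must be in (0, 1)")
        idx = int(np.searchsorted(cum, m))
        idx = min(idx, len(flat) - 1)
        out[float(m)] = float(flat[idx])
    return out


def direct_kde(points: np.ndarray, probes: np.ndarray,
               bandwidths: tuple[float, float] | None = None) -> np.ndarray:
    """Exact (non-FFT) evaluation of the same Gaussian-product KDE at
    probe points; the independent reference for the FFT path."""
    pts = np.asarray(points, dtype=float)
    probes = np.asarray(probes, dtype=float)
    hx, hy = bandwidths if bandwidths is not None else scott_bandwidths(pts)
    dx = (probes[:, None, 0] - pts[None, :, 0]) / hx
    dy = (probes[:, None, 1] - pts[None, :, 1]) / hy
    k = np.exp(-0.5 * (dx**2 + dy**2))
    return k.sum(axis=1) / (len(pts) * 2 * np.pi * hx * hy)


def plot_samples(
    densities: dict,
    means: "object",
    out_path: str,
    masses: Sequence[float] = DEFAULT_MASSES,
) -> None:
    """Render the per-sample summary figure.

    `densities`: {sample_id: Density2D}; `means`: DataFrame with columns
    sample_id, group, surgery_value, stimulation_value.  Per-sample mean
    markers are group-coded (control: blue circles, sham: green squares,
    stim: orange triangles); solid contours mark the 68% HDR and shaded
    regions the 95% HDR.  Written as SVG or PNG by file extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    style = {
        "control": dict(color="tab:blue", marker="o"),
        "sham": dict(color="tab:green", marker="s"),
        "stim": dict(color="tab:orange", marker="^"),
    }
    lo_mass, hi_mass = min(masses), max(masses)

    fig, ax = plt.subplots(figsize=(7, 6))
    present_groups = []
    for _, row in means.iterrows():
        sid, group = row["sample_id"], row["group"]
        st = style[group]
        label = group if group not in present_groups else None
        present_groups.append(group)
        ax.scatter(row["surgery_value"], row["stimulation_value"],
                   color=st["color"], marker=st["marker"], s=60, zorder=5,
                   edgecolor="black", linewidth=0.5, label=label)
        d = densities.get(sid)
        if d is None:
            continue
        levels = d.levels or hdr_levels(d, masses)
        ax.contourf(d.x, d.y, d.density.T, levels=[levels[hi_mass], np.inf],
                    colors=[st["color"]], alpha=0.2)
        ax.contour(d.x, d.y, d.density.T, levels=[levels[lo_mass]],
                   colors=[st["color"]], linewidths=1.2)
    ax.set_xlabel("surgery regression value")
    ax.set_ylabel("stimulation regression value (Shannon k)")
    if present_groups:
        ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
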