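"""End-to-end reproducible pipeline.

Stages, in data-flow order: phantom → instancing → morphometry →
structmetrics → regression → viz.  Each stage reads its inputs from the
run directory and writes its outputs there, so any stage is resumable
from prior outputs.  A deterministic manifest (config, seeds, software
versions, logged design-decision values) plus a separate timing file are
written at the end; re-running from the same config and seed reproduces
all stage outputs bit-for-bit (timings, by nature, vary).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nervemetrics import __version__, io
from nervemetrics.density_viz import kde2d, plot_samples
from nervemetrics.instancing import DEFAULT_MIN_AXON_PX, run_instancing
from nervemetrics.morphometry import FEATURE_COLUMNS, compute_morphometrics
from nervemetrics.phantom import PhantomSpec, generate_study
from nervemetrics.regression import (
    RegressionSpec,
    assemble_dataset,
    fit_regression,
    infer_all,
)
from nervemetrics.structmetrics import (
    LARGE_WINDOW_UM,
    SMALL_WINDOW_UM,
    WindowSpec,
    cellwise_metrics,
    pixelwise_metrics,
)

STAGES = ("phantom", "instancing", "morphometry", "structmetrics", "regression", "viz")

WINDOW_FEATURES = ("fiber_density_per_mm2", "axon_packing", "myelin_packing")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # phantom study (group sizes follow the study design: 8 control,
    # 5 sham, 6 stimulated samples)
    n_control: int = 8
    n_sham: int = 5
    stim_levels: tuple[float, ...] = (-3.5, -2.5, -1.5, -0.5, 0.25, 2.0)
    image_shape: tuple[int, int] = (512, 512)
    resolution: float = 0.125
    target_packing: float = 0.55
    median_fiber_diameter_um: float = 6.0
    # measurement
    min_axon_px: int = DEFAULT_MIN_AXON_PX
    large_window_um: float = LARGE_WINDOW_UM
    small_window_um: float = SMALL_WINDOW_UM
    run_pixelwise: bool = False
    pixelwise_rows_per_sample: int = 4000  # seeded subsample for regression rows
    # regression
    feature_subset: str = "cellwise-large"
    regression: RegressionSpec = field(default_factory=RegressionSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        reg = RegressionSpec(**payload.pop("regression", {}))
        cfg = cls(**payload, regression=reg)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sample_dirs(out: Path) -> list[Path]:
    dirs = sorted((out / "samples").glob("*"))
    if not dirs:
        raise FileNotFoundError(f"no sample outputs under {out / 'samples'}")
    return dirs


def _stage_phantom(cfg: PipelineConfig, out: Path) -> dict:
    spec = PhantomSpec(
        image_shape=tuple(cfg.image_shape),
        resolution=cfg.resolution,
        target_packing=cfg.target_packing,
        median_fiber_diameter_um=cfg.median_fiber_diameter_um,
    )
    samples = generate_study(cfg.n_control, cfg.n_sham, list(cfg.stim_levels), spec, seed=cfg.seed)
    meta = []
    for s in samples:
        d = out / "samples" / s.sample_id
        d.mkdir(parents=True, exist_ok=True)
        io.write_semantic(d / "semantic.tif", s.semantic)
        io.write_mask(d / "mask.tif", s.mask)
        io.write_table(d / "truth_fibers.csv", s.truth.fibers)
        io.write_table(d / "truth_fascicles.csv", s.truth.fascicles)
        meta.append(s.metadata)
    io.write_metadata(out / "metadata.yaml", meta)
    return {"n_samples": len(samples)}


def _stage_instancing(cfg: PipelineConfig, out: Path) -> dict:
    n_fibers = 0
    for d in _sample_dirs(out):
        semantic = io.read_semantic(d / "semantic.tif")
        mask = io.read_mask(d / "mask.tif")
        _, instances = run_instancing(semantic, mask, min_axon_px=cfg.min_axon_px)
        io.write_instances(d / "instances", instances)
        n_fibers += len(instances.fiber_ids)
    return {"n_fibers": n_fibers}


def _stage_morphometry(cfg: PipelineConfig, out: Path) -> dict:
    frames = []
    for d in _sample_dirs(out):
        instances = io.read_instances(d / "instances")
        fibers = compute_morphometrics(instances)
        fibers.insert(0, "sample_id", d.name)
        io.write_table(d / "fibers.csv", fibers)
        frames.append(fibers)
    all_fibers = pd.concat(frames, ignore_index=True)
    io.write_table(out / "fibers.csv", all_fibers)
    return {"n_fiber_records": len(all_fibers)}


def _stage_structmetrics(cfg: PipelineConfig, out: Path) -> dict:
    windows = {"large": WindowSpec(cfg.large_window_um), "small": WindowSpec(cfg.small_window_um)}
    counts = {}
    frames = {k: [] for k in windows}
    pixel_frames = []
    for d in _sample_dirs(out):
        instances = io.read_instances(d / "instances")
        mask = io.read_mask(d / "mask.tif")
        for key, win in windows.items():
            cw = cellwise_metrics(instances, mask, win)
            cw.insert(0, "sample_id", d.name)
            io.write_table(d / f"cellwise_{key}.csv", cw)
            frames[key].append(cw)
        if cfg.run_pixelwise:
            win = windows["large"]
            density, ap, mp = pixelwise_metrics(instances, mask, win)
            meta = {"window_um": win.side_um,
                    "window_px": win.side_px(instances.resolution),
                    "resolution_um_per_px": instances.resolution}
            io.write_metric_raster(d / "pixelwise_density.tif", density, meta)
            io.write_metric_raster(d / "pixelwise_axon_packing.tif", ap, meta)
            io.write_metric_raster(d / "pixelwise_myelin_packing.tif", mp, meta)
            valid = np.where(np.isfinite(density))
            import zlib

            rng = np.random.default_rng(cfg.seed + zlib.adler32(d.name.encode()) % 10_000)
            take = rng.choice(len(valid[0]), size=min(cfg.pixelwise_rows_per_sample, len(valid[0])),
                              replace=False)
            take.sort()
            pf = pd.DataFrame(
                {
                    "sample_id": d.name,
                    "fiber_density_per_mm2": density[valid][take],
                    "axon_packing": ap[valid][take],
                    "myelin_packing": mp[valid][take],
                }
            )
            pixel_frames.append(pf)
    for key in windows:
        table = pd.concat(frames[key], ignore_index=True)
        io.write_table(out / f"cellwise_{key}.csv", table)
        counts[f"cellwise_{key}_rows"] = len(table)
    if pixel_frames:
        table = pd.concat(pixel_frames, ignore_index=True)
        io.write_table(out / "pixelwise_rows.csv", table)
        counts["pixelwise_rows"] = len(table)
    return counts


def _feature_table(cfg: PipelineConfig, out: Path) -> tuple[pd.DataFrame, list[str]]:
    subset = cfg.feature_subset
    if subset == "morphometrics":
        fibers = io.read_table(out / "fibers.csv")
        feats = fibers.dropna(subset=list(FEATURE_COLUMNS))[
            ["sample_id", *FEATURE_COLUMNS]
        ].reset_index(drop=True)
        return feats, list(FEATURE_COLUMNS)
    if subset in ("cellwise-large", "cellwise-small"):
        key = subset.split("-")[1]
        table = io.read_table(out / f"cellwise_{key}.csv")
        return table[["sample_id", *WINDOW_FEATURES]].dropna().reset_index(drop=True), list(WINDOW_FEATURES)
    if subset in ("combined-large", "combined-small"):
        key = subset.split("-")[1]
        cw = io.read_table(out / f"cellwise_{key}.csv")
        fibers = io.read_table(out / "fibers.csv")
        merged = fibers.merge(cw, on=["sample_id", "fiber_id"], how="inner")
        cols = [*FEATURE_COLUMNS, *WINDOW_FEATURES]
        return merged[["sample_id", *cols]].dropna().reset_index(drop=True), cols
    if subset == "pixelwise-large":
        table = io.read_table(out / "pixelwise_rows.csv")
        return table.dropna().reset_index(drop=True), list(WINDOW_FEATURES)
    raise ValueError(f"unknown feature subset {subset!r}")


def _stage_regression(cfg: PipelineConfig, out: Path) -> dict:
    meta = io.read_metadata(out / "metadata.yaml")
    features, cols = _feature_table(cfg, out)
    spec = dataclasses.replace(cfg.regression, seed=cfg.seed)

    fitted = {}
    for which in ("surgery", "stimulation"):
        ds = assemble_dataset(features, meta, which, feature_columns=cols)
        fitted[which] = fit_regression(ds, spec)

    rows, means = infer_all(fitted["surgery"], fitted["stimulation"], features, meta)
    io.write_table(out / "predictions.csv", rows)
    io.write_table(out / "sample_means.csv", means)
    report = {
        "feature_subset": cfg.feature_subset,
        "features": list(cols),
        "validation_r2": {k: fitted[k].validation_r2 for k in fitted},
        "n_train": {k: fitted[k].n_train for k in fitted},
        "notes": {k: fitted[k].notes for k in fitted},
    }
    (out / "regression_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return {k: round(fitted[k].validation_r2, 4) for k in fitted}


def _stage_viz(cfg: PipelineConfig, out: Path) -> dict:
    rows = io.read_table(out / "predictions.csv")
    means = io.read_table(out / "sample_means.csv")
    densities = {}
    summary = {}
    for sid, grp in rows.groupby("sample_id"):
        pts = grp[["surgery_value", "stimulation_value"]].to_numpy()
        if len(pts) < 3 or not (pts.std(axis=0) > 0).all():
            continue
        d = kde2d(pts)
        densities[sid] = d
        summary[sid] = {
            "bandwidths": list(d.bandwidths),
            "levels": {str(k): v for k, v in d.levels.items()},
            "mean": [float(pts[:, 0].mean()), float(pts[:, 1].mean())],
        }
    plot_samples(densities, means, str(out / "samples_figure.png"))
    (out / "densities.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"n_densities": len(densities)}


_STAGE_FUNCS = {
    "phantom": _stage_phantom,
    "instancing": _stage_instancing,
    "morphometry": _stage_morphometry,
    "structmetrics": _stage_structmetrics,
    "regression": _stage_regression,
    "viz": _stage_viz,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the manifest dict.

    Stages not requested are skipped; their outputs, if present in
    `out_dir` from a previous run, serve as inputs to later stages.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": cfg.to_jsonable(),
        "stages": {},
        "decisions": {
            "connectivity": {"labeling": 8, "adjacency_tests": 4},
            "window_anchor": "top-left of central 2x2 block for even sides",
            "density_unit": "fibers per mm^2 of fascicle area",
            "split": "rows",
        },
    }
    timings = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[stage](cfg, out)
        except FileNotFoundError as exc:
            raise RuntimeError(
                f"stage '{stage}' is missing an input ({exc}); run the producing stage first"
            ) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = info
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True) + "\n")
    return manifest
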