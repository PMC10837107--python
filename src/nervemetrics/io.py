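"""Raster and table I/O with JSON sidecars.

Formats: semantic maps and fascicle masks are single-channel 8-bit TIFF
(class codes 0/1/2; masks 0/255); instance maps are 32-bit integer TIFF
pairs; metric rasters are 32-bit float TIFF; tables are CSV; study
metadata and configs are YAML.  Every raster carries a JSON sidecar with
its resolution and provenance notes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from nervemetrics.phantom import SampleMetadata
from nervemetrics.types import FascicleMask, FiberInstanceMap, SemanticMap


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    return json.loads(sc.read_text()) if sc.exists() else {}


def write_semantic(path: str | Path, semantic: SemanticMap) -> None:
    path = Path(path)
    tifffile.imwrite(path, semantic.classes.astype(np.uint8))
    _write_sidecar(path, {"kind": "semantic", "resolution_um_per_px": semantic.resolution})


def read_semantic(path: str | Path, resolution: float | None = None) -> SemanticMap:
    path = Path(path)
    data = tifffile.imread(path)
    res = resolution or _read_sidecar(path).get("resolution_um_per_px", 0.125)
    return SemanticMap(data, res)


def write_mask(path: str | Path, mask: FascicleMask) -> None:
    path = Path(path)
    tifffile.imwrite(path, (mask.include.astype(np.uint8) * 255))
    _write_sidecar(path, {"kind": "fascicle_mask", "provenance": mask.provenance})


def read_mask(path: str | Path) -> FascicleMask:
    path = Path(path)
    data = tifffile.imread(path)
    prov = _read_sidecar(path).get("provenance", "file")
    return FascicleMask(data > 0, provenance=prov)


def write_instances(dir_path: str | Path, instances: FiberInstanceMap) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "axon_labels.tif", instances.axon_labels.astype(np.int32))
    tifffile.imwrite(d / "myelin_labels.tif", instances.myelin_labels.astype(np.int32))
    (d / "instances.json").write_text(
        json.dumps(
            {
                "resolution_um_per_px": instances.resolution,
                "n_fibers": int(len(instances.fiber_ids)),
                "warnings": instances.warnings,
                "connectivity": {"labeling": 8, "adjacency_tests": 4},
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def read_instances(dir_path: str | Path) -> FiberInstanceMap:
    d = Path(dir_path)
    meta = json.loads((d / "instances.json").read_text())
    return FiberInstanceMap(
        tifffile.imread(d / "axon_labels.tif"),
        tifffile.imread(d / "myelin_labels.tif"),
        meta["resolution_um_per_px"],
        warnings=meta.get("warnings", []),
    )


def write_metric_raster(path: str | Path, raster: np.ndarray, meta: dict) -> None:
    path = Path(path)
    tifffile.imwrite(path, raster.astype(np.float32))
    _write_sidecar(path, meta)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_metadata(path: str | Path, meta: Sequence[SampleMetadata]) -> None:
    payload = [
        {
            "sample_id": m.sample_id,
            "group": m.group,
            "shannon_k": m.shannon_k,
            "stim_current_ma": m.stim_current_ma,
            "pair_id": m.pair_id,
        }
        for m in meta
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    payload = yaml.safe_load(Path(path).read_text())
    return [SampleMetadata(**entry) for entry in payload]
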