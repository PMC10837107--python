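"""Core raster containers shared by the pipeline stages.

Conventions (used everywhere in the package):

* rasters are indexed ``(row, col)``, 0-based, with pixel centers at integer
  coordinates;
* windows are half-open pixel ranges;
* physical resolution is carried as micrometres per pixel (µm/px) and
  physical units are authoritative over pixel counts in user-facing tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Semantic class codes.
BACKGROUND: int = 0
AXON: int = 1
MYELIN: int = 2


@dataclass
class SemanticMap:
    """Per-pixel class raster: background=0, axon=1, myelin=2.

    Parameters
    ----------
    classes
        2-D ``uint8`` array of class codes.
    resolution
        Physical resolution in µm per pixel (> 0).
    """

    classes: np.ndarray
    resolution: float = 0.125

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.ndim != 2:
            raise ValueError("semantic map must be a 2-D raster")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (µm/px)")
        extra = set(np.unique(self.classes)) - {BACKGROUND, AXON, MYELIN}
        if extra:
            raise ValueError(f"unknown class codes in semantic map: {sorted(extra)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    @property
    def axon(self) -> np.ndarray:
        return self.classes == AXON

    @property
    def myelin(self) -> np.ndarray:
        return self.classes == MYELIN

    @property
    def background(self) -> np.ndarray:
        return self.classes == BACKGROUND

    def copy(self) -> "SemanticMap":
        return SemanticMap(self.classes.copy(), self.resolution)


@dataclass
class FascicleMask:
    """Binary raster of measurable fascicle tissue (True = measurable)."""

    include: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include).astype(bool)
        if self.include.ndim != 2:
            raise ValueError("fascicle mask must be a 2-D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.include.shape


@dataclass
class HeightMap:
    """Watershed height raster in [0, 1]: 0 on axon, 1 on background,
    myelin interpolated between its distance to axon and to background."""

    height: np.ndarray

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=np.float64)
        if self.height.ndim != 2:
            raise ValueError("height map must be a 2-D raster")


@dataclass
class FiberInstanceMap:
    """Paired label rasters assigning axon and myelin pixels to fiber ids.

    ``axon_labels`` and ``myelin_labels`` are int32 rasters; 0 means
    "no fiber".  Every nonzero myelin label refers to an axon label present
    in ``axon_labels``.
    """

    axon_labels: np.ndarray
    myelin_labels: np.ndarray
    resolution: float = 0.125
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axon_labels = np.asarray(self.axon_labels, dtype=np.int32)
        self.myelin_labels = np.asarray(self.myelin_labels, dtype=np.int32)
        if self.axon_labels.shape != self.myelin_labels.shape:
            raise ValueError("axon and myelin label rasters must share a shape")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (µm/px)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.axon_labels.shape

    @property
    def fiber_ids(self) -> np.ndarray:
        ids = np.unique(self.axon_labels)
        return ids[ids > 0]

    @property
    def fiber_labels(self) -> np.ndarray:
        """Combined raster: axon ∪ myelin pixels labelled by fiber id."""
        return np.where(self.axon_labels > 0, self.axon_labels, self.myelin_labels)
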