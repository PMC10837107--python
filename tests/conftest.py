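"""Shared fixtures: small phantoms and their instance segmentations.

Everything is generated programmatically and seeded; session scope keeps
the expensive renders to one per suite run.
"""

from __future__ import annotations

import numpy as np
import pytest

from nervemetrics.instancing import run_instancing
from nervemetrics.phantom import PhantomSpec, generate_phantom
from nervemetrics.types import AXON, BACKGROUND, MYELIN, FascicleMask, SemanticMap


def draw_annulus(classes: np.ndarray, center: tuple[float, float], r_axon: float,
                 r_fiber: float) -> None:
    """Center-in-shape rasterization of one axon disk + myelin annulus."""
    rr, cc = np.mgrid[0:classes.shape[0], 0:classes.shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    classes[(d2 < r_fiber**2) & (classes == BACKGROUND)] = MYELIN
    classes[d2 < r_axon**2] = AXON


def single_fiber_map(shape=(64, 64), r_axon=10.0, r_fiber=16.0, resolution=0.125):
    classes = np.zeros(shape, dtype=np.uint8)
    draw_annulus(classes, (shape[0] / 2, shape[1] / 2), r_axon, r_fiber)
    semantic = SemanticMap(classes, resolution)
    mask = FascicleMask(np.ones(shape, dtype=bool), provenance="test")
    return semantic, mask


@pytest.fixture(scope="session")
def recovery_spec():
    """Phantom tuned for exact count/morphometry recovery: calibers big
    enough that every rendered fiber survives cleanup."""
    return PhantomSpec(
        image_shape=(400, 400),
        seed=11,
        target_packing=0.5,
        median_fiber_diameter_um=5.0,
        fiber_diameter_log_sd=0.25,
        gratio_mean=0.6,
        gratio_sd=0.04,
        gratio_bounds=(0.45, 0.75),
    )


@pytest.fixture(scope="session")
def recovery_phantom(recovery_spec):
    return generate_phantom(recovery_spec)


@pytest.fixture(scope="session")
def recovery_instances(recovery_phantom):
    semantic, mask, _ = recovery_phantom
    cleaned, instances = run_instancing(semantic, mask)
    return cleaned, instances


@pytest.fixture(scope="session")
def small_phantom():
    """A denser 160 px phantom with small fibers for window metrics."""
    spec = PhantomSpec(
        image_shape=(160, 160),
        seed=5,
        target_packing=0.5,
        median_fiber_diameter_um=2.5,
        fiber_diameter_log_sd=0.2,
    )
    semantic, mask, truth = generate_phantom(spec)
    _, instances = run_instancing(semantic, mask)
    return semantic, mask, truth, instances
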