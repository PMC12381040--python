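import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_roi():
    """10x10 axis-aligned square ROI (vertices at pixel centers)."""
    from octoquant.io import RoiPolygon

    return RoiPolygon(
        cell_id="sq", vertices=np.array([[5, 5], [14, 5], [14, 14], [5, 14]], dtype=float)
    )


@pytest.fixture
def small_field():
    """Tiny two-channel simulated field, quantified once per session scope cost."""
    from octoquant.pipeline import PipelineConfig, quantify_field
    from octoquant.synthetic import generate_field

    manifest, stacks, rois, masks, truth = generate_field(
        n_cells=6,
        shape_mix=0.5,
        packing="sparse",
        treatment="isotonic",
        seed=7,
        channels=("DIC", "nucleus"),
        frame_shape=(220, 220),
        n_planes=9,
        cell_radius=16,
        noise_sd=2.0,
    )
    config = PipelineConfig(simulate={"n_cells": 1})
    records, qmasks, shape_classes = quantify_field(manifest, stacks, rois, config)
    return {
        "manifest": manifest,
        "stacks": stacks,
        "rois": rois,
        "masks": qmasks,
        "records": records,
        "shape_classes": shape_classes,
        "truth": truth,
    }
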