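"""Shared phantom fixtures.

The expensive artifacts (voxelized phantoms run through the full pipeline)
are session-scoped and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from airwaymorph import phantom, pipeline


def run_phantom(spec: phantom.PhantomSpec, **kwargs) -> dict:
    vol, lms, truth = phantom.generate_phantom(spec)
    result = pipeline.run_pipeline(
        vol,
        lms,
        roi_superior=truth.roi_superior_z,
        roi_inferior=truth.roi_inferior_z,
        **kwargs,
    )
    report = phantom.evaluate_pipeline(truth, result.record)
    return {
        "spec": spec,
        "volume": vol,
        "landmarks": lms,
        "truth": truth,
        "result": result,
        "report": report,
    }


@pytest.fixture(scope="session")
def arc_run() -> dict:
    """Default arc-tube phantom (R=30 mm, taper 5->3 mm) through the pipeline."""
    return run_phantom(phantom.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def cylinder_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(
        curve_kind="line",
        curve_params={"start": (0.0, 0.0, 0.0), "direction": (0.0, 0.0, -1.0), "length": 40.0},
        a_start=5.0, a_end=5.0, b_start=5.0, b_end=5.0,
        boundaries=(5.0, 15.0, 30.0, 35.0),
        seed=2,
    )


@pytest.fixture(scope="session")
def cylinder_run(cylinder_spec) -> dict:
    """Straight vertical cylinder phantom (r=5 mm, L=40 mm, 0.5 mm voxels)."""
    return run_phantom(cylinder_spec)


@pytest.fixture(scope="session")
def tilted_run() -> dict:
    """Cylinder tilted 30 degrees from the superior axis."""
    d = (0.0, float(np.sin(np.deg2rad(30))), -float(np.cos(np.deg2rad(30))))
    spec = phantom.PhantomSpec(
        curve_kind="line",
        curve_params={"start": (0.0, 0.0, 0.0), "direction": d, "length": 40.0},
        a_start=5.0, a_end=5.0, b_start=5.0, b_end=5.0,
        boundaries=(5.0, 15.0, 30.0, 35.0),
        seed=4,
    )
    return run_phantom(spec)
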