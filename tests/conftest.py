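import numpy as np
import pytest

from tetherdic import pipeline, synthgen


@pytest.fixture(scope="session")
def rig():
    return synthgen.default_stereo_rig()


@pytest.fixture(scope="session")
def calibrated(rig):
    """DLT-calibrated pair from a noisy cylinder target (shared)."""
    return pipeline.calibrate_rig(rig, seed=11)


@pytest.fixture(scope="session")
def speckle_image(rig):
    """One rendered speckle image of the planar standard (reference state)."""
    images, _ = synthgen.make_translation_standard(rig, (0.0, 0.0, 0.0), seed=5)
    return images["cam_a"]["reference"]


@pytest.fixture(scope="session")
def tether_scene():
    """Rendered tether scene (nasal compression 0.977) with ground truth."""
    spec = synthgen.SceneSpec(deformation=synthgen.Tether(), seed=3)
    images, gt = synthgen.render_speckle_scene(spec)
    return spec, images, gt


@pytest.fixture(scope="session")
def tether_measurement(tether_scene, calibrated):
    """Full image-pipeline measurement of the tether scene (expensive)."""
    spec, images, gt = tether_scene
    pair, _ = calibrated
    roi = pipeline.roi_from_projections(
        gt.projections["cam_a"]["reference"], grid_step=10)
    meas = pipeline.measure_scene(images, pair, roi, cam_names=("cam_a", "cam_b"))
    meas.region_spec = pipeline.scene_region_spec(spec)
    meas.info["ground_truth"] = gt
    return meas


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
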