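import numpy as np
import pytest

import otstream as ot
from otstream import morphology


@pytest.fixture(scope="session")
def stream_12um():
    """Noise-free 12 µm cell digitized at 2.4 m/s with default clocking."""
    scene = ot.make_cell(12.0, 0.5, None, pitch=0.2, seed=0)
    params = ot.AcqParams(noise_sigma=0.0, seed=1)
    return scene, ot.synthesize_stream(scene, 2.4, params)


@pytest.fixture(scope="session")
def frames_12um(stream_12um):
    """Frames and pixel geometry for the 12 µm phantom at skip 16."""
    scene, stream = stream_12um
    frames, report = ot.process_stream(stream, skip=16)
    geom = morphology.PixelGeometry(
        pitch_cross=stream.params.fov_cross / stream.params.window_px,
        pitch_flow=ot.line_pitch(stream.flow_speed, stream.params.f_rep, 16))
    return frames, report, geom


@pytest.fixture(scope="session")
def population_stream():
    """Noise-free dilute population: 100 8-µm phantoms at 10 m/s.

    The 5 µm hard-core gap encodes the coincidence-free spacing of a
    sample diluted for single-cell imaging.
    """
    scene = ot.make_population(100, ("fixed", 8.0), 50.0, pitch=0.2, seed=3,
                               min_gap_um=5.0)
    params = ot.AcqParams(noise_sigma=0.0, seed=2)
    return scene, ot.synthesize_stream(scene, 10.0, params)


@pytest.fixture(scope="session")
def reference_cell_image(stream_12um):
    """Skip-1 reduced image of the 12 µm phantom (quality-curve reference)."""
    _, stream = stream_12um
    frames, _ = ot.process_stream(stream, skip=1)
    assert len(frames) == 1
    return frames[0].image.astype(float)
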