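import numpy as np
import pytest

from ctikin.io import ContourCine
from ctikin.synth import SyntheticConfig, generate_cohort


def make_cine(frames, patient_id="P0", cti_index_range=None, frame_interval=None):
    """Build a ContourCine from a nested list/array of frames."""
    return ContourCine(
        patient_id=patient_id,
        frames=np.asarray(frames, dtype=float),
        cti_index_range=cti_index_range,
        frame_interval=frame_interval,
    )


def track_cine(track, n_points=7, patient_id="P0"):
    """A cine in which every contour point follows the same 2-D track."""
    track = np.asarray(track, dtype=float)
    offsets = np.column_stack([np.linspace(0, 3, n_points), np.zeros(n_points)])
    frames = track[:, None, :] + offsets[None, :, :]
    return make_cine(frames, patient_id=patient_id, cti_index_range=(0, n_points))


@pytest.fixture(scope="session")
def default_cohort():
    """One small default-condition synthetic cohort, shared read-only."""
    return generate_cohort(SyntheticConfig(seed=42, n_patients=24))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
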