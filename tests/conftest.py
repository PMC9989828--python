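import numpy as np
import pytest

from ldtransfer.detection import detect_contacts, link_tracks, segment_stack
from ldtransfer.synthetic import (
    GroundTruthEvent,
    SimulationConfig,
    generate_timelapse,
)


@pytest.fixture(scope="session")
def pair_event():
    """A single donor/acceptor transfer event with a fast final approach."""
    return GroundTruthEvent(
        donor_center=(3.0, 4.0, 3.0),
        acceptor_center=(6.6, 4.0, 3.0),
        Vd0=4.0,
        Va0=8.0,
        Rd=0.01,
        t_contact=100.0,
        tmax=600.0,
    )


@pytest.fixture(scope="session")
def pair_movie(pair_event):
    """Rendered single-pair movie plus its truth table."""
    cfg = SimulationConfig(
        image_shape=(15, 80, 80), n_frames=35, events=[pair_event], rng_seed=5
    )
    stack, truth = generate_timelapse(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def pair_tracking(pair_movie):
    """Segmentation + tracking + contacts of the single-pair movie."""
    _, stack, _ = pair_movie
    detections, labels = segment_stack(stack)
    tracks, summary = link_tracks(detections)
    contacts = detect_contacts(tracks, labels)
    return detections, labels, tracks, summary, contacts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
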