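import numpy as np
import pytest

from microexp.descriptors import DescriptorParams, FrameSequence
from microexp.geometry import define_cells
from microexp.synthetic import (ExpressionEvent, SceneParams,
                                generate_sequence, landmark_template)


@pytest.fixture(scope="session")
def template_landmarks():
    return landmark_template((160, 160))


@pytest.fixture(scope="session")
def template_grid(template_landmarks):
    return define_cells(template_landmarks)


@pytest.fixture(scope="session")
def default_params():
    return DescriptorParams(tau=37, eps=3, n_resample=11, delta=0.25)


@pytest.fixture(scope="session")
def surprise_sequence():
    """One clean surprise event with known onset/apex/offset."""
    event = ExpressionEvent(cls="surprise", onset=40, apex=64, offset=70,
                            magnitude=3.0)
    params = SceneParams(noise_sigma=0.0, events=(event,), seq_len=130)
    frames, landmarks, annotations = generate_sequence(params, seed=7)
    return frames, landmarks, annotations, event


def constant_sequence(value: float = 100.0, n: int = 50,
                      shape=(32, 32)) -> FrameSequence:
    return FrameSequence(frames=np.full((n, *shape), value, dtype=np.float64),
                         fps=100.0)
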