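import numpy as np
import pytest

from inph_morph import LabelSchema, LabeledVolume, LandmarkSet, PhantomSpec
from inph_morph.phantom import generate_phantom

SCHEMA = LabelSchema()


@pytest.fixture(scope="session")
def default_truth():
    """The default noiseless DESH phantom, generated once per session."""
    return generate_phantom(PhantomSpec(noise_sigma=0.0))


@pytest.fixture()
def default_spec():
    return PhantomSpec(noise_sigma=0.0)


def make_volume(labels: np.ndarray, spacing=1.0, origin=None) -> LabeledVolume:
    """A LabeledVolume with centred origin unless one is given."""
    labels = np.asarray(labels, dtype=np.int16)
    if np.isscalar(spacing):
        spacing = (spacing,) * 3
    if origin is None:
        origin = tuple(-(n - 1) * s / 2 for n, s in zip(labels.shape, spacing))
    return LabeledVolume(labels=labels, spacing=spacing, origin=origin, schema=SCHEMA)


def centered_landmarks(y_ac=5.0, y_pc=-5.0) -> LandmarkSet:
    return LandmarkSet(ac=np.array([0.0, y_ac, 0.0]), pc=np.array([0.0, y_pc, 0.0]))
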