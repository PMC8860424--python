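import numpy as np
import pytest

from spchlpa.experiments import cohort_features
from spchlpa.synthetic import default_spec
from spchlpa.texture import FEATURE_NAMES, ExtractionConfig
from spchlpa.volume_io import CTVolume, LesionMask


def make_volume(values, spacing=(1.0, 1.0, 1.0)) -> CTVolume:
    return CTVolume(voxels=np.asarray(values, dtype=float), spacing=spacing)


def make_mask(flags) -> LesionMask:
    return LesionMask(flags=np.asarray(flags, dtype=bool))


@pytest.fixture(scope="session")
def default_cohort():
    """The default 13 vs 49 synthetic cohort at seed 1, with features."""
    return cohort_features(default_spec(seed=1))


@pytest.fixture(scope="session")
def default_xy(default_cohort):
    X = default_cohort[list(FEATURE_NAMES)].to_numpy()
    y = (default_cohort["label"] == "SPCH").astype(int).to_numpy()
    return X, y


@pytest.fixture()
def extraction_config():
    return ExtractionConfig()
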