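import numpy as np
import pytest

from ocpam.radiomics import extract_feature_vector
from ocpam.synthetic import generate_organoid_timeseries


@pytest.fixture(scope="session")
def feature_dataset():
    """200 organoids (HIGH/LOW texture regimes) with their 32-feature
    vectors, shared by the radiomics/classifier/acceptance tests."""
    X, y = [], []
    for s in range(4):
        vols, masks, truth = generate_organoid_timeseries(
            50,
            days=(3, 5),
            class_mix={"WEAK": 1.0},
            seed=100 + s,
            field_um=(300.0, 600.0, 600.0),
            spacing_um=(2.52, 2.52, 2.52),
            initial_semiaxis_um=(10.0, 14.0, 0.15),
            viability_mix=0.5,
        )
        for o in truth.organoids:
            X.append(extract_feature_vector(vols[0], masks[0], o.id).as_array())
            y.append(o.viability)
    return np.asarray(X), np.asarray(y)


@pytest.fixture(scope="session")
def small_scene():
    """A small 4-organoid, 2-day longitudinal scene with ground truth."""
    return generate_organoid_timeseries(
        4,
        days=(3, 5),
        class_mix={"WEAK": 1.0},
        field_um=(160.0, 320.0, 320.0),
        spacing_um=(2.52, 2.52, 2.52),
        seed=5,
        initial_semiaxis_um=(12.0, 16.0, 0.1),
    )
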