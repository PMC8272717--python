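import numpy as np
import pytest

from relmap.synthetic import (
    amplitude_class_for_icc,
    event_related_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy event-related dataset with a single amplitude class
    of known true reliability 0.75, shared across tests."""
    cfg = event_related_config(
        n_subjects=20,
        grid_shape=(5, 6, 4),
        classes={"reliable": amplitude_class_for_icc(0.75)},
        voxel_class_map=np.full((5, 6, 4), "reliable"),
        noise_sd=0.5,
        seed=11,
    )
    return simulate_dataset(cfg)
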