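import logging

import numpy as np
import pytest

from cutkin.config import RunConfig
from cutkin.pipeline import build_dataset
from cutkin.simulate import SyntheticConfig, generate_trials

logging.getLogger("cutkin").setLevel(logging.ERROR)

#: one modest configuration from inside the published search grid, used when
#: a test needs many pipeline repetitions
LIGHT_HYPERPARAMETERS = {
    t: dict(
        n_estimators=100,
        max_depth=10,
        min_samples_split=2,
        min_samples_leaf=2,
        max_features="log2",
    )
    for t in (
        "vgrf",
        "ankle_sagittal",
        "ankle_frontal",
        "ankle_transverse",
        "knee_sagittal",
        "knee_frontal",
        "knee_transverse",
    )
}


@pytest.fixture(scope="session")
def small_corpus():
    """Nine coupled trials (3 participants x 3), shared across tests."""
    cfg = SyntheticConfig(seed=42, n_participants=3, trials_per_participant=3)
    participants, bundles = generate_trials(cfg)
    return cfg, participants, bundles


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    """The small corpus run through preprocessing into a modeling Dataset."""
    _, _, bundles = small_corpus
    run_cfg = RunConfig(seed=42)
    dataset, processed = build_dataset(
        [(b.imu, b.force, b.moments_nm) for b in bundles], run_cfg
    )
    return dataset, processed
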