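import numpy as np
import pytest

import pulsetwin as pt


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Small synthetic dataset shared by io/pipeline tests: 4 subjects,
    6 train + 4 test records each, default noise and separability."""
    root = tmp_path_factory.mktemp("smallds")
    manifest = pt.generate_dataset(root, n_subjects=4, records_per_subject_train=6,
                                   records_per_subject_test=4, seed=11)
    return root, manifest


@pytest.fixture(scope="session")
def small_cycle_pools(small_dataset):
    """Processed train/test cycle pools of the small dataset (N = 3)."""
    from pulsetwin.pipeline import preprocess_manifest

    _, manifest = small_dataset
    config = pt.RunConfig(n_cycles=3)
    train_cycles, _ = preprocess_manifest(manifest, config, "train")
    test_cycles, _ = preprocess_manifest(manifest, config, "test")
    return train_cycles, test_cycles


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
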