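import numpy as np
import pytest

import pddbench as pb


@pytest.fixture(scope="session")
def synth():
    """Small synthetic table with planted structure plus its ground truth."""
    return pb.generate(pb.SyntheticSpec(n_records=600, seed=11))


@pytest.fixture(scope="session")
def synth_splits(synth):
    table, _ = synth
    return pb.split_dataset(table, pb.SplitSpec(seed=11))


@pytest.fixture(scope="session")
def fitted_pdd(synth_splits):
    train, _, _ = synth_splits
    return pb.PDDClassifier().fit(train)


@pytest.fixture(scope="session")
def reference_model(synth_splits):
    train, _, _ = synth_splits
    return pb.train_reference_classifier(train, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
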