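import numpy as np
import pytest

from trialcease.ctgov_io import TrialRecord
from trialcease.structured_features import default_drug_class_map
from trialcease.synthetic_corpus import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def class_map():
    return default_drug_class_map()


@pytest.fixture(scope="session")
def small_corpus():
    """A 240-trial seeded synthetic cohort shared by cheap tests."""
    config = GeneratorConfig(n_trials=240, seed=7)
    records, labels = generate_corpus(config)
    y = np.array([int(label == "CESSATION") for label in labels])
    return records, labels, y


def make_record(**kwargs) -> TrialRecord:
    defaults = dict(trial_id="NCT00000001", overall_status="Completed")
    defaults.update(kwargs)
    return TrialRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record
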