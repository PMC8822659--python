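import pytest

from tfscout.classifier import ModelConfig, train
from tfscout.database import merge_and_curate
from tfscout.features import AlignerParams
from tfscout.simulate import FamilySpec, generate_family_set


@pytest.fixture(scope="session")
def aligner_params():
    return AlignerParams()


@pytest.fixture(scope="session")
def small_records():
    """Three mutated-ancestor families, 8 members each, 80 aa, 5% rate."""
    specs = [
        FamilySpec("FamA", 8, 80, 0.05),
        FamilySpec("FamB", 8, 80, 0.05),
        FamilySpec("FamC", 8, 80, 0.05),
    ]
    return generate_family_set(specs, seed=1)


@pytest.fixture(scope="session")
def small_db(small_records):
    return merge_and_curate([small_records])


@pytest.fixture(scope="session")
def small_model(small_db):
    return train(small_db, ModelConfig(epochs=120, seed=42))
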