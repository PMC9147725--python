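import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from myrmitox.pipeline import run_pipeline
from myrmitox.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def study_config():
    """High-signal study conditions: 10x gland enrichment, 10% template
    mutation, well-separated target/decoy PSM scores, fixed seed."""
    return SimConfig(n_background=60, n_reads=1000, seed=2022)


@pytest.fixture(scope="session")
def study_dataset(study_config):
    return generate_dataset(study_config)


@pytest.fixture(scope="session")
def study_result(study_dataset):
    return run_pipeline(study_dataset)
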