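import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from prophage_census import default_config, run_all
from prophage_census.pipeline import PipelineResult


@pytest.fixture(scope="session")
def default_result() -> PipelineResult:
    """The default synthetic survey (3 species x 5 genomes, planted count
    medians {3, 1, 0}) run through the whole pipeline once per session."""
    return run_all(default_config(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
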