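import numpy as np
import pytest

from rubisco_prospector.plate import AssayConfig
from rubisco_prospector.records import ProteinRecord


@pytest.fixture
def assay_config() -> AssayConfig:
    return AssayConfig(epsilon_eff=1800.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture
def bait(rng) -> ProteinRecord:
    return ProteinRecord(id="bait", sequence=random_protein(rng, 400))
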