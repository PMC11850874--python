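import pytest

from cwqsar import CorrelationWeightQSAR, GeneratorSpec, generate_library

CHALCONE = "O=C(C=Cc1ccccc1)c1ccccc1"


@pytest.fixture(scope="session")
def chalcone():
    return CHALCONE


@pytest.fixture(scope="session")
def small_library():
    """Compact noise-free library with a single strong planted effect."""
    spec = GeneratorSpec(
        n_compounds=60,
        effects={"NMe2": -1.2, "OCH3": 0.5},
        noise_sd=0.0,
        seed=7,
    )
    return spec, generate_library(spec)


@pytest.fixture(scope="session")
def small_model(small_library):
    _, lib = small_library
    return CorrelationWeightQSAR.from_dataframe(lib, seed=7)


@pytest.fixture(scope="session")
def default_library():
    """The study-geometry library: 190 compounds, noise SD 0.15."""
    spec = GeneratorSpec(seed=1)
    return spec, generate_library(spec)
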