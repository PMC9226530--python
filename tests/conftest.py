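import numpy as np
import pytest

from ahyflex import (
    AnnotatedDuplex,
    Modification,
    IntraBpParameters,
    StepParameters,
)
from ahyflex.ensemble import REFERENCE_FRAGMENT


@pytest.fixture(scope="session")
def printed_fragment() -> str:
    """Top strand of the 25-bp duplex used throughout (CpG sites at 8, 16)."""
    return REFERENCE_FRAGMENT


@pytest.fixture
def duplex_c(printed_fragment) -> AnnotatedDuplex:
    return AnnotatedDuplex(printed_fragment, name="C")


@pytest.fixture
def duplex_ahycx4(printed_fragment) -> AnnotatedDuplex:
    return AnnotatedDuplex(
        printed_fragment,
        [Modification(8, "top", "ahy"), Modification(9, "bottom", "ahy"),
         Modification(16, "top", "ahy"), Modification(17, "bottom", "ahy")],
        name="ahyCx4",
    )


@pytest.fixture
def duplex_ahycx2(printed_fragment) -> AnnotatedDuplex:
    return AnnotatedDuplex(
        printed_fragment,
        [Modification(8, "top", "ahy"), Modification(16, "top", "ahy")],
        name="ahyCx2",
    )


def random_plausible_parameters(rng: np.random.Generator, length: int):
    """B-DNA-plausible random parameter draw for round-trip tests."""
    intra = [IntraBpParameters(*rng.uniform(-0.5, 0.5, 3), *rng.uniform(-10, 10, 3),
                               bp_index=i) for i in range(1, length + 1)]
    step = [StepParameters(rng.uniform(-2, 2), rng.uniform(-2, 2), rng.uniform(2.8, 4.0),
                           rng.uniform(-15, 15), rng.uniform(-15, 15), rng.uniform(25, 45),
                           step_index=i) for i in range(1, length)]
    return intra, step
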