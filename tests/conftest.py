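import numpy as np
import pytest

from cambiokit import load_preset, make_cell_files, render_section
from cambiokit.synthetic_cambium import GeneratorPreset
from cambiokit.fate_simulator import FateParams


def binomial_3sigma(p: float, n: int) -> float:
    return 3.0 * np.sqrt(p * (1.0 - p) / n)


@pytest.fixture(scope="session")
def col0_mock():
    return load_preset("col0_mock")


@pytest.fixture
def point_mass_preset():
    """Degenerate preset: gradient always ends at -1, ANT on both daughters."""
    return GeneratorPreset(
        name="point_mass",
        end_position_probs={"-1": 1.0},
        spread_probs={"both_daughters": 1.0},
        edu_probs={"overlap_ant": 1.0},
        fate=FateParams(q_x=0.5, q_p=0.5),
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_section(col0_mock):
    """A noise-free 16-wedge rendered section with ground truth attached."""
    files = make_cell_files(col0_mock, 16, rng_seed=1234)
    return render_section(files, noise_sd=0.0, rng_seed=0)
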