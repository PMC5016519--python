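import numpy as np
import pytest
from hypothesis import settings

import locquant as lq

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def region5um() -> lq.Region:
    """The standard 5x5 um^2 analysis window."""
    return lq.Region.square(5000.0)


@pytest.fixture
def small_table() -> lq.LocalizationTable:
    rng = np.random.default_rng(11)
    n = 50
    return lq.LocalizationTable.from_arrays(
        rng.uniform(0, 5000, n), rng.uniform(0, 5000, n),
        rng.integers(0, 1000, n), rng.uniform(500, 2000, n))


@pytest.fixture(scope="session")
def reference_scenes():
    """Diluted blinking scenes shared by the calibration-recovery tests.

    Sixteen independent 5x5 um^2 scenes at 2 fluorophores/um^2, ~5
    blinks each (conditioned >= 1), 8 nm precision, 20,000 frames --
    the reference-sample regime.
    """
    region = lq.Region.square(5000.0)
    rng = np.random.default_rng(2026)
    tables, truths = [], []
    for _ in range(16):
        t, tr = lq.simulate_blinking_scene(2.0, 5.0, 8.0, 20_000, region, rng)
        tables.append(t)
        truths.append(tr)
    return tables, truths


@pytest.fixture(scope="session")
def reference_fit(reference_scenes):
    """Blink calibration fitted once to the shared reference scenes."""
    tables, _ = reference_scenes
    return lq.BlinkCalibrationModel(tables).fit()
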