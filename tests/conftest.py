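import numpy as np
import pandas as pd
import pytest

from odorhab.curves import CurveSet
from odorhab.datasets import load_table1
from odorhab.simulate import CohortConfig, GenerativeTruth, generate_cohort


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact clean cohort (8 subjects, 32 odorants, no contamination)."""
    config = CohortConfig(
        n_subjects=8, n_absent_subjects=0, n_chaotic_subjects=0, n_delayed_curves=0
    )
    truth = GenerativeTruth(seed=7)
    return generate_cohort(config, truth)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-pattern cohort: 58 recruited, 3 absent, 5 chaotic, 69 delayed."""
    return generate_cohort(CohortConfig(), GenerativeTruth(seed=11))


def make_curves(values, dt=0.25, start_level=60.0, subjects=None, odorants=None):
    """Build a CurveSet from a raw value matrix for hand-made test cases."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    subjects = subjects if subjects is not None else [f"s{i}" for i in range(n)]
    odorants = odorants if odorants is not None else ["odo"] * n
    index = pd.DataFrame({"subject_id": subjects, "odorant_id": odorants})
    times = np.arange(values.shape[1]) * dt
    return CurveSet(index=index, values=values, times=times, start_level=start_level)
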