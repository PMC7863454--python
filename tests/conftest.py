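import numpy as np
import pandas as pd
import pytest

from gestimpute import WeightDataset


def make_dataset(rows, covariates=None, scale="natural"):
    """Dataset from (subject_id, gest_week, weight) tuples."""
    frame = pd.DataFrame(rows, columns=["subject_id", "gest_week", "weight"])
    return WeightDataset(frame, covariates=covariates, scale=scale)


@pytest.fixture
def tiny_dataset():
    return make_dataset(
        [
            ("S1", 16.0, 60.0),
            ("S1", 20.0, 62.0),
            ("S2", 14.0, 58.0),
            ("S2", 18.0, 59.5),
            ("S2", 22.0, 61.0),
        ]
    )


@pytest.fixture
def linear_cohort():
    """5 subjects, 4 visits each, exactly linear with distinct lines."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(5):
        a, b = 50.0 + 3.0 * i, 0.3 + 0.08 * i
        for t in (10.0, 16.0, 22.0, 28.0):
            rows.append((f"P{i}", t, a + b * t))
    return make_dataset(rows), [(f"P{i}", 50.0 + 3.0 * i, 0.3 + 0.08 * i) for i in range(5)]


@pytest.fixture
def common_slope_cohort():
    """Subjects offset from one shared line, identical visit grids."""
    rows = []
    slope = 0.4
    for i, a in enumerate((48.0, 52.0, 55.0, 61.0, 66.0, 70.0)):
        for t in (10.0, 16.0, 22.0, 28.0, 34.0):
            rows.append((f"C{i}", t, a + slope * t))
    return make_dataset(rows), slope
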