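import numpy as np
import pandas as pd
import pytest

from tugait import CohortTable, SignalSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_recording_csv(tmp_path):
    """Write x/y/z columns to a CSV file and return its path."""

    def _write(x, y, z, name="rec.csv", headers=("x", "y", "z")):
        path = tmp_path / name
        pd.DataFrame({headers[0]: x, headers[1]: y, headers[2]: z}).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def small_cohort_table():
    """Four-subject cohort with two features and clean group separation."""
    return CohortTable(
        pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "group": ["faller", "faller", "non_faller", "non_faller"],
                "feat1": [1.0, 2.0, 3.0, 4.0],
                "feat2": [0.5, 0.1, -0.3, 0.0],
            }
        )
    )


@pytest.fixture
def default_recording():
    """One deterministic synthetic recording with its ground truth."""
    spec = SignalSpec(lead_s=3.0, trail_s=3.0, seed=7, group="non_faller")
    rec, truth = generate_recording(spec)
    return rec, truth, spec
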