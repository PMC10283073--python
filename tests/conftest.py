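import numpy as np
import pytest

from irdose import (
    Dataset,
    OutcomeCategory,
    TrialRecord,
    default_truth,
    replicate_design,
)


@pytest.fixture(scope="session")
def powers_60s() -> np.ndarray:
    return replicate_design(60).powers()


@pytest.fixture(scope="session")
def truth_60s():
    return default_truth(60)


@pytest.fixture(scope="session")
def truth_1s():
    return default_truth(1)


def make_dataset(rows) -> Dataset:
    """Build a Dataset from (power, outcome[, cell_size]) tuples at 60 s."""
    records = []
    for i, row in enumerate(rows):
        power, outcome = row[0], row[1]
        size = row[2] if len(row) > 2 else None
        records.append(
            TrialRecord(
                trial_id=f"t{i}",
                power=float(power),
                duration=60.0,
                cell_size=size,
                outcome=OutcomeCategory(outcome),
            )
        )
    return Dataset(records=records)


@pytest.fixture
def six_category_dataset() -> Dataset:
    rows = [
        (6.0, "NONE", 2500.0),
        (8.5, "TARGET_ONLY", 3100.0),
        (11.0, "TARGET_AND_NEIGHBOR", None),
        (12.5, "NEIGHBOR_ONLY", 4100.0),
        (16.0, "DEATH_TARGET", 1800.0),
        (19.0, "DEATH_AND_EXPRESSION", 3600.0),
    ]
    return make_dataset(rows)
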