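import numpy as np
import pytest

from platesort import (
    PlateScenario,
    generate_plate,
    generate_training_pair,
    normalize,
    plate_from_records,
    summarize_plate,
)


@pytest.fixture
def small_plate():
    """A tiny hand-built plate with known values in three wells."""
    records = [
        {"well": "A1", "tof": 10.0, "ext": 5.0, "green": 1.0, "yellow": 2.0, "red": 3.0},
        {"well": "A1", "tof": 20.0, "ext": 8.0, "green": 1.5, "yellow": 2.5, "red": 3.5},
        {"well": "A1", "tof": 30.0, "ext": 12.0, "green": 2.0, "yellow": 3.0, "red": 4.0},
        {"well": "B2", "tof": 100.0, "ext": 50.0, "green": 5.0, "yellow": 6.0, "red": 7.0},
        {"well": "H12", "tof": 0.0, "ext": 7.0, "green": 0.0, "yellow": 0.0, "red": 0.0},
    ]
    return plate_from_records(records, source="small-fixture")


@pytest.fixture(scope="session")
def contaminated_plate():
    """Synthetic plate with 10% bubbles and two empty wells, plus truth."""
    scenario = PlateScenario(seed=101, bubble_fraction=0.10, empty_wells=("C3", "F8"))
    return generate_plate(scenario)


@pytest.fixture(scope="session")
def training_pair():
    """Well-separated organism/bubble plates (two-plate protocol), 500 each."""
    return generate_training_pair(PlateScenario(seed=202), n_each=500)


@pytest.fixture(scope="session")
def summarized_plate():
    """Normalized and summarized synthetic plate, 96 populated wells."""
    plate, _ = generate_plate(PlateScenario(seed=303))
    return summarize_plate(normalize(plate))


def random_plate(rng: np.random.Generator, n_wells: int = 12, n_per_well: int = 8):
    """Small random plate for oracle-equivalence sweeps (fast to build)."""
    from platesort.wells import ALL_WELL_LABELS

    wells = rng.choice(ALL_WELL_LABELS, size=n_wells, replace=False)
    records = []
    for w in wells:
        n = rng.integers(1, n_per_well + 1)
        for _ in range(n):
            records.append(
                {
                    "well": str(w),
                    "tof": float(rng.gamma(4.0, 60.0)),
                    "ext": float(rng.gamma(3.0, 40.0)),
                    "green": float(rng.gamma(2.0, 10.0)),
                    "yellow": float(rng.gamma(2.0, 8.0)),
                    "red": float(rng.gamma(2.0, 5.0)),
                }
            )
    return plate_from_records(records, source="random-fixture")
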