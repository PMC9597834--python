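import datetime as dt

import pytest

from gwforage.synthetic import SimulationConfig, generate_dataset
from gwforage.transects import TransectRecord, WhaleObservation


@pytest.fixture(scope="session")
def default_dataset():
    """One full 20-season synthetic dataset shared across tests."""
    return generate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def annual_summaries(default_dataset):
    from gwforage.transects import summarize_seasons

    return summarize_seasons(default_dataset.transects)


def make_transect(year, day_offsets_counts, season_start=(5, 24)):
    """Build a year's TransectRecords from (day-offset, count) pairs."""
    start = dt.date(year, *season_start)
    records = []
    for i, (off, count) in enumerate(day_offsets_counts):
        date = start + dt.timedelta(days=off)
        units = tuple(
            WhaleObservation(
                timestamp=dt.datetime.combine(date, dt.time(hour=10)),
                lat=49.25,
                lon=-126.15,
            )
            for _ in range(count)
        )
        records.append(
            TransectRecord(transect_id=f"{year}-T{i:02d}", date=date, units=units)
        )
    return records
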