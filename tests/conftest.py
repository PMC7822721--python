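import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chronocall import (
    CallRecordSet,
    PopulationConfig,
    generate_population,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic cohort: 11 morning + 10 evening always-active
    persons and 5 partial persons over 12 months."""
    config = PopulationConfig(seed=20150101)
    records, truth = generate_population(config)
    return records, truth


def make_records(rows) -> CallRecordSet:
    """Build a CallRecordSet from (person, iso_timestamp, direction) or
    (person, iso_timestamp, direction, duration) tuples."""
    frame = pd.DataFrame(
        {
            "person_id": [r[0] for r in rows],
            "timestamp": pd.to_datetime([r[1] for r in rows]),
            "recipient_id": "c1",
            "direction": [r[2] for r in rows],
            "duration_s": [float(r[3]) if len(r) > 3 else 60.0 for r in rows],
            "device_id": np.nan,
        }
    )
    return CallRecordSet(frame)
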