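import numpy as np
import pandas as pd
import pytest

from cascadeflow import from_frame


@pytest.fixture
def simple_events():
    """Three numeric-time events, no case column."""
    return from_frame(pd.DataFrame({"Time": [5.0, 7.0, 10.0]}))


@pytest.fixture
def two_case_events():
    """Two cases with per-case anchored relative times."""
    return from_frame(
        pd.DataFrame(
            {
                "Time": [10.0, 12.0, 100.0, 103.0],
                "Case": ["A", "A", "B", "B"],
                "EventType": ["TRN", "EQ", "COM", "TRN"],
            }
        )
    )


@pytest.fixture
def table1_counts():
    """Published per-type (in-cascade, total) disruption counts."""
    return {
        "TRN": (117, 376),
        "COM": (64, 278),
        "ENV": (4, 18),
        "SDM": (32, 148),
        "IC": (26, 126),
        "EQ": (90, 460),
        "PF": (11, 58),
        "COO": (71, 385),
        "EXT": (13, 125),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
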