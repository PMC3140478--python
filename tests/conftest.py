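import numpy as np
import pandas as pd
import pytest

from vervetnet.core import (
    DyadicOccurrence,
    EventLog,
    PresenceMatrix,
    Roster,
    assign_sampling_periods,
)


@pytest.fixture
def small_roster():
    """Seven individuals, two of them in the small cooperation class."""
    ids = [f"V{i}" for i in range(1, 8)]
    table = pd.DataFrame(
        {
            "sex": ["M", "F", "M", "F", "M", "F", "M"],
            "age_class": ["adult", "juvenile", "adult", "adult",
                          "juvenile", "adult", "juvenile"],
            "coop_class": ["small", "large", "large", "large",
                           "large", "large", "small"],
            "matriline": ["A", "A", "B", "B", "B", "A", "B"],
            "group": ["G"] * 7,
        },
        index=pd.Index(ids, name="id"),
    )
    sibs = {i: frozenset() for i in ids}
    sibs["V1"] = frozenset({"V2"})
    sibs["V2"] = frozenset({"V1"})
    return Roster(table, sibs)


def make_event_df(rows):
    """Event-log DataFrame from (date, time_s, kind, behaviour, actor,
    recipient, nn_m, feeder_m) tuples, with periods assigned."""
    df = pd.DataFrame(
        rows,
        columns=[
            "date",
            "time_s",
            "kind",
            "behaviour",
            "actor",
            "recipient",
            "neighbour_distance_m",
            "feeder_distance_m",
        ],
    )
    return assign_sampling_periods(df)


@pytest.fixture
def event_df_factory():
    return make_event_df


def occurrence_from_arrays(x, presence_values, ids=None):
    x = np.asarray(x)
    n = x.shape[1]
    ids = ids or [f"I{k}" for k in range(n)]
    presence = PresenceMatrix(list(ids), np.asarray(presence_values))
    return DyadicOccurrence(list(ids), x, presence)


@pytest.fixture
def occ_factory():
    return occurrence_from_arrays
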