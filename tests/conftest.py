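"""Shared fixtures: tiny hand-built checklist tables and random generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def make_checklists(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical checklist table from terse row dicts."""
    defaults = {
        "group_id": None,
        "date": "2015-06-15",
        "latitude": 45.5,
        "longitude": -69.5,
        "state": "US-ME",
        "county": "Piscataquis",
        "count_type": "Traveling",
        "complete": True,
        "duration_hours": 1.0,
        "distance_km": 2.0,
        "observer_id": "obs1",
    }
    records = []
    for row in rows:
        record = {**defaults, **row}
        records.append(record)
    frame = pd.DataFrame(records)
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


def make_observations(rows: list[tuple]) -> pd.DataFrame:
    """(checklist_id, species, count) triples to an observation table."""
    return pd.DataFrame(
        [
            {
                "checklist_id": cid,
                "species": species,
                "count": count,
                "presence_only": False,
            }
            for cid, species, count in rows
        ],
        columns=["checklist_id", "species", "count", "presence_only"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160731)


@pytest.fixture
def small_dataset():
    """Three checklists, two with a focal record, one group pair."""
    checklists = make_checklists(
        [
            {"checklist_id": "S001"},
            {"checklist_id": "S002", "group_id": "G1", "latitude": 45.6},
            {"checklist_id": "S003", "group_id": "G1", "latitude": 45.6},
        ]
    )
    observations = make_observations(
        [
            ("S001", "fox_sparrow", 2),
            ("S002", "fox_sparrow", 1),
            ("S002", "blackpoll_warbler", 3),
        ]
    )
    return checklists, observations
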