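"""Reading, writing and zero-filling eBird-style checklist data.

The eBird Basic Dataset (EBD) and its derivatives ship as tab-delimited text
with one row per species observation; checklist-level metadata (location,
date, protocol, effort) is repeated on every row of the same sampling event.
This module parses that layout into two tidy tables:

* a **checklist** table with one row per sampling event, and
* an **observation** table with one row per (checklist, species) record,

and expands them into a **zero-filled detection table** in which every
(checklist, species-of-interest) pair carries an explicit present/absent
record — the prerequisite for treating complete checklists as evidence of
absence.

Column names differ between EBD versions, so the mapping from logical field
to column header is a configurable :class:`Dialect` rather than a constant.
Durations are stored internally in hours (the EBD ships minutes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical columns of a checklist table, one row per sampling event.
CHECKLIST_COLUMNS = [
    "checklist_id",
    "group_id",
    "date",
    "latitude",
    "longitude",
    "state",
    "county",
    "count_type",
    "complete",
    "duration_hours",
    "distance_km",
    "observer_id",
]

#: Canonical columns of an observation table.
OBSERVATION_COLUMNS = ["checklist_id", "species", "count", "presence_only"]

#: Canonical columns of a zero-filled detection table.
DETECTION_COLUMNS = ["checklist_id", "species", "present", "count"]


class MalformedRowError(ValueError):
    """A data row failed validation; the message lists offending line numbers."""


class DialectError(KeyError):
    """A required logical field has no matching column in the input file."""


@dataclass(frozen=True)
class Dialect:
    """Mapping from logical checklist fields to physical column headers.

    Defaults match current EBD headers.  ``duration`` is interpreted in
    minutes and converted to hours at parse time.  Optional fields whose
    column is absent from a file are filled with missing values rather than
    raising.
    """

    checklist_id: str = "SAMPLING EVENT IDENTIFIER"
    group_id: str = "GROUP IDENTIFIER"
    date: str = "OBSERVATION DATE"
    latitude: str = "LATITUDE"
    longitude: str = "LONGITUDE"
    state: str = "STATE CODE"
    county: str = "COUNTY"
    count_type: str = "PROTOCOL TYPE"
    complete: str = "ALL SPECIES REPORTED"
    duration_minutes: str = "DURATION MINUTES"
    distance_km: str = "EFFORT DISTANCE KM"
    observer_id: str = "OBSERVER ID"
    species: str = "COMMON NAME"
    count: str = "OBSERVATION COUNT"

    #: logical fields that must be present in the header
    REQUIRED = (
        "checklist_id",
        "date",
        "latitude",
        "longitude",
        "count_type",
        "complete",
        "duration_minutes",
    )

    def with_overrides(self, **overrides: str) -> "Dialect":
        return replace(self, **overrides)


DEFAULT_DIALECT = Dialect()

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"}


def _parse_bool(values: pd.Series) -> pd.Series:
    low = values.astype(str).str.strip().str.lower()
    out = pd.Series(pd.NA, index=values.index, dtype="boolean")
    out[low.isin(_TRUE_STRINGS)] = True
    out[low.isin(_FALSE_STRINGS)] = False
    return out


def read_checklists(
    path,
    dialect: Dialect | None = None,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse an EBD-style TSV into (checklists, observations) tables.

    Parameters
    ----------
    path
        Tab-separated UTF-8 file with a header row.  Rows with embedded
        tabs shift fields and are rejected by the parser.
    dialect
        Column-name mapping; defaults to current EBD headers.
    on_error
        ``"raise"`` (default) aborts with a :class:`MalformedRowError`
        naming the bad data lines; ``"skip"`` drops bad rows after logging
        each with its line number.

    Returns
    -------
    checklists : DataFrame
        One row per distinct sampling-event identifier, with the columns in
        :data:`CHECKLIST_COLUMNS`; duration converted from minutes to hours.
    observations : DataFrame
        One row per species record, with the columns in
        :data:`OBSERVATION_COLUMNS`.  Presence-only records (count "X")
        get ``count=1`` and ``presence_only=True``.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    dialect = dialect or DEFAULT_DIALECT

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in Dialect.REQUIRED:
        column = getattr(dialect, logical)
        if column not in raw.columns:
            raise DialectError(
                f"required column {column!r} (logical field {logical!r}) "
                f"missing from {path}"
            )
    if raw.empty:
        return (
            pd.DataFrame(columns=CHECKLIST_COLUMNS),
            pd.DataFrame(columns=OBSERVATION_COLUMNS),
        )

    def col(logical: str, default: str = "") -> pd.Series:
        column = getattr(dialect, logical)
        if column in raw.columns:
            return raw[column].str.strip()
        return pd.Series(default, index=raw.index)

    # header is line 1, first data row is line 2
    lines = raw.index.to_numpy() + 2
    errors: list[str] = []
    bad = np.zeros(len(raw), dtype=bool)

    date = pd.to_datetime(col("date"), format="%Y-%m-%d", errors="coerce")
    lat = pd.to_numeric(col("latitude"), errors="coerce")
    lon = pd.to_numeric(col("longitude"), errors="coerce")
    dur_min = pd.to_numeric(col("duration_minutes"), errors="coerce")
    dist = pd.to_numeric(col("distance_km"), errors="coerce")
    complete = _parse_bool(col("complete"))

    checks = [
        (date.isna(), "unparseable date"),
        (lat.isna() | (lat < -90) | (lat > 90), "invalid latitude"),
        (lon.isna() | (lon < -180) | (lon > 180), "invalid longitude"),
        (dur_min.isna() | (dur_min < 0), "invalid duration"),
        (complete.isna().to_numpy(), "invalid completeness flag"),
    ]
    for mask, label in checks:
        mask = np.asarray(mask, dtype=bool)
        for line in lines[mask & ~bad]:
            errors.append(f"line {line}: {label}")
        bad |= mask

    if errors:
        message = "; ".join(errors[:20]) + ("" if len(errors) <= 20 else " ...")
        if on_error == "raise":
            raise MalformedRowError(f"{len(errors)} malformed row(s): {message}")
        logger.warning("skipping %d malformed row(s): %s", len(errors), message)

    keep = ~bad
    frame = pd.DataFrame(
        {
            "checklist_id": col("checklist_id"),
            "group_id": col("group_id").replace("", pd.NA),
            "date": date,
            "latitude": lat,
            "longitude": lon,
            "state": col("state"),
            "county": col("county"),
            "count_type": col("count_type"),
            "complete": complete,
            "duration_hours": dur_min / 60.0,
            "distance_km": dist,
            "observer_id": col("observer_id"),
            "species": col("species"),
            "count_raw": col("count"),
        }
    )[keep]

    checklists = (
        frame[CHECKLIST_COLUMNS]
        .drop_duplicates("checklist_id", keep="first")
        .reset_index(drop=True)
    )
    checklists["complete"] = checklists["complete"].astype(bool)

    obs = frame[frame["species"] != ""][["checklist_id", "species", "count_raw"]]
    presence_only = obs["count_raw"].str.upper().eq("X")
    counts = pd.to_numeric(obs["count_raw"].where(~presence_only, "1"), errors="coerce")
    if (counts.dropna() < 1).any():
        raise MalformedRowError("observation counts must be >= 1")
    observations = pd.DataFrame(
        {
            "checklist_id": obs["checklist_id"],
            "species": obs["species"],
            "count": counts.fillna(1).astype(int),
            "presence_only": presence_only.to_numpy(),
        }
    ).reset_index(drop=True)
    return checklists, observations


def write_checklists(
    checklists: pd.DataFrame,
    observations: pd.DataFrame,
    path,
    dialect: Dialect | None = None,
) -> None:
    """Serialize (checklists, observations) back to EBD-style TSV.

    Emits one row per observation; checklists with no observations get a
    single row with an empty species field so they survive a round trip.
    """
    dialect = dialect or DEFAULT_DIALECT
    merged = checklists.merge(
        observations[["checklist_id", "species", "count", "presence_only"]],
        on="checklist_id",
        how="left",
    )
    count_str = merged["count"].astype("string")
    presence_only = merged["presence_only"].astype("boolean").fillna(False)
    count_str = count_str.where(~presence_only, "X")
    out = pd.DataFrame(
        {
            dialect.checklist_id: merged["checklist_id"],
            dialect.group_id: merged["group_id"].fillna(""),
            dialect.date: merged["date"].dt.strftime("%Y-%m-%d"),
            dialect.latitude: merged["latitude"],
            dialect.longitude: merged["longitude"],
            dialect.state: merged["state"],
            dialect.county: merged["county"],
            dialect.count_type: merged["count_type"],
            dialect.complete: merged["complete"].astype(int),
            dialect.duration_minutes: merged["duration_hours"] * 60.0,
            dialect.distance_km: merged["distance_km"],
            dialect.observer_id: merged["observer_id"],
            dialect.species: merged["species"].fillna(""),
            dialect.count: count_str.fillna(""),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def zero_fill(
    checklists: pd.DataFrame,
    observations: pd.DataFrame,
    species_list: list[str],
) -> pd.DataFrame:
    """Expand observations into an explicit detection/nondetection table.

    Every (checklist, species) pair for the given species list gets exactly
    one row; a species is marked present on a checklist iff at least one
    observation of it exists there, and absent (count 0) otherwise.
    Duplicate observations of the same species on one checklist are merged
    by summing counts, with a warning.

    Returns a DataFrame with columns ``checklist_id, species, present,
    count`` and ``len(checklists) * len(species_list)`` rows.
    """
    if len(species_list) == 0:
        raise ValueError("species_list must be non-empty")
    if len(set(species_list)) != len(species_list):
        raise ValueError("species_list contains duplicates")

    ids = checklists["checklist_id"].to_numpy()
    id_index = pd.Index(ids)
    row = id_index.get_indexer(observations["checklist_id"])
    if (row < 0).any():
        unknown = sorted(set(observations["checklist_id"].to_numpy()[row < 0]))
        raise ValueError(
            f"observations reference unknown checklist(s): {unknown[:5]}"
        )

    n, s = len(ids), len(species_list)
    column = pd.Index(species_list).get_indexer(observations["species"])
    listed = column >= 0
    row, column = row[listed], column[listed]
    flat = row * s + column
    counts = np.bincount(flat, weights=observations["count"].to_numpy()[listed], minlength=n * s)
    hits = np.bincount(flat, minlength=n * s)
    if (hits > 1).any():
        logger.warning(
            "merging %d duplicate observation(s) of the same species on one "
            "checklist by summing counts",
            int((hits - 1)[hits > 1].sum()),
        )
    return pd.DataFrame(
        {
            "checklist_id": np.repeat(ids, s),
            "species": np.tile(np.asarray(species_list, dtype=object), n),
            "present": hits > 0,
            "count": counts.astype(int),
        }
    )


def write_detection_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a zero-filled detection table to delimited text."""
    table[DETECTION_COLUMNS].to_csv(path, sep=sep, index=False)


def read_detection_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a detection table written by :func:`write_detection_table`."""
    table = pd.read_csv(
        path,
        sep=sep,
        dtype={"checklist_id": str, "species": str, "count": int},
    )
    table["present"] = table["present"].astype(bool)
    return table[DETECTION_COLUMNS]
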