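"""Seasonal, regional, protocol, completeness and group-deduplication filters.

Citizen-science checklist extracts need bespoke cleaning before occupancy
analysis: restrict to the breeding-season window so migrants drop out, keep
only counties covering the habitat of interest, drop survey protocols that
cannot detect the focal species (yard and pelagic counts), require complete
checklists so nondetections are informative, and collapse group checklists
(several observers sharing one birding event) to a single record.

Filters are pure set-reducing functions on a checklist DataFrame.
:func:`apply_filters` runs them in a fixed order — completeness, season,
region, protocol, then group deduplication — and returns a
:class:`FilterReport` whose per-stage counts reconcile exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Breeding-season months used by default (June and July).
DEFAULT_MONTHS = frozenset({6, 7})

#: Default study region: counties spanning the northern halves of Maine and
#: New Hampshire.
DEFAULT_REGION = (
    ("US-ME", "Aroostook"),
    ("US-ME", "Penobscot"),
    ("US-ME", "Piscataquis"),
    ("US-ME", "Somerset"),
    ("US-ME", "Franklin"),
    ("US-ME", "Oxford"),
    ("US-NH", "Coos"),
    ("US-NH", "Grafton"),
)

#: Survey protocols incompatible with detecting a breeding songbird.
DEFAULT_EXCLUDED_COUNT_TYPES = (
    "Yard Count",
    "Loon Watch",
    "My Yard eBird",
    "Pelagic",
)


@dataclass(frozen=True)
class FilterSpec:
    """Configuration of the filtering pipeline.

    Defaults reproduce the standard breeding-season analysis: June-July,
    the eight northern Maine / New Hampshire counties, the four excluded
    protocols, complete checklists only, group deduplication on.
    """

    months: frozenset = DEFAULT_MONTHS
    region: tuple = DEFAULT_REGION
    excluded_count_types: tuple = DEFAULT_EXCLUDED_COUNT_TYPES
    require_complete: bool = True
    dedup: bool = True

    def __post_init__(self):
        months = frozenset(int(m) for m in self.months)
        if not months or not months <= set(range(1, 13)):
            raise ValueError("months must be a non-empty subset of 1..12")
        object.__setattr__(self, "months", months)
        object.__setattr__(
            self, "region", tuple((s, c) for s, c in self.region)
        )
        object.__setattr__(
            self, "excluded_count_types", tuple(self.excluded_count_types)
        )

    def to_dict(self) -> dict:
        return {
            "months": sorted(self.months),
            "region": [list(pair) for pair in self.region],
            "excluded_count_types": list(self.excluded_count_types),
            "require_complete": self.require_complete,
            "dedup": self.dedup,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FilterSpec":
        kwargs = {}
        if "months" in data:
            kwargs["months"] = frozenset(data["months"])
        if "region" in data:
            kwargs["region"] = tuple(tuple(pair) for pair in data["region"])
        if "excluded_count_types" in data:
            kwargs["excluded_count_types"] = tuple(data["excluded_count_types"])
        for key in ("require_complete", "dedup"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "FilterSpec":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class FilterReport:
    """Per-stage bookkeeping of checklists removed and retained.

    Invariant: ``retained`` after stage k equals ``retained`` after stage
    k-1 minus ``removed`` at stage k, so no checklist goes unaccounted.
    """

    n_input: int = 0
    stages: list = field(default_factory=list)

    def add_stage(self, stage: str, removed: int, retained: int, **extra) -> None:
        self.stages.append(
            {"stage": stage, "removed": int(removed), "retained": int(retained), **extra}
        )
        logger.info("filter stage %-12s removed %6d retained %7d", stage, removed, retained)

    @property
    def n_output(self) -> int:
        return self.stages[-1]["retained"] if self.stages else self.n_input

    def reconciles(self) -> bool:
        previous = self.n_input
        for stage in self.stages:
            if stage["retained"] != previous - stage["removed"]:
                return False
            previous = stage["retained"]
        return True

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_output": self.n_output, "stages": self.stages},
            sort_keys=True,
            **kwargs,
        )


def _month_of(checklists: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(checklists["date"]).dt.month


def filter_window(checklists: pd.DataFrame, months) -> pd.DataFrame:
    """Keep checklists whose calendar month falls in ``months``."""
    months = set(int(m) for m in months)
    if not months <= set(range(1, 13)):
        raise ValueError("months must be within 1..12")
    return checklists[_month_of(checklists).isin(months)]


def _normalized_codes(series: pd.Series):
    """Factorize a low-cardinality string column, normalizing distinct values only."""
    codes, uniques = pd.factorize(series.fillna("").astype(str))
    normed = [value.strip().casefold() for value in uniques]
    return codes, normed


def filter_region(checklists: pd.DataFrame, region) -> pd.DataFrame:
    """Keep checklists whose (state, county) pair is in ``region``.

    Comparison is case-insensitive after trimming whitespace; checklists
    with a missing county are removed (counted separately by
    :func:`apply_filters`).
    """
    wanted = {(s.strip().casefold(), c.strip().casefold()) for s, c in region}
    if not wanted:
        raise ValueError("region must be non-empty")
    state_codes, state_values = _normalized_codes(checklists["state"])
    county_codes, county_values = _normalized_codes(checklists["county"])
    pair_code = state_codes.astype(np.int64) * max(1, len(county_values)) + county_codes
    allowed = [
        i * max(1, len(county_values)) + j
        for i, state in enumerate(state_values)
        for j, county in enumerate(county_values)
        if (state, county) in wanted
    ]
    mask = np.isin(pair_code, allowed)
    return checklists[pd.Series(mask, index=checklists.index)]


def _protocol_counts(checklists: pd.DataFrame, excluded) -> dict:
    """Number of checklists per excluded protocol (exact match after trimming)."""
    codes, uniques = pd.factorize(checklists["count_type"].fillna("").astype(str))
    trimmed = [value.strip() for value in uniques]
    tallies = np.bincount(codes, minlength=len(uniques))
    return {
        name: int(
            sum(t for t, value in zip(tallies, trimmed) if value == name.strip())
        )
        for name in excluded
    }


def filter_protocols(checklists: pd.DataFrame, excluded) -> pd.DataFrame:
    """Drop checklists whose count type exactly matches an excluded protocol."""
    wanted = {name.strip() for name in excluded}
    codes, uniques = pd.factorize(checklists["count_type"].fillna("").astype(str))
    drop = [i for i, value in enumerate(uniques) if value.strip() in wanted]
    mask = ~np.isin(codes, drop)
    return checklists[pd.Series(mask, index=checklists.index)]


def require_complete(checklists: pd.DataFrame) -> pd.DataFrame:
    """Keep only complete checklists (all species reported)."""
    return checklists[checklists["complete"].astype(bool)]


def dedup_groups(
    checklists: pd.DataFrame,
    detections: pd.DataFrame,
    focal: str,
    return_disagreements: bool = False,
):
    """Collapse each shared group to a single checklist.

    Within a group the retained checklist is chosen by: focal species
    present first, then maximal focal count, then lexicographically
    smallest checklist identifier.  Checklists without a group identifier
    pass through untouched.  Groups whose members disagree on the focal
    count are logged (a disagreement means the shared event was recorded
    inconsistently) and, with ``return_disagreements``, tallied in the
    returned ``(subset, n_disagreements)`` pair.
    """
    focal_det = detections[detections["species"] == focal]
    position = pd.Index(focal_det["checklist_id"]).get_indexer(
        checklists["checklist_id"]
    )
    if (position < 0).any():
        raise ValueError(
            f"detections are not zero-filled for {focal!r}: "
            f"{int((position < 0).sum())} checklist(s) missing"
        )
    present = focal_det["present"].to_numpy()[position]
    count = focal_det["count"].to_numpy()[position]

    group_raw = checklists["group_id"]
    has_group = (group_raw.notna() & (group_raw.astype(str) != "")).to_numpy()
    n_disagree = 0
    if has_group.any():
        group_codes, _ = pd.factorize(group_raw.to_numpy()[has_group])
        counts_in_group = count[has_group]
        # a group disagrees when its members report different focal counts
        order_simple = np.argsort(group_codes, kind="stable")
        gc_sorted = group_codes[order_simple]
        ct_sorted = counts_in_group[order_simple]
        new_group = np.r_[True, gc_sorted[1:] != gc_sorted[:-1]]
        differs = np.r_[False, ct_sorted[1:] != ct_sorted[:-1]] & ~new_group
        n_disagree = int(len(np.unique(gc_sorted[differs])))
        if n_disagree:
            logger.warning(
                "%d group(s) disagree on the focal species count", n_disagree
            )
        # rank ids lexicographically for the deterministic tie-break
        ids_in_group = checklists["checklist_id"].to_numpy()[has_group]
        id_rank = np.empty(len(ids_in_group), dtype=np.int64)
        id_rank[np.argsort(ids_in_group, kind="stable")] = np.arange(len(ids_in_group))
        # lexsort: last key is primary; prefer present, then max count, then min id
        order = np.lexsort(
            (id_rank, -counts_in_group, ~present[has_group], group_codes)
        )
        first = np.r_[True, group_codes[order][1:] != group_codes[order][:-1]]
        keep_in_group = np.zeros(len(group_codes), dtype=bool)
        keep_in_group[order[first]] = True
        mask = ~has_group
        mask[np.flatnonzero(has_group)[keep_in_group]] = True
    else:
        mask = np.ones(len(checklists), dtype=bool)
    subset = checklists[pd.Series(mask, index=checklists.index)]
    if return_disagreements:
        return subset, n_disagree
    return subset


def apply_filters(
    checklists: pd.DataFrame,
    spec: FilterSpec,
    detections: pd.DataFrame | None = None,
    focal: str | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full filter pipeline and account for every checklist.

    Order is fixed: completeness, season, region, protocol, group
    deduplication (so the detection information used by the dedup
    tie-break is final).  Deduplication requires ``detections`` zero-filled
    for ``focal``; with ``spec.dedup`` False both may be omitted.
    """
    report = FilterReport(n_input=len(checklists))
    current = checklists

    if spec.require_complete:
        kept = require_complete(current)
        report.add_stage("complete", len(current) - len(kept), len(kept))
        current = kept

    kept = filter_window(current, spec.months)
    report.add_stage("season", len(current) - len(kept), len(kept))
    current = kept

    if spec.region:
        county_codes, county_values = _normalized_codes(current["county"])
        empty = [i for i, value in enumerate(county_values) if value == ""]
        missing_county = int(np.isin(county_codes, empty).sum())
        kept = filter_region(current, spec.region)
        report.add_stage(
            "region",
            len(current) - len(kept),
            len(kept),
            removed_missing_county=missing_county,
        )
        current = kept

    if spec.excluded_count_types:
        per_type = _protocol_counts(current, spec.excluded_count_types)
        kept = filter_protocols(current, spec.excluded_count_types)
        report.add_stage(
            "protocol", len(current) - len(kept), len(kept), removed_per_type=per_type
        )
        current = kept

    if spec.dedup:
        if detections is None or focal is None:
            raise ValueError("dedup requires detections zero-filled for the focal species")
        kept, n_disagree = dedup_groups(
            current, detections, focal, return_disagreements=True
        )
        report.add_stage(
            "dedup",
            len(current) - len(kept),
            len(kept),
            count_disagreements=n_disagree,
        )
        current = kept

    assert report.reconciles()
    return current.reset_index(drop=True), report
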