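"""Synthetic eBird-like checklist datasets with known occupancy trends.

The generator emulates the statistical structure of a breeding-season
checklist extract over a bounded two-state region: a planar grid of cells,
each latently occupied by the focal species in a given year with
probability ``logistic(baseline + b_year * (year - year0))``; observer
effort (checklists per cell) growing multiplicatively across years;
imperfect per-checklist detection conditional on latent occupancy; control
species with flat or slightly declining trends; shared group checklists
(duplicates of one birding event); and a sprinkle of excluded survey
protocols.  Checklist coordinates are drawn uniformly within cells and a
synthetic county map partitions the grid so the regional filter is
exercised end to end.

Because detection is conditional on latent occupancy, the pipeline
estimates the trend in *apparent* (detected) occupancy.  The generator
emits its own realized detected-occupancy table as ground truth, alongside
the latent occupancy, so recovery experiments can target either.

All randomness flows from one seed; equal seeds give byte-identical data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .ebd_io import zero_fill
from .filtering import (
    DEFAULT_EXCLUDED_COUNT_TYPES,
    FilterSpec,
    apply_filters,
)
from .gridding import (
    AsciiGrid,
    DEFAULT_CRS,
    GridSpec,
    aggregate_cell_year,
    assign_cells,
    make_grid,
)
from .trend_model import confidence_interval, fit_occupancy_glm

logger = logging.getLogger(__name__)

#: Anchor of the synthetic study region (western Maine / New Hampshire line).
REGION_ANCHOR_LON = -70.9
REGION_ANCHOR_LAT = 44.9

_OK_PROTOCOLS = np.array(["Traveling", "Stationary"], dtype=object)
_EXCLUDED_PROTOCOLS = np.array(DEFAULT_EXCLUDED_COUNT_TYPES, dtype=object)


@dataclass(frozen=True)
class ControlSpecies:
    """A co-occurring species with its own baseline and trend."""

    name: str
    baseline_logit_occupancy: float
    b_year_true: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the generator.

    Defaults mirror a breeding-season songbird extract: 14 years
    (2003-2016), 300 cells of 10 km side, a rare focal species whose
    occupancy odds grow 0.18/year on the log scale from a ~1.8% baseline,
    detection probability high enough that detected occupancy tracks
    latent occupancy, and observer effort growing 25%/year from 3
    checklists per cell (about 78,000 checklists over the series).
    """

    year_start: int = 2003
    year_end: int = 2016
    n_cells: int = 300
    cell_side_km: float = 10.0
    baseline_logit_occupancy: float = -4.0
    b_year_true: float = 0.18
    detection_prob: float = 0.95
    effort_base: float = 3.0
    effort_growth: float = 1.25
    duration_mean_h: float = 1.5
    duration_sd_h: float = 1.0
    group_prob: float = 0.10
    excluded_protocol_prob: float = 0.02
    focal_species: str = "fox_sparrow"
    control_species: tuple = (
        ControlSpecies("bicknells_thrush", -2.5, 0.0),
        ControlSpecies("blackpoll_warbler", -1.5, -0.03),
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("detection_prob", "group_prob", "excluded_protocol_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.effort_growth <= 0:
            raise ValueError("effort_growth must be positive")
        if self.year_end < self.year_start + 1:
            raise ValueError("need at least two years")
        object.__setattr__(
            self,
            "control_species",
            tuple(
                c if isinstance(c, ControlSpecies) else ControlSpecies(*c)
                for c in self.control_species
            ),
        )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def species_names(self) -> list[str]:
        return [self.focal_species] + [c.name for c in self.control_species]

    def true_slope(self, species: str) -> float:
        if species == self.focal_species:
            return self.b_year_true
        for control in self.control_species:
            if control.name == species:
                return control.b_year_true
        raise KeyError(species)

    def _baseline(self, species: str) -> float:
        if species == self.focal_species:
            return self.baseline_logit_occupancy
        for control in self.control_species:
            if control.name == species:
                return control.baseline_logit_occupancy
        raise KeyError(species)

    def apparent_slope(self, species: str) -> float:
        """Per-year slope of the *detected*-occupancy process.

        Because detection is imperfect and per-checklist, the quantity the
        pipeline estimates is the trend in apparent occupancy — the
        probability that a surveyed cell-year yields at least one
        detection — not the latent occupancy trend.  This method computes
        that estimand analytically: apparent occupancy is
        ``q_t = logistic(base + b t) * P(>=1 detection | occupied, surveyed)``
        under Poisson checklist counts, and the estimand is the slope of
        the logistic curve closest to ``q_t`` in survey-weighted
        Kullback-Leibler divergence (what the occupancy GLM converges to
        as the number of cells grows).  With high detection probability it
        sits just above the latent slope, approaching it as effort grows.
        """
        from scipy.optimize import minimize
        from scipy.special import expit

        base = self._baseline(species)
        slope = self.true_slope(species)
        t = np.arange(len(self.years), dtype=float)
        lam = self.effort_base * self.effort_growth**t * (1.0 - self.excluded_protocol_prob)
        surveyed = 1.0 - np.exp(-lam)
        detect = 1.0 - (np.exp(-lam * self.detection_prob) - np.exp(-lam)) / surveyed
        q = expit(base + slope * t) * detect

        def cross_entropy(ab):
            mu = np.clip(expit(ab[0] + ab[1] * t), 1e-12, 1.0 - 1e-12)
            return -np.sum(surveyed * (q * np.log(mu) + (1.0 - q) * np.log(1.0 - mu)))

        best = minimize(
            cross_entropy, np.array([base, slope]), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000},
        )
        return float(best.x[1])

    def to_dict(self) -> dict:
        data = {
            k: getattr(self, k)
            for k in (
                "year_start", "year_end", "n_cells", "cell_side_km",
                "baseline_logit_occupancy", "b_year_true", "detection_prob",
                "effort_base", "effort_growth", "duration_mean_h",
                "duration_sd_h", "group_prob", "excluded_protocol_prob",
                "focal_species", "seed",
            )
        }
        data["control_species"] = [
            [c.name, c.baseline_logit_occupancy, c.b_year_true]
            for c in self.control_species
        ]
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        if "control_species" in data:
            data["control_species"] = tuple(
                ControlSpecies(*c) for c in data["control_species"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class SimulatedDataset:
    """Output bundle of :func:`simulate_dataset`."""

    checklists: pd.DataFrame
    observations: pd.DataFrame
    truth: pd.DataFrame
    grid: GridSpec
    config: SyntheticConfig


def _grid_shape(n_cells: int) -> tuple[int, int]:
    n_cols = max(1, int(np.ceil(np.sqrt(n_cells))))
    n_rows = int(np.ceil(n_cells / n_cols))
    return n_cols, n_rows


def _county_map(cell_col, cell_row, n_cols, n_rows):
    """Synthetic two-state county partition of the grid.

    The westernmost quarter of columns is New Hampshire (Coos north,
    Grafton south); the rest is Maine, split into three column bands and
    two row bands named after the six northern Maine counties.
    """
    cell_col = np.asarray(cell_col)
    cell_row = np.asarray(cell_row)
    nh_cols = max(1, n_cols // 4)
    north = cell_row >= (n_rows + 1) // 2
    state = np.where(cell_col < nh_cols, "US-NH", "US-ME").astype(object)
    me_band = np.clip(
        (cell_col - nh_cols) * 3 // max(1, n_cols - nh_cols), 0, 2
    )
    me_names = np.array(
        [["Oxford", "Franklin"], ["Somerset", "Piscataquis"], ["Penobscot", "Aroostook"]],
        dtype=object,
    )
    county = np.where(
        cell_col < nh_cols,
        np.where(north, "Coos", "Grafton"),
        me_names[me_band, north.astype(int)],
    ).astype(object)
    return state, county


def simulate_dataset(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> SimulatedDataset:
    """Draw one synthetic checklist dataset from the generative model.

    Returns checklists and observations in the canonical table layouts of
    :mod:`gridocc.ebd_io`, plus a ground-truth table with one row per
    (cell, year): latent ``occupied_<species>``, realized
    ``detected_<species>`` (over core checklists, i.e. excluding
    excluded-protocol checklists and counting each group once),
    ``n_checklists`` and ``effort_hours`` for the same core set.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    years = config.years
    n_years = len(years)
    n_cells = config.n_cells
    n_cols, n_rows = _grid_shape(n_cells)
    side = config.cell_side_km * 1000.0
    crs = DEFAULT_CRS
    anchor_x, anchor_y = crs.forward(REGION_ANCHOR_LON, REGION_ANCHOR_LAT)
    # snap to the canonical lattice so analysis grids align with these cells
    origin_x = float(np.floor(anchor_x / side) * side)
    origin_y = float(np.floor(anchor_y / side) * side)
    grid = GridSpec(crs, origin_x, origin_y, side, n_cols, n_rows)
    cell_col = np.arange(n_cells) % n_cols
    cell_row = np.arange(n_cells) // n_cols

    species = config.species_names
    baselines = [config.baseline_logit_occupancy] + [
        c.baseline_logit_occupancy for c in config.control_species
    ]
    slopes = [config.b_year_true] + [c.b_year_true for c in config.control_species]

    # latent occupancy, (n_species, n_cells, n_years)
    from scipy.special import expit

    occupied = np.empty((len(species), n_cells, n_years), dtype=bool)
    for s, (base, slope) in enumerate(zip(baselines, slopes)):
        p_year = expit(base + slope * (years - config.year_start))
        occupied[s] = rng.random((n_cells, n_years)) < p_year[None, :]

    # checklist counts per (cell, year)
    lam = config.effort_base * config.effort_growth ** np.arange(n_years)
    counts = rng.poisson(np.broadcast_to(lam, (n_cells, n_years)))
    total = int(counts.sum())
    flat = counts.ravel()
    pair = np.repeat(np.arange(n_cells * n_years), flat)
    ci = pair // n_years  # cell index per checklist
    ti = pair % n_years  # year index per checklist

    # locations: uniform within the cell, then back to lon/lat
    x = origin_x + (cell_col[ci] + rng.random(total)) * side
    y = origin_y + (cell_row[ci] + rng.random(total)) * side
    lon, lat = crs.inverse(x, y)

    # dates: uniform over the 61 days of June and July
    day = rng.integers(0, 61, total)
    date = (
        np.array([np.datetime64(f"{year}-06-01") for year in years])[ti]
        + day.astype("timedelta64[D]")
    )

    duration = np.clip(
        rng.normal(config.duration_mean_h, config.duration_sd_h, total), 0.05, None
    )
    distance = np.round(rng.gamma(2.0, 1.6, total), 3)  # km, median ~ 3 km
    is_excluded = rng.random(total) < config.excluded_protocol_prob
    protocol = np.where(
        is_excluded,
        _EXCLUDED_PROTOCOLS[rng.integers(0, len(_EXCLUDED_PROTOCOLS), total)],
        _OK_PROTOCOLS[rng.integers(0, len(_OK_PROTOCOLS), total)],
    )
    observer = np.char.add(
        "obs", rng.integers(0, max(10, total // 20), total).astype(str)
    ).astype(object)
    state, county = _county_map(cell_col[ci], cell_row[ci], n_cols, n_rows)

    # detections, conditional on the checklist's cell-year being occupied
    detected = np.empty((len(species), total), dtype=bool)
    det_count = np.empty((len(species), total), dtype=int)
    for s in range(len(species)):
        occ_here = occupied[s][ci, ti]
        detected[s] = occ_here & (rng.random(total) < config.detection_prob)
        det_count[s] = 1 + rng.poisson(0.5, total)

    # group duplicates: a duplicated checklist and its copy share a group id
    dup = rng.random(total) < config.group_prob
    n_dup = int(dup.sum())
    group_id = np.full(total, None, dtype=object)
    group_id[dup] = [f"G{k:06d}" for k in range(n_dup)]

    n_all = total + n_dup
    ids = np.char.add("S", np.char.zfill(np.arange(n_all).astype(str), 7)).astype(object)
    dup_src = np.flatnonzero(dup)

    def _dup(values):
        return np.concatenate([values, np.asarray(values, dtype=None)[dup_src]])

    checklists = pd.DataFrame(
        {
            "checklist_id": ids,
            "group_id": np.concatenate([group_id, group_id[dup_src]]),
            "date": _dup(date),
            "latitude": _dup(lat),
            "longitude": _dup(lon),
            "state": _dup(state),
            "county": _dup(county),
            "count_type": _dup(protocol),
            "complete": np.ones(n_all, dtype=bool),
            "duration_hours": _dup(duration),
            "distance_km": _dup(distance),
            "observer_id": _dup(observer),
        }
    )

    obs_frames = []
    for s, name in enumerate(species):
        hit = np.concatenate([detected[s], detected[s][dup_src]])
        counts_s = np.concatenate([det_count[s], det_count[s][dup_src]])
        obs_frames.append(
            pd.DataFrame(
                {
                    "checklist_id": ids[hit],
                    "species": name,
                    "count": counts_s[hit],
                    "presence_only": False,
                }
            )
        )
    observations = pd.concat(obs_frames, ignore_index=True)

    # ground truth per (cell, year), over core checklists only
    core = ~is_excluded
    truth = pd.DataFrame(
        {
            "cell_col": np.repeat(cell_col, n_years),
            "cell_row": np.repeat(cell_row, n_years),
            "year": np.tile(years, n_cells),
        }
    )
    n_core = np.bincount(pair[core], minlength=n_cells * n_years)
    effort_core = np.bincount(
        pair[core], weights=duration[core], minlength=n_cells * n_years
    )
    truth["n_checklists"] = n_core
    truth["effort_hours"] = effort_core
    for s, name in enumerate(species):
        truth[f"occupied_{name}"] = occupied[s].ravel()
        det_core = np.zeros(n_cells * n_years, dtype=bool)
        np.logical_or.at(det_core, pair[core], detected[s][core])
        truth[f"detected_{name}"] = det_core

    return SimulatedDataset(
        checklists=checklists,
        observations=observations,
        truth=truth,
        grid=grid,
        config=config,
    )


def synthetic_dem(
    grid: GridSpec,
    cellsize_deg: float = 0.01,
    seed: int = 0,
    base_m: float = 350.0,
    relief_m: float = 1100.0,
) -> AsciiGrid:
    """A smooth synthetic elevation surface covering the grid, in degrees.

    Synthetic stand-in for a real digital-elevation model: a deterministic
    ridge-and-valley surface (sinusoidal in lon/lat) plus seeded noise,
    useful only for exercising raster sampling end to end.
    """
    min_x, min_y, max_x, max_y = grid.extent
    corners_x = np.array([min_x, max_x, min_x, max_x])
    corners_y = np.array([min_y, min_y, max_y, max_y])
    lon, lat = grid.crs.inverse(corners_x, corners_y)
    west, east = lon.min() - 0.05, lon.max() + 0.05
    south, north = lat.min() - 0.05, lat.max() + 0.05
    ncols = int(np.ceil((east - west) / cellsize_deg))
    nrows = int(np.ceil((north - south) / cellsize_deg))
    rng = np.random.default_rng(seed)
    lon_centers = west + (np.arange(ncols) + 0.5) * cellsize_deg
    lat_centers = north - (np.arange(nrows) + 0.5) * cellsize_deg
    lon_grid, lat_grid = np.meshgrid(lon_centers, lat_centers)
    surface = (
        base_m
        + relief_m
        * (0.5 + 0.5 * np.sin(8.0 * lon_grid) * np.cos(11.0 * lat_grid))
        + rng.normal(0.0, 15.0, (nrows, ncols))
    )
    return AsciiGrid(
        data=np.round(surface, 1), xll=west, yll=north - nrows * cellsize_deg,
        cellsize=cellsize_deg,
    )


def analyze_simulated(
    dataset: SimulatedDataset,
    filter_spec: FilterSpec | None = None,
    predictors=("year",),
    ci_method: str | None = "profile",
    level: float = 0.95,
):
    """Run filters -> grid -> GLM on a simulated dataset for every species.

    Returns ``{species: (TrendFit, IntervalEstimate | None)}``; degenerate
    fits carry ``None`` intervals.
    """
    config = dataset.config
    spec = filter_spec or FilterSpec()
    species_list = config.species_names
    detections = zero_fill(dataset.checklists, dataset.observations, species_list)
    filtered, _ = apply_filters(
        dataset.checklists, spec, detections=detections, focal=config.focal_species
    )
    grid = make_grid(
        filtered["longitude"], filtered["latitude"], config.cell_side_km
    )
    assignment = assign_cells(filtered, grid)
    cell_year, _ = aggregate_cell_year(filtered, detections, assignment, species_list)
    results = {}
    for name in species_list:
        fit = fit_occupancy_glm(cell_year, name, predictors=predictors)
        interval = None
        if not fit.degenerate and fit.converged and ci_method is not None:
            interval = confidence_interval(fit, "year", level=level, method=ci_method)
        results[name] = (fit, interval)
    return results


def recovery_experiment(
    config: SyntheticConfig | None = None,
    n_reps: int = 100,
    level: float = 0.95,
    ci_method: str = "profile",
) -> pd.DataFrame:
    """Repeatedly simulate and re-estimate the trend through the pipeline.

    Each replicate simulates a dataset from ``config``, pushes it through
    the full filter/grid/GLM pipeline, and records, per species, the slope
    estimate, its SE, confidence interval, Wald p-value, and whether the
    interval covers that species' true slope.  Degenerate replicates are
    recorded with ``degenerate=True`` so summaries can exclude them.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or SyntheticConfig()
    master = np.random.default_rng(config.seed)
    apparent_slopes = {
        name: config.apparent_slope(name) for name in config.species_names
    }
    rows = []
    for rep in range(n_reps):
        seed = int(master.integers(2**31))
        dataset = simulate_dataset(config, seed=seed)
        results = analyze_simulated(dataset, ci_method=ci_method, level=level)
        for name, (fit, interval) in results.items():
            true_slope = config.true_slope(name)
            apparent = apparent_slopes[name]
            if fit.degenerate or not fit.converged:
                rows.append(
                    {
                        "rep": rep, "species": name, "b_true": true_slope,
                        "b_apparent": apparent,
                        "degenerate": True, "b_hat": np.nan, "se": np.nan,
                        "ci_lower": np.nan, "ci_upper": np.nan,
                        "p_wald": np.nan, "covered": np.nan,
                        "covered_apparent": np.nan,
                    }
                )
                continue
            rows.append(
                {
                    "rep": rep,
                    "species": name,
                    "b_true": true_slope,
                    "b_apparent": apparent,
                    "degenerate": False,
                    "b_hat": fit.coef("year"),
                    "se": fit.se("year"),
                    "ci_lower": interval.lower,
                    "ci_upper": interval.upper,
                    "p_wald": fit.wald_p("year"),
                    "covered": bool(interval.lower <= true_slope <= interval.upper),
                    "covered_apparent": bool(
                        interval.lower <= apparent <= interval.upper
                    ),
                }
            )
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame) -> pd.DataFrame:
    """Bias, spread, CI coverage and rejection rate per species.

    Bias and coverage are reported against both targets: the latent slope
    (``b_true``) and the apparent detected-occupancy slope
    (``b_apparent``, the pipeline's actual estimand; see
    :meth:`SyntheticConfig.apparent_slope`).  Degenerate replicates are
    excluded from the moments and counted in ``n_degenerate``.
    """
    summaries = []
    for name, group in results.groupby("species", sort=False):
        good = group[~group["degenerate"].astype(bool)]
        n = len(good)
        summaries.append(
            {
                "species": name,
                "b_true": float(group["b_true"].iloc[0]),
                "b_apparent": float(group["b_apparent"].iloc[0]),
                "n_reps": int(len(group)),
                "n_degenerate": int(len(group) - n),
                "mean_b_hat": float(good["b_hat"].mean()),
                "bias": float(good["b_hat"].mean() - group["b_true"].iloc[0]),
                "bias_vs_apparent": float(
                    good["b_hat"].mean() - group["b_apparent"].iloc[0]
                ),
                "empirical_sd": float(good["b_hat"].std(ddof=1)) if n > 1 else np.nan,
                "mean_se": float(good["se"].mean()),
                "mc_se_of_mean": (
                    float(good["b_hat"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
                ),
                "ci_coverage": float(good["covered"].mean()),
                "ci_coverage_apparent": float(good["covered_apparent"].mean()),
                "rejection_rate_05": float((good["p_wald"] <= 0.05).mean()),
            }
        )
    return pd.DataFrame(summaries)
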