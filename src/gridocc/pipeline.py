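"""End-to-end runs: configuration, report assembly, and file outputs.

`run_pipeline` ties the stages together — read an EBD-style extract,
zero-fill, filter, overlay one grid per configured cell size, fit the
year-only and year+effort occupancy GLMs per species, compare them by
analysis of deviance, test overdispersion, compute confidence intervals,
co-occurrence rates, and (if a DEM is supplied) elevation summaries for
checklists recording the focal species.  Everything is deterministic given
the inputs and config, and every number in the report is recomputable from
the intermediate CSVs written alongside it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ebd_io import read_checklists, zero_fill, write_detection_table
from .filtering import FilterSpec, apply_filters
from .gridding import (
    AsciiGrid,
    aggregate_cell_year,
    assign_cells,
    elevation_summary,
    make_grid,
    sample_elevation,
)
from .trend_model import (
    annual_growth,
    confidence_interval,
    cooccurrence_rates,
    fit_occupancy_glm,
    likelihood_ratio_test,
    overdispersion_test,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    input_path: str | None = None
    dem_path: str | None = None
    output_dir: str = "gridocc_output"
    focal_species: str = "fox_sparrow"
    control_species: tuple = ()
    cell_sizes_km: tuple = (10.0, 5.0)
    cell_size_interpretation: str = "side"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    ci_method: str = "profile"
    level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not self.focal_species:
            raise ValueError("focal species must be named")
        self.cell_sizes_km = tuple(float(s) for s in self.cell_sizes_km)
        if len(self.cell_sizes_km) < 1:
            raise ValueError("need at least one cell size")
        self.control_species = tuple(self.control_species)
        if not isinstance(self.filter_spec, FilterSpec):
            self.filter_spec = FilterSpec.from_dict(self.filter_spec)

    @property
    def species_list(self) -> list[str]:
        return [self.focal_species, *self.control_species]

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "dem_path": self.dem_path,
            "output_dir": self.output_dir,
            "focal_species": self.focal_species,
            "control_species": list(self.control_species),
            "cell_sizes_km": list(self.cell_sizes_km),
            "cell_size_interpretation": self.cell_size_interpretation,
            "filter_spec": self.filter_spec.to_dict(),
            "ci_method": self.ci_method,
            "level": self.level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "filter_spec" in data and not isinstance(data["filter_spec"], FilterSpec):
            data["filter_spec"] = FilterSpec.from_dict(data["filter_spec"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")


def _species_block(cell_year, species, ci_method, level):
    """Fit blocks for one species on one grid: models, LRT, diagnostics."""
    fit_year = fit_occupancy_glm(cell_year, species, predictors=("year",))
    if fit_year.degenerate:
        return {"degenerate": True, "note": "occupancy constant; no fit"}
    fit_full = fit_occupancy_glm(cell_year, species, predictors=("year", "effort"))
    lrt = likelihood_ratio_test(fit_year, fit_full)
    # the effort model is preferred only if the deviance drop is significant
    preferred = "year_effort" if lrt.p < 0.05 else "year"
    interval = confidence_interval(fit_year, "year", level=level, method=ci_method)
    block = {
        "degenerate": False,
        "model_year": fit_year.to_dict(),
        "model_year_effort": fit_full.to_dict(),
        "effort_lrt": {"statistic": lrt.statistic, "df": lrt.df, "p": lrt.p},
        "preferred_model": preferred,
        "b_year": fit_year.coef("year"),
        "b_year_se": fit_year.se("year"),
        "b_year_p_wald": fit_year.wald_p("year"),
        "b_year_ci": {
            "lower": interval.lower,
            "upper": interval.upper,
            "level": level,
            "method": interval.method,
        },
        "growth": annual_growth(fit_year),
        "overdispersion": {},
    }
    for label, fit in (("year", fit_year), ("year_effort", fit_full)):
        if fit.converged:
            test = overdispersion_test(fit)
            block["overdispersion"][label] = {
                "ratio": test.ratio,
                "statistic": test.statistic,
                "df": test.df,
                "p": test.p,
                "overdispersed": test.overdispersed,
            }
    return block


def run_pipeline(
    config: RunConfig,
    checklists: pd.DataFrame | None = None,
    observations: pd.DataFrame | None = None,
    write: bool = True,
) -> dict:
    """Execute the full analysis and (optionally) write outputs to disk.

    Checklist/observation tables may be passed directly (e.g. from the
    synthetic generator); otherwise ``config.input_path`` is read.  Writes
    ``filter_report.json``, ``detections.tsv``, per-grid
    ``cell_year_<size>km.csv`` and ``occupancy_series_<size>km.csv``, and
    the assembled ``report.json``.  Returns the report as a dict.
    """
    if checklists is None:
        if config.input_path is None:
            raise ValueError("no input: provide checklists or config.input_path")
        logger.info("reading checklists from %s", config.input_path)
        checklists, observations = read_checklists(config.input_path)

    species_list = config.species_list
    detections = zero_fill(checklists, observations, species_list)
    filtered, filter_report = apply_filters(
        checklists,
        config.filter_spec,
        detections=detections,
        focal=config.focal_species,
    )
    if len(filtered) == 0:
        raise ValueError("no checklists remain after filtering")

    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        (out / "filter_report.json").write_text(filter_report.to_json(indent=2) + "\n")
        write_detection_table(detections, out / "detections.tsv")

    report: dict = {
        "config": config.to_dict(),
        "filter_report": json.loads(filter_report.to_json()),
        "grids": {},
        "cooccurrence": [],
    }

    for size in config.cell_sizes_km:
        grid = make_grid(
            filtered["longitude"],
            filtered["latitude"],
            size,
            interpretation=config.cell_size_interpretation,
        )
        assignment = assign_cells(filtered, grid)
        cell_year, per_year = aggregate_cell_year(
            filtered, detections, assignment, species_list
        )
        key = f"{size:g}km"
        if write:
            cell_year.to_csv(out / f"cell_year_{key}.csv", index=False)
            per_year.to_csv(out / f"occupancy_series_{key}.csv", index=False)
        species_blocks = {
            name: _species_block(cell_year, name, config.ci_method, config.level)
            for name in species_list
        }
        report["grids"][key] = {
            "grid_spec": grid.to_dict(),
            "n_cell_years": int(len(cell_year)),
            "per_year": {
                name: per_year[per_year["species"] == name]
                .drop(columns="species")
                .to_dict("records")
                for name in species_list
            },
            "species": species_blocks,
        }

    for other in config.control_species:
        rates = cooccurrence_rates(detections, config.focal_species, other)
        report["cooccurrence"].append(
            {
                "species_a": rates.species_a,
                "species_b": rates.species_b,
                "pct_a_with_b": rates.pct_a_with_b,
                "pct_b_with_a": rates.pct_b_with_a,
                "n_a": rates.n_a,
                "n_b": rates.n_b,
            }
        )

    if config.dem_path:
        raster = AsciiGrid.read(config.dem_path)
        focal_present = detections.loc[
            (detections["species"] == config.focal_species) & detections["present"],
            "checklist_id",
        ]
        hits = filtered[filtered["checklist_id"].isin(set(focal_present))]
        elevations = pd.DataFrame(
            {
                "region": hits["state"].to_numpy(),
                "elevation_m": sample_elevation(
                    hits["longitude"].to_numpy(), hits["latitude"].to_numpy(), raster
                ),
            }
        )
        report["elevation"] = elevation_summary(elevations).to_dict("records")

    if write:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        logger.info("report written to %s", out / "report.json")
    return report


def compare_species(report: dict, focal: str, controls, grid_key: str | None = None) -> pd.DataFrame:
    """Side-by-side trend contrast table from an assembled report.

    One row per species with the year slope, its CI and Wald p, and a flag
    for a positive trend significant at the report's configured level.
    """
    if grid_key is None:
        grid_key = next(iter(report["grids"]))
    blocks = report["grids"][grid_key]["species"]
    rows = []
    for name in [focal, *controls]:
        if name not in blocks:
            raise KeyError(f"no fitted block for species {name!r}")
        block = blocks[name]
        if block.get("degenerate"):
            rows.append(
                {"species": name, "degenerate": True, "b_year": np.nan,
                 "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan,
                 "positive_trend": False}
            )
            continue
        alpha = 1.0 - block["b_year_ci"]["level"]
        rows.append(
            {
                "species": name,
                "degenerate": False,
                "b_year": block["b_year"],
                "ci_lower": block["b_year_ci"]["lower"],
                "ci_upper": block["b_year_ci"]["upper"],
                "p": block["b_year_p_wald"],
                "positive_trend": bool(
                    block["b_year"] > 0 and block["b_year_p_wald"] < alpha
                ),
            }
        )
    return pd.DataFrame(rows)
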