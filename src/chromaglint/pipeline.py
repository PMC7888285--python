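"""One-call orchestration: design -> simulate/load -> analyze -> model fit.

``run_pipeline`` executes the full analysis on either a synthetic-observer
dataset (default) or response CSVs, returning a :class:`RunReport` and
optionally writing every table to an output directory.  All randomness
flows from the single top-level seed; two runs with identical config and
seed produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colorimetry import GamutError
from .design import (
    HUES,
    RELIEFS,
    ROUGHNESS_PC,
    SLANTS,
    GRID_STEP,
    GRID_C_RANGE,
    GRID_L_RANGE,
    build_matching_grid,
)
from .model import forced_weight_fit, pooled_fit, sweep_weight
from .observers import ObserverParams, SyntheticDataset, make_dataset
from .psychophysics import aggregate_matches, pc_probability, rm_anova

__all__ = ["RunConfig", "RunReport", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on.

    Synthetic mode (default) simulates observers from ``observer_params``;
    data mode reads the three response CSVs instead.  ``forced_W``
    ``"pooled-best"`` re-fits every block at the pooled-data optimum.
    """

    hues: tuple = HUES
    reliefs: tuple = RELIEFS
    roughnesses: tuple = ROUGHNESS_PC
    slants: tuple = SLANTS
    grid_L_range: tuple = GRID_L_RANGE
    grid_C_range: tuple = GRID_C_RANGE
    grid_step: float = GRID_STEP
    white_point: str = "d65"
    #: "clip" tolerates (and records) out-of-gamut grid cells as an 8-bit
    #: display would; True aborts the run on any out-of-gamut cell.
    grid_gamut_mode: bool | str = "clip"
    observer_params: ObserverParams = field(default_factory=ObserverParams)
    n_matching_observers: int = 9
    n_choice_observers: int = 4
    matching_csv: str | None = None
    gloss_csv: str | None = None
    coverage_csv: str | None = None
    dvs: tuple = ("saturation", "lightness")
    sweep_step: float = 0.01
    forced_W: str | float = "pooled-best"
    run_anova: bool = True
    seed: int = 0

    @property
    def synthetic(self) -> bool:
        return self.matching_csv is None

    def validate(self) -> None:
        for name in ("hues", "reliefs", "roughnesses", "slants"):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"empty level set: {name}")
        if self.sweep_step <= 0 or self.sweep_step > 2:
            raise ConfigError(f"invalid sweep step {self.sweep_step}")
        if not self.synthetic and (self.gloss_csv is None or self.coverage_csv is None):
            raise ConfigError("data mode needs matching, gloss and coverage CSVs")
        for dv in self.dvs:
            if dv not in ("saturation", "lightness"):
                raise ConfigError(f"unknown dependent variable {dv!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        obs = raw.pop("observer_params", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hues", "reliefs", "roughnesses", "slants", "dvs",
                    "grid_L_range", "grid_C_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw) if obs is None else cls(
            observer_params=ObserverParams(**obs), **raw
        )
        cfg.validate()
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        d["observer_params"]["hue_W_offsets"] = dict(
            self.observer_params.hue_W_offsets
        )
        return d


@dataclass
class RunReport:
    """All tables a run produced, plus the config echo that regenerates them."""

    percepts: pd.DataFrame
    model_fits: dict
    anova: dict
    recovery: dict
    inter_correlation: float
    config_echo: dict
    seed: int
    version: str = __version__
    artifacts: dict = field(default_factory=dict)


def _percept_table(dataset: SyntheticDataset | dict, cfg: RunConfig) -> pd.DataFrame:
    """Observer-averaged percepts per condition, merged across the tasks."""
    if isinstance(dataset, SyntheticDataset):
        matching = dataset.matching
        gloss = dataset.gloss_choices
        coverage = dataset.coverage_choices
    else:
        matching, gloss, coverage = (
            dataset["matching"], dataset["gloss"], dataset["coverage"]
        )
    per_obs = aggregate_matches(matching)
    keys = ["hue", "relief", "roughness", "slant"]
    match_mean = (
        per_obs.groupby(keys, sort=True)[["mean_L", "mean_C", "mean_S"]]
        .mean()
        .reset_index()
    )
    out = match_mean
    for task_name, frame in (("p_gloss", gloss), ("p_coverage", coverage)):
        p = pc_probability(frame)
        p_mean = (
            p.groupby(["hue", "slant", "relief", "roughness"], sort=True)["p"]
            .mean()
            .reset_index()
            .rename(columns={"p": task_name})
        )
        out = out.merge(p_mean, on=keys, how="left")
    return out


def _fit_tables(percepts: pd.DataFrame, cfg: RunConfig):
    """Per hue x slant sweeps, the pooled sweep, and forced-weight refits."""
    dv_col = {"saturation": "mean_S", "lightness": "mean_L"}
    complete = percepts.dropna(subset=["p_gloss", "p_coverage"])
    model_fits = {}
    recovery = {}
    inter_r = np.nan
    for dv in cfg.dvs:
        col = dv_col[dv]
        pooled_df = complete.rename(columns={col: "percept"})[
            ["hue", "slant", "p_gloss", "p_coverage", "percept"]
        ]
        pooled_sweep, inter_r = pooled_fit(pooled_df, "percept", cfg.sweep_step, dv=dv)
        forced_at = (
            pooled_sweep.best.W if cfg.forced_W == "pooled-best" else float(cfg.forced_W)
        )
        rows = []
        for (hue, slant), blk in complete.groupby(["hue", "slant"], sort=True):
            sweep = sweep_weight(
                blk[col].to_numpy(),
                blk["p_gloss"].to_numpy(),
                blk["p_coverage"].to_numpy(),
                step=cfg.sweep_step,
                pooling=f"hue={hue},slant={slant}",
                dv=dv,
            )
            forced = forced_weight_fit(
                forced_at,
                blk[col].to_numpy(),
                blk["p_gloss"].to_numpy(),
                blk["p_coverage"].to_numpy(),
                dv=dv,
            )
            rows.append(
                (hue, slant, sweep.best.W, sweep.best.r, sweep.best.p,
                 forced.W, forced.r, sweep.best.n)
            )
        table = pd.DataFrame(
            rows,
            columns=["hue", "slant", "W", "r_W", "p_W",
                     "W_forced", "r_forced", "n"],
        )
        pooled_row = pd.DataFrame(
            [("pooled", "all", pooled_sweep.best.W, pooled_sweep.best.r,
              pooled_sweep.best.p, forced_at, pooled_sweep.best.r,
              pooled_sweep.best.n)],
            columns=table.columns,
        )
        model_fits[dv] = pd.concat([table, pooled_row], ignore_index=True)
        recovery[dv] = {"pooled_W": pooled_sweep.best.W}
    return model_fits, recovery, float(inter_r)


def run_pipeline(cfg: RunConfig, out_dir=None) -> RunReport:
    """Execute design, data, analysis, and model stages in order.

    Any stage failure raises :class:`StageError` naming the stage.
    Idempotent for a fixed config and seed.
    """
    cfg.validate()

    # -- design: matching grids must be displayable before anything runs
    try:
        grids = {
            float(h): build_matching_grid(
                h,
                cfg.grid_L_range[0], cfg.grid_L_range[1],
                cfg.grid_C_range[0], cfg.grid_C_range[1],
                cfg.grid_step, white_point=cfg.white_point,
                validate_gamut=cfg.grid_gamut_mode,
            )
            for h in cfg.hues
        }
    except GamutError as e:
        raise StageError(f"design stage: {e}") from e

    # -- data: simulate or load
    try:
        if cfg.synthetic:
            params = ObserverParams(
                **{**asdict(cfg.observer_params), "seed": cfg.seed}
            )
            dataset = make_dataset(
                params, cfg.hues, cfg.slants, cfg.reliefs, cfg.roughnesses,
                grids, cfg.n_matching_observers, cfg.n_choice_observers,
            )
        else:
            dataset = {
                "matching": pd.read_csv(cfg.matching_csv),
                "gloss": pd.read_csv(cfg.gloss_csv),
                "coverage": pd.read_csv(cfg.coverage_csv),
            }
    except StageError:
        raise
    except Exception as e:
        raise StageError(f"data stage: {e}") from e

    # -- analysis
    try:
        percepts = _percept_table(dataset, cfg)
    except Exception as e:
        raise StageError(f"analysis stage: {e}") from e

    anova = {}
    if cfg.run_anova:
        matching = (
            dataset.matching if isinstance(dataset, SyntheticDataset)
            else dataset["matching"]
        )
        per_obs = aggregate_matches(matching)
        n_obs = per_obs["observer"].nunique()
        if n_obs >= 2:
            factors = [
                f for f, levels in (
                    ("hue", cfg.hues), ("slant", cfg.slants),
                    ("relief", cfg.reliefs), ("roughness", cfg.roughnesses),
                ) if len(levels) >= 2
            ]
            for dv, col in (("saturation", "mean_S"), ("lightness", "mean_L")):
                try:
                    anova[dv] = rm_anova(per_obs, col, factors)
                except ValueError as e:
                    raise StageError(f"analysis stage (anova): {e}") from e

    # -- model fitting
    try:
        model_fits, recovery, inter_r = _fit_tables(percepts, cfg)
    except Exception as e:
        raise StageError(f"model stage: {e}") from e

    if cfg.synthetic:
        recovery["true_W_sat"] = cfg.observer_params.true_W_sat
        recovery["true_W_light"] = cfg.observer_params.true_W_light

    report = RunReport(
        percepts=percepts,
        model_fits=model_fits,
        anova=anova,
        recovery=recovery,
        inter_correlation=inter_r,
        config_echo=cfg.echo(),
        seed=cfg.seed,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        percepts.to_csv(out / "percepts.csv", index=False)
        paths["percepts"] = str(out / "percepts.csv")
        for dv, table in model_fits.items():
            p = out / f"model_fits_{dv}.csv"
            table.to_csv(p, index=False)
            paths[f"model_fits_{dv}"] = str(p)
        for dv, table in anova.items():
            p = out / f"anova_{dv}.csv"
            table.to_csv(p, index=False)
            paths[f"anova_{dv}"] = str(p)
        # artifact names are stored relative to the report so two runs into
        # different directories stay byte-identical
        summary = {
            "seed": cfg.seed,
            "version": __version__,
            "inter_correlation": inter_r,
            "recovery": recovery,
            "config": cfg.echo(),
            "artifacts": sorted(Path(p).name for p in paths.values()),
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        paths["report"] = str(out / "report.json")
        report.artifacts = paths
    return report
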