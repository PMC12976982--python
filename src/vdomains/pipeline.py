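"""End-to-end workflow: generate -> preprocess -> calibrate -> transfer ->
surface -> scenarios, with YAML configuration and a run manifest.

Each stage writes plain-text artifacts (CSV/YAML) into the run directory,
so later stages can resume from an earlier run.  Re-running with the same
configuration reproduces every artifact bit-for-bit apart from timing
entries in the manifest.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (CalibratedModel, CalibrationSpec, FAILURE_PENALTY,
                        fit_location)
from .errors import ConfigurationError
from .gp import fit_gp
from .phenoflex import PhenoFlexParams
from .scenarios import (build_validation_groups, default_scenarios,
                        fit_baseline, scenario_overlay, simulate_weather)
from .surface import DEFAULT_THRESHOLD, delineate, krige_matrix
from .synthetic import SyntheticConfig, generate_dataset
from .thermal import read_weather_csv, filter_complete_seasons, fill_gaps
from .transfer import (LocationDataset, TransferMatrix, build_matrix,
                       datasets_from_synthetic)


@dataclass
class RunConfig:
    """Single-file configuration of a full pipeline run."""

    out_dir: str = "runs/demo"
    approach: str = "both"             # "process", "ml" or "both"
    seed: int = 0
    # synthetic data (used unless weather/phenology CSV paths are given)
    n_locations: int = 6
    mean_temp_range: tuple[float, float] = (6.0, 17.0)
    years_range: tuple[int, int] = (20, 20)
    obs_noise_sd: float = 1.5
    weather_csv: str | None = None
    phenology_csv: str | None = None
    # preprocessing / evaluation
    max_missing_days: int = 6
    penalty: float = FAILURE_PENALTY
    # calibration
    budget: int = 1500
    restarts: int = 1
    # surface
    resolution: float = 0.1
    threshold: float = DEFAULT_THRESHOLD
    # scenarios
    run_scenarios: bool = True
    n_simulations: int = 100
    group_bin_width: float = 0.5
    group_cap: int = 30
    group_range: tuple[float, float] | None = None  # None = derive from data

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        for key in ("mean_temp_range", "years_range", "group_range"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


class Pipeline:
    """Stage-by-stage runner; stages may be re-run from on-disk artifacts."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.timings: dict[str, float] = {}
        self.datasets: dict[str, LocationDataset] | None = None
        self.process_models: dict[str, CalibratedModel] | None = None
        self.gp_models: dict | None = None
        self.matrices: dict[str, TransferMatrix] = {}

    # -- stage: data ----------------------------------------------------
    def stage_data(self) -> None:
        t0 = time.perf_counter()
        cfg = self.config
        if cfg.weather_csv and cfg.phenology_csv:
            seasons = read_weather_csv(cfg.weather_csv)
            seasons = [
                fill_gaps(s)
                for s in filter_complete_seasons(seasons, cfg.max_missing_days)
            ]
            phen = pd.read_csv(cfg.phenology_csv)
            datasets = {}
            for loc in sorted({s.location for s in seasons}):
                obs = phen[phen["location"] == loc].set_index("year")["bloom_doy"]
                ss = [s for s in seasons if s.location == loc and s.year in obs.index]
                if ss:
                    datasets[loc] = LocationDataset(
                        loc, ss[0].latitude, ss,
                        obs.loc[[s.year for s in ss]].to_numpy(float),
                    )
            self.datasets = datasets
        else:
            syn = generate_dataset(
                SyntheticConfig(
                    n_locations=cfg.n_locations,
                    mean_temp_range=cfg.mean_temp_range,
                    years_range=cfg.years_range,
                    obs_noise_sd=cfg.obs_noise_sd,
                    seed=cfg.seed,
                )
            )
            syn.write(self.out / "data")
            self.datasets = datasets_from_synthetic(syn)
        self.timings["data"] = time.perf_counter() - t0

    # -- stage: calibrate -----------------------------------------------
    def stage_calibrate(self) -> None:
        if self.datasets is None:
            self.stage_data()
        t0 = time.perf_counter()
        cfg = self.config
        mdir = self.out / "models"
        mdir.mkdir(exist_ok=True)
        if cfg.approach in ("process", "both"):
            self.process_models = {}
            for li, (loc, ds) in enumerate(sorted(self.datasets.items())):
                spec = CalibrationSpec(
                    budget=cfg.budget, restarts=cfg.restarts,
                    penalty=cfg.penalty,
                    seed=int(np.random.default_rng((cfg.seed, 11, li)).integers(2**31 - 1)),
                )
                model = fit_location(
                    ds.hourly, ds.observed, spec, location=loc, t_calib=ds.t_mean
                )
                self.process_models[loc] = model
                with open(mdir / f"{loc}_process.yaml", "w") as fh:
                    yaml.safe_dump(
                        {
                            "location": loc,
                            "t_calib": model.t_calib,
                            "rmse": model.rmse,
                            "n_seasons": model.n_seasons,
                            "params": model.params.to_dict(),
                            "diagnostics": model.diagnostics,
                        },
                        fh,
                    )
        if cfg.approach in ("ml", "both"):
            self.gp_models = {}
            for li, (loc, ds) in enumerate(sorted(self.datasets.items())):
                model = fit_gp(
                    ds.features, ds.observed,
                    seed=int(np.random.default_rng((cfg.seed, 13, li)).integers(2**31 - 1)),
                    location=loc, t_calib=ds.t_mean,
                )
                self.gp_models[loc] = model
                with open(mdir / f"{loc}_ml.yaml", "w") as fh:
                    yaml.safe_dump(
                        {
                            "location": loc,
                            "t_calib": model.t_calib,
                            "rmse": model.rmse,
                            "hyperparameters": model.hyperparameters,
                        },
                        fh,
                    )
        self.timings["calibrate"] = time.perf_counter() - t0

    def load_process_models(self) -> None:
        """Rebuild process models from a previous run's YAML files."""
        self.process_models = {}
        for path in sorted((self.out / "models").glob("*_process.yaml")):
            with open(path) as fh:
                raw = yaml.safe_load(fh)
            self.process_models[raw["location"]] = CalibratedModel(
                location=raw["location"],
                params=PhenoFlexParams(**raw["params"]),
                rmse=raw["rmse"],
                n_seasons=raw["n_seasons"],
                t_calib=raw["t_calib"],
                diagnostics=raw.get("diagnostics", {}),
            )

    # -- stage: transfer -------------------------------------------------
    def stage_transfer(self) -> None:
        if self.process_models is None and self.gp_models is None:
            self.stage_calibrate()
        t0 = time.perf_counter()
        cfg = self.config
        pairs = []
        if cfg.approach in ("process", "both"):
            pairs.append(("process", self.process_models))
        if cfg.approach in ("ml", "both"):
            pairs.append(("ml", self.gp_models))
        for name, models in pairs:
            matrix = build_matrix(models, self.datasets, name, cfg.penalty)
            self.matrices[name] = matrix
            matrix.to_frame().to_csv(self.out / f"transfer_{name}.csv", index=False)
            matrix.rmse_grid().to_csv(self.out / f"transfer_{name}_grid.csv")
        self.timings["transfer"] = time.perf_counter() - t0

    # -- stage: surface ---------------------------------------------------
    def stage_surface(self) -> None:
        if not self.matrices:
            self.stage_transfer()
        t0 = time.perf_counter()
        cfg = self.config
        self.surfaces = {}
        self.domains = {}
        for name, matrix in self.matrices.items():
            surf = krige_matrix(matrix, resolution=cfg.resolution)
            dom = delineate(surf, threshold=cfg.threshold)
            self.surfaces[name] = surf
            self.domains[name] = dom
            surf.to_frame().to_csv(self.out / f"surface_{name}.csv")
            dom.widths().to_csv(self.out / f"domain_{name}.csv", index=False)
        self.timings["surface"] = time.perf_counter() - t0

    # -- stage: scenarios --------------------------------------------------
    def stage_scenarios(self) -> None:
        if self.process_models is None:
            self.stage_calibrate()
        t0 = time.perf_counter()
        cfg = self.config
        means = np.array([ds.t_mean for ds in self.datasets.values()])
        if cfg.group_range is not None:
            grange = cfg.group_range
        else:
            lo = np.floor(means.min() * 2) / 2
            hi = np.ceil((means.max() + 1.0) * 2) / 2
            grange = (float(lo), float(hi))
        groups = build_validation_groups(
            self.datasets, cfg.group_bin_width, cfg.group_cap, grange, seed=cfg.seed
        )
        dists = []
        for loc, ds in sorted(self.datasets.items()):
            if ds.n_seasons < 10:  # too few seasons for a stable baseline
                continue
            baseline = fit_baseline(ds.seasons)
            for spec in default_scenarios(cfg.n_simulations, seed=cfg.seed):
                _, dist = simulate_weather(baseline, spec)
                dists.append(dist)
        overlay = scenario_overlay(
            self.process_models, groups, dists, cfg.penalty,
            resolution=max(cfg.resolution, 0.05),
        )
        overlay.to_csv(self.out / "overlay.csv", index=False)
        self.overlay = overlay
        self.timings["scenarios"] = time.perf_counter() - t0

    # -- manifest ---------------------------------------------------------
    def write_manifest(self) -> None:
        manifest = {
            "package_version": __version__,
            "config": asdict(self.config),
            "seed": self.config.seed,
            "n_locations": len(self.datasets) if self.datasets else 0,
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
        }
        with open(self.out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)


def run_pipeline(config: RunConfig) -> Pipeline:
    """Run every stage and return the populated pipeline object."""
    p = Pipeline(config)
    p.stage_data()
    p.stage_calibrate()
    p.stage_transfer()
    p.stage_surface()
    if config.run_scenarios:
        p.stage_scenarios()
    p.write_manifest()
    return p
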