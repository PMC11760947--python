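"""End-to-end orchestration: configuration, staging, manifest, seeding.

A pipeline run chains preprocess -> drivers -> (baseline, UDE ensemble) ->
sparse identification -> interpretation -> evaluation on either a
monitoring CSV or a named synthetic preset. Every output file is listed in
a manifest with its content digest, together with the master seed and the
config digest, so identical configurations reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import baseline as bl
from . import preprocessing as prep
from .drivers import DriverSet, fit_driver_set
from .interpretation import (contributions_frame, detect_growth_windows,
                             rank_contributions, ranking_frame, term_timeseries)
from .sindy import (build_library, evaluate_library, fit_sparse,
                    sample_derivatives, to_equations, tune_sparsity)
from .synthetic import make_two_bloom_preset, sample_monitoring, with_noise
from .ude import (EnsembleResult, NetworkSpec, TrainingConfig,
                  select_representative, train_ensemble)

logger = logging.getLogger(__name__)

_PRESETS = {"two_bloom": make_two_bloom_preset}


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DriverOrdersConfig(_Base):
    temp: int = 5
    sal: int = 4
    kd: int = 4


class NetworkConfig(_Base):
    hidden_layers: int = 4
    hidden_width: int = 16
    rate_scale: float = 0.02

    def widths(self) -> tuple[int, ...]:
        return (8, *([self.hidden_width] * self.hidden_layers), 5)


class TrainConfig(_Base):
    iterations: int = 500
    members: int = 20
    learning_rate: float = 0.05
    lr_schedule: str = "constant"
    w_length: float = 0.2
    w_angle: float = 0.8
    loss_on: str = "state"


class SindyConfig(_Base):
    penalty_grid: list[float] | None = None
    kappa: float | None = None
    state_jitter: float = 0.2
    n_repeats: int = 3


class WindowConfig(_Base):
    min_days: float = 5.0


class SyntheticConfig(_Base):
    noise_sd: float = 0.1
    missing_rate: float = 0.05
    n_years: int = 22
    n_stations: int = 5


class BaselineConfig(_Base):
    n_knots: int = 12
    smoothing: float | None = None


class PipelineConfig(_Base):
    """Validated, fully defaulted pipeline configuration."""

    input_csv: str | None = None
    synthetic_preset: str | None = "two_bloom"
    pattern: str = "two_bloom"
    train_years: tuple[int, int] = (2000, 2018)
    valid_years: tuple[int, int] = (2019, 2021)
    driver_orders: DriverOrdersConfig = DriverOrdersConfig()
    network: NetworkConfig = NetworkConfig()
    training: TrainConfig = TrainConfig()
    sindy: SindyConfig = SindyConfig()
    windows: WindowConfig = WindowConfig()
    synthetic: SyntheticConfig = SyntheticConfig()
    baseline: BaselineConfig = BaselineConfig()
    seed: int = 0
    outdir: str = "bloomdyn_out"

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    pass


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        bad = sorted({".".join(str(p) for p in e["loc"]) for e in exc.errors()})
        raise ConfigError(f"invalid configuration keys/values: {bad}") from exc


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


# -- stages ------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Generate synthetic records (or load the input CSV)."""
    if config.input_csv is not None:
        records = pd.read_csv(config.input_csv)
    else:
        if config.synthetic_preset not in _PRESETS:
            raise ConfigError(f"unknown preset {config.synthetic_preset!r}")
        system = _PRESETS[config.synthetic_preset](config.seed)
        system = with_noise(system, config.synthetic.noise_sd,
                            config.synthetic.missing_rate)
        system.n_years = config.synthetic.n_years
        system.n_stations = config.synthetic.n_stations
        records = sample_monitoring(system).records
    _write_csv(records, outdir / "records.csv")
    return records


def stage_preprocess(config: PipelineConfig, outdir: Path, records: pd.DataFrame):
    complete = prep.drop_incomplete(records)
    train, valid = prep.split_by_year(
        complete, range(config.train_years[0], config.train_years[1] + 1),
        range(config.valid_years[0], config.valid_years[1] + 1))
    spec = prep.TransformSpec.fit(train, config.pattern)
    std_train = prep.log_zscore(train, spec)
    std_valid = prep.log_zscore(valid, spec) if len(valid) else valid
    spec.to_yaml(outdir / "transform_spec.yaml")
    _write_csv(std_train, outdir / "standardized_train.csv")
    if len(std_valid):
        _write_csv(std_valid, outdir / "standardized_valid.csv")
    return spec, std_train, std_valid


def stage_drivers(config: PipelineConfig, outdir: Path, std_train) -> DriverSet:
    orders = {"temp": config.driver_orders.temp, "sal": config.driver_orders.sal,
              "kd": config.driver_orders.kd}
    drivers = fit_driver_set(std_train, orders)
    drivers.to_yaml(outdir / "drivers.yaml")
    return drivers


def stage_baseline(config: PipelineConfig, outdir: Path, std_train):
    """Cyclic-spline annual curve per state variable."""
    t_grid = np.arange(1.0, 366.0)
    smoothers, rows = {}, []
    for v in prep.STATE_VARS:
        sm = bl.fit_cyclic_smoother(std_train["day_of_year"], std_train[v],
                                    n_knots=config.baseline.n_knots,
                                    smoothing=config.baseline.smoothing,
                                    variable=v)
        smoothers[v] = sm
        fit = bl.predict_smoother(sm, t_grid)
        se = sm.standard_error(t_grid)
        rows.append(pd.DataFrame({"day": t_grid, "variable": v,
                                  "fit": fit, "se": se}))
    _write_csv(pd.concat(rows, ignore_index=True), outdir / "baseline_curves.csv")
    return smoothers


def stage_train_ude(config: PipelineConfig, outdir: Path, std_train,
                    drivers: DriverSet) -> EnsembleResult:
    spec = NetworkSpec(widths=config.network.widths(), seed=config.seed,
                       rate_scale=config.network.rate_scale)
    tcfg = TrainingConfig(iterations=config.training.iterations,
                          w_length=config.training.w_length,
                          w_angle=config.training.w_angle,
                          learning_rate=config.training.learning_rate,
                          lr_schedule=config.training.lr_schedule,
                          loss_on=config.training.loss_on,
                          seed=config.seed)
    ensemble = train_ensemble(std_train, drivers, spec, tcfg,
                              n_members=config.training.members)
    mean = pd.DataFrame(ensemble.mean_trajectory, columns=prep.STATE_VARS)
    mean.insert(0, "day", ensemble.t_grid)
    _write_csv(mean, outdir / "ude_mean_trajectory.csv")
    for k, member in enumerate(ensemble.members):
        member.to_json(outdir / f"ude_member_{k:02d}.json")
    return ensemble


def stage_sindy(config: PipelineConfig, outdir: Path, ensemble: EnsembleResult,
                drivers: DriverSet):
    library = build_library()
    rep = select_representative(ensemble)
    sample = sample_derivatives(rep, drivers,
                                state_jitter=config.sindy.state_jitter,
                                n_repeats=config.sindy.n_repeats,
                                seed=config.seed)
    grid = config.sindy.penalty_grid
    penalty = tune_sparsity(sample, library, kappa=config.sindy.kappa,
                            **({"penalty_grid": grid} if grid else {}))
    model = fit_sparse(sample, library, penalty)
    (outdir / "equations.txt").write_text(to_equations(model, library) + "\n")
    rows = []
    for eq, state in enumerate(model.state_names):
        for j in np.flatnonzero(model.coef[eq]):
            rows.append({"equation": state, "term": library.names[j],
                         "coefficient": model.coef[eq, j]})
    _write_csv(pd.DataFrame(rows), outdir / "sindy_coefficients.csv")
    return library, model, sample


def stage_interpret(config: PipelineConfig, outdir: Path, library, model, sample):
    terms = term_timeseries(model, sample, library, equation=0)
    _write_csv(contributions_frame(terms), outdir / "term_contributions.csv")
    base = sample.base()
    theta = evaluate_library(library, base.Z)
    chla = base.X[:, 0]
    dchla = theta @ model.coef[0]
    windows = detect_growth_windows(chla, dchla, base.t,
                                    min_days=config.windows.min_days)
    if windows and terms:
        rankings = rank_contributions(terms, windows)
        _write_csv(ranking_frame(rankings, config.pattern),
                   outdir / "term_rankings.csv")
    else:
        rankings = []
        logger.warning("no growth windows (or no active terms); rankings skipped")
    return windows, rankings


def stage_evaluate(config: PipelineConfig, outdir: Path, smoothers, ensemble,
                   std_train, std_valid):
    """Eq.-style MSE table: data vs baseline, data vs UDE mean, model vs model."""
    t_grid = ensemble.t_grid
    rows = []
    for split_name, split in (("train", std_train), ("valid", std_valid)):
        if split is None or not len(split):
            continue
        for iv, v in enumerate(prep.STATE_VARS):
            obs_t = split["day_of_year"].to_numpy(dtype=float)
            obs_x = split[v].to_numpy(dtype=float)
            base_curve = bl.predict_smoother(smoothers[v], t_grid)
            ude_curve = ensemble.mean_trajectory[:, iv]
            rows.append({"split": split_name, "variable": v,
                         "comparison": "data_baseline",
                         "mse": bl.mse_data_model(obs_t, obs_x, t_grid, base_curve)})
            rows.append({"split": split_name, "variable": v,
                         "comparison": "data_ude_mean",
                         "mse": bl.mse_data_model(obs_t, obs_x, t_grid, ude_curve)})
            rows.append({"split": split_name, "variable": v,
                         "comparison": "baseline_ude_mean",
                         "mse": bl.mse_model_model(base_curve, ude_curve)})
    metrics = pd.DataFrame(rows)
    _write_csv(metrics, outdir / "metrics.csv")
    return metrics


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_digest": config.digest(), "seed": config.seed,
                "stages": [], "files": {}}
    t_start = time.time()

    def done(stage):
        manifest["stages"].append(stage)
        logger.info("stage %-12s done (%.1fs elapsed)", stage, time.time() - t_start)

    try:
        records = stage_simulate(config, outdir); done("simulate")
        spec, std_train, std_valid = stage_preprocess(config, outdir, records)
        done("preprocess")
        drivers = stage_drivers(config, outdir, std_train); done("drivers")
        smoothers = stage_baseline(config, outdir, std_train); done("baseline")
        ensemble = stage_train_ude(config, outdir, std_train, drivers)
        done("train_ude")
        library, model, sample = stage_sindy(config, outdir, ensemble, drivers)
        done("sindy")
        stage_interpret(config, outdir, library, model, sample); done("interpret")
        stage_evaluate(config, outdir, smoothers, ensemble, std_train, std_valid)
        done("evaluate")
    finally:
        for f in sorted(outdir.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][f.name] = _sha256(f)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    if len(manifest["stages"]) < 8:
        raise RuntimeError(
            f"pipeline stopped after stages {manifest['stages']}; see manifest")
    return manifest


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
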