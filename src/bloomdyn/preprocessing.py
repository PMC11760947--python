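"""Standardisation of scattered coastal monitoring records.

Monitoring programmes sample chlorophyll-a and nutrients roughly monthly,
but not on the same day each year, and often with single variables missing.
This module turns such records into pooled, log/z-scored day-of-year series
suitable for fitting a mean annual dynamic: concentrations are natural-log
transformed (they are approximately lognormal), z-scored with statistics
estimated from the training years only, and pooled across stations and
years per blooming pattern.

Light attenuation Kd (m^-1) is derived from Secchi depth where it is not
measured directly, via the empirical conversion Kd = 1.32 / Secchi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: the five dynamical state variables, in equation order
STATE_VARS = ["chla", "din", "dip", "totn", "totp"]
#: the three external drivers, in driver order
DRIVER_VARS = ["temp", "sal", "kd"]
#: all standardised variables
ALL_VARS = STATE_VARS + DRIVER_VARS

#: display names used in equation output and rankings
DISPLAY_NAMES = {
    "chla": "Chl-a", "din": "DIN", "dip": "DIP", "totn": "totN",
    "totp": "totP", "temp": "Temp", "sal": "Sal", "kd": "Kd",
}

#: Secchi-to-Kd conversion coefficient (m * m^-1)
KD_SECCHI_COEF = 1.32

#: additive shift (degC) applied to temperature before the log transform,
#: so that near- and sub-zero winter temperatures stay in the log domain
TEMP_SHIFT = 5.0

DEFAULT_TRAIN_YEARS = range(2000, 2019)
DEFAULT_VALID_YEARS = range(2019, 2022)


def secchi_to_kd(secchi):
    """Convert Secchi depth (m) to light attenuation Kd (m^-1).

    Uses the empirical relation Kd = 1.32 / Secchi. Accepts scalars or
    arrays; raises ``ValueError`` on non-positive depths.
    """
    s = np.asarray(secchi, dtype=float)
    if np.any(s[~np.isnan(s)] <= 0):
        raise ValueError("Secchi depth must be strictly positive")
    out = KD_SECCHI_COEF / s
    return out.item() if np.isscalar(secchi) else out


def to_day_of_year(date) -> int:
    """Ordinal day within the year, 1..365 (366 in leap years)."""
    ts = pd.Timestamp(date)
    return int(ts.dayofyear)


def derive_kd(records: pd.DataFrame) -> pd.DataFrame:
    """Fill missing ``kd`` from ``secchi`` where possible (non-destructive)."""
    df = records.copy()
    if "kd" not in df.columns:
        df["kd"] = np.nan
    if "secchi" in df.columns:
        fill = df["kd"].isna() & df["secchi"].notna()
        if fill.any():
            df.loc[fill, "kd"] = secchi_to_kd(df.loc[fill, "secchi"].to_numpy())
    return df


def drop_incomplete(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records where any state variable or driver is missing.

    ``kd`` is derived from ``secchi`` first, so a record lacking only Secchi
    but carrying a direct Kd measurement (or vice versa) is retained. The
    number of removed records is logged; an empty result is a warning,
    not an error.
    """
    df = derive_kd(records)
    complete = df[STATE_VARS + DRIVER_VARS].notna().all(axis=1)
    removed = int((~complete).sum())
    if removed:
        logger.info("drop_incomplete: removed %d of %d records", removed, len(df))
    out = df.loc[complete].reset_index(drop=True)
    if out.empty:
        logger.warning("drop_incomplete: no complete records remain")
    return out


def split_by_year(
    records: pd.DataFrame,
    train_years=DEFAULT_TRAIN_YEARS,
    valid_years=DEFAULT_VALID_YEARS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into training and validation sets by calendar year.

    Records outside both ranges are excluded (and counted in the log).
    Overlapping year ranges are a configuration error.
    """
    train_set, valid_set = set(train_years), set(valid_years)
    if train_set & valid_set:
        raise ValueError(f"train/validation years overlap: {sorted(train_set & valid_set)}")
    years = pd.to_datetime(records["date"]).dt.year
    train = records.loc[years.isin(train_set)].reset_index(drop=True)
    valid = records.loc[years.isin(valid_set)].reset_index(drop=True)
    n_excl = len(records) - len(train) - len(valid)
    if n_excl:
        logger.info("split_by_year: excluded %d records outside both ranges", n_excl)
    return train, valid


@dataclass
class TransformSpec:
    """Per-variable log/z-score statistics, estimated from training data.

    ``mean`` and ``sd`` are statistics of the natural-log transformed data
    (temperature is shifted by ``temp_shift`` degC before the log). The
    standard deviation is the sample (n-1) convention. A spec is estimated
    once per blooming pattern from the pooled training years and then
    applied unchanged to training and validation data alike.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    pattern: str = ""
    temp_shift: float = TEMP_SHIFT
    variables: list[str] = field(default_factory=lambda: list(ALL_VARS))

    def __post_init__(self):
        for v in self.variables:
            if self.sd[v] <= 0:
                raise ValueError(f"degenerate data: zero/negative sd for {v!r}")

    # -- estimation ---------------------------------------------------------

    @classmethod
    def fit(cls, records: pd.DataFrame, pattern: str = "") -> "TransformSpec":
        """Estimate log-space mean/sd per variable from (training) records."""
        mean, sd = {}, {}
        for v in ALL_VARS:
            x = records[v].dropna().to_numpy(dtype=float)
            logx = _safe_log(x, v)
            if len(logx) < 2:
                raise ValueError(f"not enough observations to standardise {v!r}")
            mean[v] = float(np.mean(logx))
            sd_v = float(np.std(logx, ddof=1))
            # a relative threshold: identical raw values leave only float
            # rounding in the log, which is not a usable scale
            if sd_v <= 1e-12 * max(1.0, abs(mean[v])):
                raise ValueError(f"degenerate data: constant variable {v!r}")
            sd[v] = sd_v
        return cls(mean=mean, sd=sd, pattern=pattern)

    # -- application --------------------------------------------------------

    def transform_values(self, values, variable: str):
        """Raw scale -> z-score for one variable."""
        logx = _safe_log(np.asarray(values, dtype=float), variable)
        return (logx - self.mean[variable]) / self.sd[variable]

    def inverse_values(self, z, variable: str):
        """z-score -> raw scale for one variable."""
        raw = np.exp(np.asarray(z, dtype=float) * self.sd[variable] + self.mean[variable])
        if variable == "temp":
            raw = raw - self.temp_shift
        return raw

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "temp_shift": self.temp_shift,
            "variables": list(self.variables),
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]), pattern=d.get("pattern", ""),
                   temp_shift=d.get("temp_shift", TEMP_SHIFT),
                   variables=list(d.get("variables", ALL_VARS)))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TransformSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _safe_log(x: np.ndarray, variable: str) -> np.ndarray:
    """Natural log with the temperature shift; domain-checked."""
    if variable == "temp":
        x = x + TEMP_SHIFT
    bad = x[~np.isnan(x)] <= 0
    if np.any(bad):
        raise ValueError(f"non-positive value in log transform of {variable!r}")
    return np.log(x)


def log_zscore(records: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """Standardise complete records into a pooled day-of-year series.

    Returns a frame with provenance columns (pattern, station_id, year,
    day_of_year) and one z-scored column per variable. Applying a spec to
    the training set it was estimated from yields per-variable mean 0 and
    sample sd 1 (to numerical precision).
    """
    dates = pd.to_datetime(records["date"])
    out = pd.DataFrame({
        "pattern": records["pattern"].to_numpy() if "pattern" in records else spec.pattern,
        "station_id": records["station_id"].to_numpy(),
        "year": dates.dt.year.to_numpy(),
        "day_of_year": dates.dt.dayofyear.to_numpy(),
    })
    for v in ALL_VARS:
        out[v] = spec.transform_values(records[v].to_numpy(dtype=float), v)
    return out
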