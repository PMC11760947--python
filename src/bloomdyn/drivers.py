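"""Continuous annual forcing functions for temperature, salinity and Kd.

The three external drivers are reduced to a mean annual dynamic by an
ordinary least-squares polynomial fit on the day-of-year axis, pooled over
all training years and stations of a blooming pattern. Temperature uses a
degree-5 polynomial, salinity and light attenuation degree 4. Fits are done
in rescaled time tau = t/366 for numerical conditioning; coefficients are
stored in ascending degree of tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .preprocessing import DRIVER_VARS

#: time rescaling constant: tau = day / TAU_SCALE
TAU_SCALE = 366.0

DOMAIN = (1.0, 366.0)

DEFAULT_ORDERS = {"temp": 5, "sal": 4, "kd": 4}


@dataclass
class DriverModel:
    """One fitted polynomial forcing function on the day-of-year axis."""

    variable: str
    coef: np.ndarray            # ascending degree, in tau = t/366
    order: int
    domain: tuple[float, float] = DOMAIN
    residual_rms: float = float("nan")

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if not np.all(np.isfinite(self.coef)):
            raise ValueError(f"non-finite coefficients for driver {self.variable!r}")
        if len(self.coef) != self.order + 1:
            raise ValueError("coefficient count must be order + 1")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        _check_domain(t, self.domain)
        return np.polynomial.polynomial.polyval(t / TAU_SCALE, self.coef)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "order": int(self.order),
            "coef": [float(c) for c in self.coef],
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "residual_rms": float(self.residual_rms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriverModel":
        return cls(variable=d["variable"], coef=np.asarray(d["coef"]),
                   order=int(d["order"]), domain=tuple(d["domain"]),
                   residual_rms=float(d.get("residual_rms", "nan")))


def fit_driver_polynomial(t_obs, y_obs, order: int, variable: str = "") -> DriverModel:
    """Least-squares polynomial fit of one driver on the day-of-year axis.

    Requires at least ``order + 1`` distinct day values; raises on
    rank-deficient designs.
    """
    t = np.asarray(t_obs, dtype=float)
    y = np.asarray(y_obs, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if len(np.unique(t)) < order + 1:
        raise ValueError(
            f"need at least {order + 1} distinct day values for an order-{order} fit"
        )
    tau = t / TAU_SCALE
    V = np.vander(tau, order + 1, increasing=True)
    coef, res, rank, _ = np.linalg.lstsq(V, y, rcond=None)
    if rank < order + 1:
        raise ValueError(f"rank-deficient polynomial design for {variable or 'driver'}")
    resid = y - V @ coef
    return DriverModel(variable=variable, coef=coef, order=order,
                       residual_rms=float(np.sqrt(np.mean(resid**2))))


@dataclass
class DriverSet:
    """The three forcing functions Temp(t), Sal(t), Kd(t), z-score scale."""

    models: dict[str, DriverModel] = field(default_factory=dict)

    def __post_init__(self):
        missing = [v for v in DRIVER_VARS if v not in self.models]
        if missing:
            raise ValueError(f"DriverSet missing drivers: {missing}")

    def __call__(self, t):
        """Evaluate all drivers; returns array with trailing axis (temp, sal, kd)."""
        t = np.asarray(t, dtype=float)
        return np.stack([self.models[v](t) for v in DRIVER_VARS], axis=-1)

    @property
    def domain(self) -> tuple[float, float]:
        return self.models[DRIVER_VARS[0]].domain

    def to_dict(self) -> dict:
        return {v: self.models[v].to_dict() for v in DRIVER_VARS}

    @classmethod
    def from_dict(cls, d: dict) -> "DriverSet":
        return cls(models={v: DriverModel.from_dict(d[v]) for v in DRIVER_VARS})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DriverSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def fit_driver_set(std_series, orders: dict | None = None) -> DriverSet:
    """Fit all three drivers from a standardised day-of-year series."""
    orders = dict(DEFAULT_ORDERS if orders is None else orders)
    models = {}
    for v in DRIVER_VARS:
        models[v] = fit_driver_polynomial(
            std_series["day_of_year"], std_series[v], orders[v], variable=v
        )
    return DriverSet(models=models)


def evaluate_drivers(drivers: DriverSet, t):
    """Evaluate a DriverSet at day(s) ``t`` (domain-checked, no extrapolation)."""
    return drivers(t)


def _check_domain(t: np.ndarray, domain) -> None:
    lo, hi = domain
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"day-of-year outside fit domain [{lo}, {hi}]")
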