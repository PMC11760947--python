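"""Cyclic-spline seasonal baseline and the MSE comparison metrics.

A descriptive counterpart to the dynamical model: each variable's annual
cycle is fitted by a penalised cyclic cubic regression spline on the
day-of-year axis, closing the year (the fitted curve and its first two
derivatives are continuous across the December/January wrap). This is a
pooled fixed-effect smoother; the full mixed-model treatment (station and
year random effects fitted by REML) is intentionally out of scope -- the
baseline serves only as a comparison curve for the dynamical fit.

The basis is the classical cyclic cubic regression spline construction:
coefficients are the function values at K equally spaced knots on the
annual circle, the spline between knots is the periodic natural cubic
interpolant, and the wiggliness penalty is the integrated squared second
derivative. The smoothing parameter is chosen by generalised
cross-validation when not supplied.

Model quality is summarised by two mean squared errors: data vs model
(mean over observations of the squared prediction error) and model vs
model (mean over a shared day grid of the squared difference between two
fitted curves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: annual period in days; day 366 is identified with day 1
PERIOD = 365.0

DOMAIN = (1.0, 366.0)


def _cyclic_matrices(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """B and D of the cyclic natural-spline system (K x K, circulant-like)."""
    K = len(h)
    B = np.zeros((K, K))
    D = np.zeros((K, K))
    for i in range(K):
        hm, hi = h[i - 1], h[i]
        B[i, i] = (hm + hi) / 3.0
        B[i, (i + 1) % K] += hi / 6.0
        B[i, (i - 1) % K] += hm / 6.0
        D[i, i] = -(1.0 / hm + 1.0 / hi)
        D[i, (i + 1) % K] += 1.0 / hi
        D[i, (i - 1) % K] += 1.0 / hm
    return B, D


@dataclass
class CyclicSmoother:
    """A fitted penalised cyclic cubic regression spline."""

    variable: str
    knots: np.ndarray          # K knot positions on [0, PERIOD)
    beta: np.ndarray           # function values at the knots
    smoothing: float
    F: np.ndarray              # maps knot values to knot second derivatives
    edf: float = float("nan")  # effective degrees of freedom at the chosen lambda
    sigma2: float = float("nan")
    cov: np.ndarray | None = None

    def basis(self, t) -> np.ndarray:
        """Design rows mapping knot values to spline values at days ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        _check_domain(t)
        u = np.mod(t - DOMAIN[0], PERIOD)
        K = len(self.knots)
        h = np.diff(np.append(self.knots, PERIOD))
        A = np.zeros((len(u), K))
        seg = np.minimum(np.searchsorted(self.knots, u, side="right") - 1, K - 1)
        for r, (x, i) in enumerate(zip(u, seg)):
            hi = h[i]
            dm = (self.knots[i] + hi) - x       # distance to right knot
            dp = x - self.knots[i]              # distance from left knot
            cm = dm**3 / (6 * hi) - hi * dm / 6
            cp = dp**3 / (6 * hi) - hi * dp / 6
            A[r, i] += dm / hi
            A[r, (i + 1) % K] += dp / hi
            A[r] += cm * self.F[i] + cp * self.F[(i + 1) % K]
        return A

    def __call__(self, t):
        out = self.basis(t) @ self.beta
        return out if np.ndim(t) else float(out[0])

    def standard_error(self, t) -> np.ndarray:
        """Pointwise standard error of the fitted curve."""
        if self.cov is None:
            raise ValueError("smoother was fitted without covariance")
        A = self.basis(t)
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", A, self.cov, A), 0.0))


def fit_cyclic_smoother(t_obs, y_obs, n_knots: int = 12,
                        smoothing: float | None = None,
                        variable: str = "") -> CyclicSmoother:
    """Penalised cyclic spline fit with GCV-chosen smoothing.

    ``t_obs`` are days of year in [1, 366]; requires at least ``n_knots``
    observations spread over the year (rank check on the design).
    """
    t = np.asarray(t_obs, dtype=float)
    y = np.asarray(y_obs, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if len(t) < n_knots:
        raise ValueError(f"need at least n_knots={n_knots} observations")
    knots = PERIOD * np.arange(n_knots) / n_knots
    h = np.diff(np.append(knots, PERIOD))
    B, D = _cyclic_matrices(h)
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D                      # integrated squared second derivative
    probe = CyclicSmoother(variable=variable, knots=knots,
                           beta=np.zeros(n_knots), smoothing=0.0, F=Binv_D)
    A = probe.basis(t)
    if np.linalg.matrix_rank(A) < n_knots:
        raise ValueError("degenerate design: observations do not span the year")
    AtA, Aty = A.T @ A, A.T @ y
    n = len(y)

    def solve(lam):
        M = AtA + lam * S
        beta = np.linalg.solve(M, Aty)
        edf = float(np.trace(np.linalg.solve(M, AtA)))
        rss = float(np.sum((y - A @ beta) ** 2))
        return beta, edf, rss, M

    if smoothing is None:
        grid = np.logspace(-4, 8, 40)
        gcv = []
        for lam in grid:
            _, edf, rss, _ = solve(lam)
            denom = max(n - edf, 1e-8)
            gcv.append(n * rss / denom**2)
        smoothing = float(grid[int(np.argmin(gcv))])
    beta, edf, rss, M = solve(float(smoothing))
    sigma2 = rss / max(n - edf, 1e-8)
    Minv = np.linalg.inv(M)
    cov = sigma2 * (Minv @ AtA @ Minv)
    return CyclicSmoother(variable=variable, knots=knots, beta=beta,
                          smoothing=float(smoothing), F=Binv_D, edf=edf,
                          sigma2=sigma2, cov=cov)


def predict_smoother(model: CyclicSmoother, t_grid) -> np.ndarray:
    """Deterministic evaluation of the fitted curve (domain-checked)."""
    return np.atleast_1d(model(np.asarray(t_grid, dtype=float)))


# -- MSE metrics -------------------------------------------------------------

def mse_data_model(obs_days, obs_values, pred_days, pred_values) -> float:
    """Mean squared error between observations and a fitted curve.

    The curve is given on a dense day grid and linearly interpolated to
    each observation's day.
    """
    t = np.asarray(obs_days, dtype=float)
    x = np.asarray(obs_values, dtype=float)
    if len(t) == 0:
        raise ValueError("need at least one observation")
    m = np.interp(t, np.asarray(pred_days, dtype=float),
                  np.asarray(pred_values, dtype=float))
    return float(np.mean((m - x) ** 2))


def mse_model_model(pred_a, pred_b) -> float:
    """Mean squared difference of two model curves on a common day grid."""
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"prediction grids differ: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _check_domain(t: np.ndarray) -> None:
    if np.any(t < DOMAIN[0]) or np.any(t > DOMAIN[1]):
        raise ValueError(f"day-of-year outside [{DOMAIN[0]}, {DOMAIN[1]}]")
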