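"""Sparse identification of the governing equations (SInDy stage).

The trained neural ODE is a black box; this module approximates it by a
sparse linear combination of second-order polynomial basis functions of the
five state variables and three drivers:

    dx_i/dt = sum_j c_ij * f_j(Chl-a, DIN, DIP, totN, totP, Temp, Sal, Kd)

with the library {1, 8 linear terms, 8 squares, 28 cross products} = 45
functions. Derivatives are harvested from the ANN itself (evaluated
directly, no finite differencing of noisy data), and each of the five
equations is fitted independently by an L1-penalised regression followed
by an unpenalised least-squares refit on the selected support (the
standard debiasing step, so coefficients are quantitatively
interpretable).

Identifiability note: a single annual trajectory is a one-dimensional
curve in the eight-dimensional input space, on which the 45 library
columns are strongly collinear. ``sample_derivatives`` therefore augments
the trajectory with a few state-jittered replicas (the ANN is queried
slightly off-manifold, where it interpolates), which restores support
identifiability; see docs/methods.md.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .preprocessing import ALL_VARS, DISPLAY_NAMES

logger = logging.getLogger(__name__)

#: coefficients with absolute value below this are snapped to exact zero,
#: so "active term" counts are well defined
ZERO_SNAP = 1e-8

#: default penalty grid for sparsity tuning (unit-norm column scale)
DEFAULT_PENALTY_GRID = tuple(np.logspace(-7, -3, 10))

#: sentinel: complexity weight scaled to the sample's own noise level
ADAPTIVE_KAPPA = None


@dataclass(frozen=True)
class BasisLibrary:
    """Ordered, named polynomial basis over states and drivers.

    Ordering is deterministic: constant, linear terms in declaration order,
    squares, then cross products in lexicographic pair order. For n inputs
    and order 2 the count is 1 + n + n(n+1)/2.
    """

    n_state: int = 5
    n_driver: int = 3
    order: int = 2
    input_names: tuple[str, ...] = ()
    terms: tuple[tuple[int, ...], ...] = ()   # () = constant, (i,) linear, (i,j) product

    @property
    def n_inputs(self) -> int:
        return self.n_state + self.n_driver

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def names(self) -> list[str]:
        out = []
        for t in self.terms:
            if not t:
                out.append("1")
            elif len(t) == 1:
                out.append(self.input_names[t[0]])
            elif t[0] == t[1]:
                out.append(f"{self.input_names[t[0]]}^2")
            else:
                out.append(f"{self.input_names[t[0]]}*{self.input_names[t[1]]}")
        return out


def build_library(n_state: int = 5, n_driver: int = 3, order: int = 2,
                  input_names=None) -> BasisLibrary:
    """Construct the polynomial basis library (order 1 or 2)."""
    if order not in (1, 2):
        raise ValueError(f"unsupported polynomial order {order}; use 1 or 2")
    n = n_state + n_driver
    if input_names is None:
        if (n_state, n_driver) == (5, 3):
            input_names = tuple(DISPLAY_NAMES[v] for v in ALL_VARS)
        else:
            input_names = tuple(f"x{i}" for i in range(n))
    if len(input_names) != n:
        raise ValueError("input_names length must equal n_state + n_driver")
    terms: list[tuple[int, ...]] = [()]
    terms += [(i,) for i in range(n)]
    if order == 2:
        terms += [(i, i) for i in range(n)]
        terms += [(i, j) for i in range(n) for j in range(i + 1, n)]
    return BasisLibrary(n_state=n_state, n_driver=n_driver, order=order,
                        input_names=tuple(input_names), terms=tuple(terms))


def evaluate_library(library: BasisLibrary, state, drivers=None) -> np.ndarray:
    """Evaluate all basis functions; rows = samples, columns = library order.

    ``state`` may already contain the drivers (shape (..., n_inputs)); if
    ``drivers`` is given separately the two are concatenated.
    """
    z = np.asarray(state, dtype=float)
    if drivers is not None:
        z = np.concatenate([z, np.asarray(drivers, dtype=float)], axis=-1)
    if z.shape[-1] != library.n_inputs:
        raise ValueError(f"expected {library.n_inputs} inputs, got {z.shape[-1]}")
    cols = []
    for t in library.terms:
        if not t:
            cols.append(np.ones(z.shape[:-1]))
        elif len(t) == 1:
            cols.append(z[..., t[0]])
        else:
            cols.append(z[..., t[0]] * z[..., t[1]])
    return np.stack(cols, axis=-1)


@dataclass
class DerivativeSample:
    """(state, driver, derivative) triples harvested from a model.

    The first ``len(t) `` rows of ``X``/``D``/``Xdot`` lie exactly on the
    simulated trajectory; subsequent blocks are jittered replicas of it.
    """

    t: np.ndarray          # day grid of the base trajectory
    X: np.ndarray          # (rows, 5) states
    D: np.ndarray          # (rows, 3) drivers
    Xdot: np.ndarray       # (rows, 5) derivatives from the model
    n_base: int = 0        # rows of the unjittered trajectory block

    def __post_init__(self):
        if not (len(self.X) == len(self.D) == len(self.Xdot)):
            raise ValueError("X, D, Xdot must have matching row counts")
        if not np.all(np.isfinite(self.Xdot)):
            raise ValueError("non-finite derivatives in sample")
        if self.n_base == 0:
            self.n_base = len(self.t)

    @property
    def Z(self) -> np.ndarray:
        return np.concatenate([self.X, self.D], axis=-1)

    def base(self) -> "DerivativeSample":
        """The unjittered on-trajectory block."""
        n = self.n_base
        return DerivativeSample(t=self.t, X=self.X[:n], D=self.D[:n],
                                Xdot=self.Xdot[:n], n_base=n)


def sample_derivatives(model, drivers, t_grid=None, state_jitter: float = 0.2,
                       n_repeats: int = 3, seed: int = 0) -> DerivativeSample:
    """Harvest (state, derivative) pairs from a trained UDE.

    The state trajectory comes from simulating the model over ``t_grid``
    (default daily grid 1..365); derivatives are the ANN output evaluated
    directly at those states (no finite differencing). ``n_repeats``
    state-jittered replicas (Gaussian sd ``state_jitter`` z-units) are
    appended for identifiability of the sparse fit.
    """
    from .ude import simulate_ude   # local import to avoid cycle

    if t_grid is None:
        t_grid = np.arange(1.0, 366.0)
    t_grid = np.asarray(t_grid, dtype=float)
    X = simulate_ude(model, model.x0, t_grid, drivers)
    D = drivers(t_grid)
    rng = np.random.default_rng(seed)
    Xs, Ds = [X], [D]
    for _ in range(n_repeats):
        Xs.append(X + rng.normal(0.0, state_jitter, X.shape))
        Ds.append(D)
    Xall = np.vstack(Xs)
    Dall = np.vstack(Ds)
    Xdot = model.rhs(Xall, Dall)
    return DerivativeSample(t=t_grid, X=Xall, D=Dall, Xdot=Xdot, n_base=len(t_grid))


@dataclass
class SparseModel:
    """Sparse coefficient matrix of the five governing equations."""

    coef: np.ndarray               # (5, n_library)
    penalty: float
    rss: np.ndarray                # per-equation residual sum of squares
    library_names: tuple[str, ...] = ()
    state_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(DISPLAY_NAMES[v] for v in ALL_VARS[:5]))

    @property
    def n_active(self) -> np.ndarray:
        return (self.coef != 0).sum(axis=1)

    def support(self) -> np.ndarray:
        return self.coef != 0

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """Fitted derivatives for evaluated library rows."""
        return theta @ self.coef.T


def fit_sparse(sample: DerivativeSample, library: BasisLibrary,
               penalty: float) -> SparseModel:
    """LASSO-then-refit sparse regression of derivatives on the library.

    Per equation: L1-penalised regression on unit-norm columns selects the
    support, then an unpenalised least-squares refit on that support
    de-biases the coefficients. Coefficients below ``ZERO_SNAP`` are
    snapped to exact zero. ``penalty=0`` reduces to ordinary least squares.
    """
    theta = evaluate_library(library, sample.Z)
    n_rows, n_feat = theta.shape
    if n_rows < n_feat:
        logger.warning("fit_sparse: %d rows < %d library functions", n_rows, n_feat)
    y = sample.Xdot
    n_eq = y.shape[1]
    coef = np.zeros((n_eq, n_feat))
    rss = np.zeros(n_eq)
    norms = np.linalg.norm(theta, axis=0)
    norms[norms == 0] = 1.0
    theta_n = theta / norms
    for eq in range(n_eq):
        if penalty == 0:
            c = _lstsq_refit(theta, y[:, eq], np.ones(n_feat, bool))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                lasso = Lasso(alpha=penalty, fit_intercept=False,
                              max_iter=100_000, tol=1e-10)
                lasso.fit(theta_n, y[:, eq])
            support = np.abs(lasso.coef_ / norms) > ZERO_SNAP
            c = _lstsq_refit(theta, y[:, eq], support)
        c[np.abs(c) < ZERO_SNAP] = 0.0
        coef[eq] = c
        resid = y[:, eq] - theta @ c
        rss[eq] = float(resid @ resid)
    return SparseModel(coef=coef, penalty=float(penalty), rss=rss,
                       library_names=tuple(library.names))


def _lstsq_refit(theta: np.ndarray, y: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Unpenalised least squares on the selected columns (min-norm on ties)."""
    c = np.zeros(theta.shape[1])
    if support.any():
        sub = theta[:, support]
        sol, _, rank, _ = np.linalg.lstsq(sub, y, rcond=None)
        if rank < sub.shape[1]:
            logger.info("fit_sparse refit: rank-deficient support (%d < %d); "
                        "minimum-norm solution used", rank, sub.shape[1])
        c[support] = sol
    return c


def tune_sparsity(sample: DerivativeSample, library: BasisLibrary,
                  penalty_grid=DEFAULT_PENALTY_GRID,
                  kappa: float | None = ADAPTIVE_KAPPA) -> float:
    """Select the penalty balancing accuracy against model complexity.

    Minimises total residual sum of squares plus ``kappa`` times the total
    active-term count; the selection is deterministic (first minimiser in
    ascending penalty order). The default ``kappa`` is adaptive,
    ``2 * sigma2 * ln(n_library)`` with ``sigma2`` the per-sample residual
    variance of the unpenalised fit -- an AIC/BIC-style per-term cost on
    the scale of the sample's own noise. On a noiseless sample this is
    ~0, and with ``kappa=0`` the smallest penalty in the grid wins, since
    the residual is non-increasing as the penalty decreases.
    """
    grid = sorted(float(p) for p in penalty_grid)
    if not grid:
        raise ValueError("empty penalty grid")
    if kappa is None:
        ols = fit_sparse(sample, library, 0.0)
        sigma2 = float(ols.rss.sum()) / sample.Xdot.size
        kappa = 2.0 * sigma2 * np.log(len(library))
    best_p, best_score = None, np.inf
    for p in grid:
        model = fit_sparse(sample, library, p)
        score = float(model.rss.sum()) + kappa * int(model.n_active.sum())
        if score < best_score - 1e-15:
            best_p, best_score = p, score
    return best_p


# -- textual equation export -------------------------------------------------

def to_equations(model: SparseModel, library: BasisLibrary) -> str:
    """Human-readable governing equations, active terms only, 6 sig. digits."""
    lines = []
    names = library.names
    for eq, state in enumerate(model.state_names):
        parts = []
        for j in np.flatnonzero(model.coef[eq]):
            c = model.coef[eq, j]
            term = f"{c:.6g}" if names[j] == "1" else f"{c:.6g}*{names[j]}"
            parts.append(term)
        rhs = " + ".join(parts).replace("+ -", "- ") if parts else "0"
        lines.append(f"d{state}/dt = {rhs}")
    return "\n".join(lines)


def parse_equations(text: str, library: BasisLibrary) -> np.ndarray:
    """Parse equations emitted by :func:`to_equations` back to a matrix."""
    name_to_idx = {n: i for i, n in enumerate(library.names)}
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    coef = np.zeros((len(lines), len(library)))
    for eq, line in enumerate(lines):
        rhs = line.split("=", 1)[1].strip()
        if rhs == "0":
            continue
        # normalise "a - b" to "a + -b" then split on " + "; variable names
        # such as Chl-a contain no spaced minus, so this is unambiguous
        rhs = rhs.replace(" - ", " + -")
        for part in rhs.split(" + "):
            part = part.strip()
            if "*" in part:
                val, name = part.split("*", 1)
                coef[eq, name_to_idx[name]] = float(val)
            else:
                coef[eq, name_to_idx["1"]] = float(part)
    return coef
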