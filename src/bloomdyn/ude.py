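"""Neural ODE (UDE) training against scattered day-of-year observations.

The right-hand side of the 5-variable system is a small multilayer
perceptron taking the current state (Chl-a, DIN, DIP, totN, totP) and the
three driver values (Temp, Sal, Kd) and returning the five time
derivatives.  Training simulates the ODE over the annual window,
evaluates the simulated trajectory at every observation's day of year,
and minimises a trajectory loss that combines the squared difference of
state-vector lengths with one minus the cosine similarity of paired state
vectors (weighted 0.2 / 0.8 by default).

Gradients are exact gradients of the discretised problem: the trajectory
is produced by a fixed-step classical Runge-Kutta (RK4) scheme and
reverse-mode differentiation is carried through every solver stage and
network evaluation by hand (discretise-then-optimise).  Separately,
:func:`simulate_ude` integrates a trained model with an adaptive solver
for downstream use.

Because the network starts from random weights, trained models vary; an
ensemble of independently initialised members is trained, its pointwise
mean trajectory is the headline fit, and the member closest to the mean
(smallest MSE) is handed to the sparse-identification stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import erf

from .drivers import DriverSet

logger = logging.getLogger(__name__)

N_STATE = 5
N_DRIVER = 3

#: state magnitude treated as a diverged simulation during training
TRAIN_BLOWUP = 1.0e3

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x):
    """Gaussian-error linear unit, exact (erf) form."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x):
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT2PI * np.exp(-0.5 * x * x)


@dataclass
class NetworkSpec:
    """Architecture of the right-hand-side network.

    Default: 8 inputs (5 states + 3 drivers), four hidden layers of 16
    GELU units, 5 linear outputs; Glorot-uniform initialisation. The
    network output is multiplied by ``rate_scale`` (z-units per day), which
    sets the magnitude of the initial vector field so that the first
    simulated trajectories stay bounded; the scaling is absorbed into the
    last layer during training and does not restrict the model class.
    """

    widths: tuple[int, ...] = (8, 16, 16, 16, 16, 5)
    activation: str = "gelu"
    init: str = "glorot"
    seed: int = 0
    rate_scale: float = 0.02

    def __post_init__(self):
        self.widths = tuple(int(w) for w in self.widths)
        if self.widths[0] != N_STATE + N_DRIVER:
            raise ValueError("input width must equal 5 states + 3 drivers")
        if self.widths[-1] != N_STATE:
            raise ValueError("output width must equal 5 states")
        if self.activation != "gelu" or self.init != "glorot":
            raise ValueError("only GELU activation with Glorot init is supported")

    @property
    def n_params(self) -> int:
        return sum(w_in * w_out + w_out
                   for w_in, w_out in zip(self.widths[:-1], self.widths[1:]))


@dataclass
class TrainingConfig:
    """Hyperparameters of the trajectory fit."""

    iterations: int = 500
    w_length: float = 0.2
    w_angle: float = 0.8
    learning_rate: float = 0.05
    lr_schedule: str = "constant"     # "constant", or "cosine" decay to lr/40
    solver_step: float = 1.0          # days, fixed-step RK4 used in training
    solver_rtol: float = 1e-6         # adaptive solver tolerance (inference)
    x0_day_max: float = 30.0          # observations this early anchor x0
    loss_on: str = "state"            # "state" or "displacement" vectors
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if abs(self.w_length + self.w_angle - 1.0) > 1e-12:
            raise ValueError("loss weights must sum to 1")
        if self.loss_on not in ("state", "displacement"):
            raise ValueError("loss_on must be 'state' or 'displacement'")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")


@dataclass
class UDEModel:
    """A (possibly trained) neural right-hand side plus its context."""

    spec: NetworkSpec
    params: list                       # [(W, b), ...]
    drivers: DriverSet | None = None
    x0: np.ndarray | None = None
    loss_history: list = field(default_factory=list)
    config: TrainingConfig | None = None

    def rhs(self, X, D) -> np.ndarray:
        """Network derivative for batched states X (n,5) and drivers D (n,3)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        D = np.atleast_2d(np.asarray(D, dtype=float))
        Z = np.concatenate([X, D], axis=1)
        A = Z
        last = len(self.params) - 1
        for layer, (W, b) in enumerate(self.params):
            A = A @ W.T + b
            if layer < last:
                A = gelu(A)
        return self.spec.rate_scale * A

    # -- checkpointing (plain JSON, text-only) ------------------------------

    def to_json(self, path):
        payload = {
            "spec": asdict(self.spec),
            "params": [[W.tolist(), b.tolist()] for W, b in self.params],
            "x0": None if self.x0 is None else self.x0.tolist(),
            "loss_history": [float(v) for v in self.loss_history],
            "config": None if self.config is None else asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path, drivers: DriverSet | None = None) -> "UDEModel":
        with open(path) as fh:
            d = json.load(fh)
        spec = NetworkSpec(**{**d["spec"], "widths": tuple(d["spec"]["widths"])})
        params = [(np.asarray(W), np.asarray(b)) for W, b in d["params"]]
        cfg = None if d.get("config") is None else TrainingConfig(**d["config"])
        x0 = None if d.get("x0") is None else np.asarray(d["x0"])
        return cls(spec=spec, params=params, drivers=drivers, x0=x0,
                   loss_history=list(d.get("loss_history", [])), config=cfg)


def init_network(spec: NetworkSpec, drivers: DriverSet | None = None) -> UDEModel:
    """Glorot-uniform initialised, untrained model (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    params = []
    for w_in, w_out in zip(spec.widths[:-1], spec.widths[1:]):
        limit = np.sqrt(6.0 / (w_in + w_out))
        W = rng.uniform(-limit, limit, size=(w_out, w_in))
        b = np.zeros(w_out)
        params.append((W, b))
    return UDEModel(spec=spec, params=params, drivers=drivers)


def simulate_ude(model: UDEModel, x0, t_grid, drivers: DriverSet | None = None,
                 rtol: float = 1e-6) -> np.ndarray:
    """Integrate the trained right-hand side with an adaptive solver.

    Returns the trajectory at the requested days (the first row equals
    ``x0`` exactly). Days must lie inside the driver fit domain.
    """
    drivers = drivers if drivers is not None else model.drivers
    t_grid = np.asarray(t_grid, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    lo, hi = drivers.domain
    if t_grid[0] < lo or t_grid[-1] > hi:
        raise ValueError(f"t_grid outside driver domain [{lo}, {hi}]")

    def fun(t, x):
        return model.rhs(x[None, :], drivers(t)[None, :])[0]

    sol = solve_ivp(fun, (t_grid[0], t_grid[-1]), x0, t_eval=t_grid,
                    rtol=rtol, atol=rtol * 1e-2, method="RK45")
    if not sol.success:
        raise RuntimeError(f"UDE simulation failed: {sol.message}")
    out = sol.y.T
    out[0] = x0
    return out


# -- trajectory loss ---------------------------------------------------------

def lda_loss(simulated, observed, w_length: float = 0.2, w_angle: float = 0.8):
    """Length/angle trajectory loss between paired state vectors.

    ``w_length`` weights the mean squared difference of vector norms,
    ``w_angle`` the mean (1 - cosine similarity). Pairs where either
    vector is exactly zero contribute zero to the angle term.
    """
    m = np.atleast_2d(np.asarray(simulated, dtype=float))
    y = np.atleast_2d(np.asarray(observed, dtype=float))
    if m.shape != y.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {y.shape}")
    if len(m) == 0:
        raise ValueError("need at least one pair of points")
    nm = np.linalg.norm(m, axis=1)
    ny = np.linalg.norm(y, axis=1)
    length_term = np.mean((nm - ny) ** 2)
    nz = (nm > 0) & (ny > 0)
    cos = np.zeros(len(m))
    cos[nz] = np.sum(m[nz] * y[nz], axis=1) / (nm[nz] * ny[nz])
    angle = np.where(nz, 1.0 - cos, 0.0)
    angle_term = np.mean(angle)
    return w_length * length_term + w_angle * angle_term


def _lda_loss_grad(m, y, w_length, w_angle):
    """Loss value and gradient with respect to the simulated points."""
    n = len(m)
    nm = np.linalg.norm(m, axis=1)
    ny = np.linalg.norm(y, axis=1)
    nz = (nm > 0) & (ny > 0)
    cos = np.zeros(n)
    cos[nz] = np.sum(m[nz] * y[nz], axis=1) / (nm[nz] * ny[nz])
    loss = w_length * np.mean((nm - ny) ** 2) + w_angle * np.mean(np.where(nz, 1 - cos, 0.0))
    grad = np.zeros_like(m)
    # length term: d/dm (|m|-|y|)^2 = 2(|m|-|y|) m/|m|
    mask = nm > 0
    grad[mask] += (w_length * 2.0 / n) * ((nm - ny)[mask] / nm[mask])[:, None] * m[mask]
    # angle term: d/dm (1 - cos) = -(y/(|m||y|) - cos * m/|m|^2)
    grad[nz] += (w_angle / n) * (
        cos[nz][:, None] * m[nz] / (nm[nz] ** 2)[:, None]
        - y[nz] / (nm[nz] * ny[nz])[:, None]
    )
    return loss, grad


# -- forward/backward through the RK4 discretisation -------------------------

def _mlp_forward(params, z, rate_scale):
    """Single-sample forward pass with caches for reverse mode."""
    caches = []
    a = z
    last = len(params) - 1
    for layer, (W, b) in enumerate(params):
        s = W @ a + b
        caches.append((a, s))
        a = gelu(s) if layer < last else s
    return rate_scale * a, caches


def _mlp_vjp(params, caches, g_out, rate_scale, grads):
    """Accumulate parameter gradients; return gradient w.r.t. the input."""
    g = g_out * rate_scale
    last = len(params) - 1
    for layer in range(last, -1, -1):
        a_in, s = caches[layer]
        ds = g if layer == last else g * gelu_grad(s)
        gW, gb = grads[layer]
        gW += np.outer(ds, a_in)
        gb += ds
        g = params[layer][0].T @ ds
    return g


def _rk4_forward(params, rate_scale, x0, d_half, h):
    """Fixed-step RK4 over the precomputed half-step driver table.

    Returns (trajectory, caches, ok). ``d_half[2*i]`` is the driver value
    at grid node i, ``d_half[2*i+1]`` at the midpoint after it.
    """
    n_steps = (len(d_half) - 1) // 2
    X = np.empty((n_steps + 1, N_STATE))
    X[0] = x0
    caches = []
    x = x0
    for i in range(n_steps):
        d0, dm, d1 = d_half[2 * i], d_half[2 * i + 1], d_half[2 * i + 2]
        k1, c1 = _mlp_forward(params, np.concatenate([x, d0]), rate_scale)
        k2, c2 = _mlp_forward(params, np.concatenate([x + 0.5 * h * k1, dm]), rate_scale)
        k3, c3 = _mlp_forward(params, np.concatenate([x + 0.5 * h * k2, dm]), rate_scale)
        k4, c4 = _mlp_forward(params, np.concatenate([x + h * k3, d1]), rate_scale)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > TRAIN_BLOWUP:
            return X[: i + 1], caches, False
        X[i + 1] = x
        caches.append((c1, c2, c3, c4))
    return X, caches, True


def _rk4_backward(params, rate_scale, caches, node_grads, h):
    """Reverse sweep through all RK4 steps; returns parameter gradients."""
    grads = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    n_steps = len(caches)
    g = node_grads[n_steps].copy()
    for i in range(n_steps - 1, -1, -1):
        c1, c2, c3, c4 = caches[i]
        gk4 = (h / 6.0) * g
        gx4 = _mlp_vjp(params, c4, gk4, rate_scale, grads)[:N_STATE]
        gk3 = (2 * h / 6.0) * g + h * gx4
        gx3 = _mlp_vjp(params, c3, gk3, rate_scale, grads)[:N_STATE]
        gk2 = (2 * h / 6.0) * g + 0.5 * h * gx3
        gx2 = _mlp_vjp(params, c2, gk2, rate_scale, grads)[:N_STATE]
        gk1 = (h / 6.0) * g + 0.5 * h * gx2
        gx1 = _mlp_vjp(params, c1, gk1, rate_scale, grads)[:N_STATE]
        g = g + gx1 + gx2 + gx3 + gx4 + node_grads[i]
    return grads


# -- training ----------------------------------------------------------------

def _prepare_observations(series, config):
    """Pooled (day, 5-vector) observations sorted by day, plus the x0 rule."""
    from .preprocessing import STATE_VARS

    df = series.sort_values("day_of_year")
    t_obs = df["day_of_year"].to_numpy(dtype=float)
    Y = df[STATE_VARS].to_numpy(dtype=float)
    if len(Y) == 0:
        raise ValueError("empty training series")
    if np.isnan(Y).any():
        raise ValueError("training series contains missing state values")
    early = t_obs <= config.x0_day_max
    x0 = Y[early].mean(axis=0) if early.any() else Y.mean(axis=0)
    return t_obs, Y, x0


def train_ude(series, drivers: DriverSet, spec: NetworkSpec,
              config: TrainingConfig) -> UDEModel:
    """Fit one network to the pooled day-of-year observations.

    Full-batch Adam on the exact gradient of the trajectory loss through
    the RK4 discretisation. A step whose simulation diverges is rejected:
    parameters are kept, the learning rate is halved, and the previous
    loss is recorded for that iteration.
    """
    t_obs, Y, x0 = _prepare_observations(series, config)
    model = init_network(spec, drivers)
    model.x0 = x0
    model.config = config

    h = float(config.solver_step)
    t0, t1 = 1.0, 366.0
    n_steps = int(round((t1 - t0) / h))
    d_half = drivers(t0 + 0.5 * h * np.arange(2 * n_steps + 1))

    # linear interpolation weights from grid nodes to observation days
    pos = np.clip((t_obs - t0) / h, 0.0, n_steps - 1e-9)
    i0 = np.floor(pos).astype(int)
    w1 = pos - i0

    params = model.params
    mom = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    vel = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    lr0 = float(config.learning_rate)
    lr_cut = 1.0                      # multiplicative cut from step rejections
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    adam_t = 0
    last_loss = np.inf
    history = []
    prev_params = None

    for it in range(config.iterations):
        if config.lr_schedule == "cosine" and config.iterations > 1:
            frac = it / (config.iterations - 1)
            lr = lr_cut * lr0 * (0.025 + 0.975 * 0.5 * (1 + np.cos(np.pi * frac)))
        else:
            lr = lr_cut * lr0
        X, caches, ok = _rk4_forward(params, spec.rate_scale, x0, d_half, h)
        if not ok:
            # reject the update that produced the divergence: roll back to
            # the previous parameters and retry with a smaller step
            if prev_params is not None:
                params = prev_params
            else:
                params = [(0.5 * W, 0.5 * b) for W, b in params]
            lr_cut *= 0.5
            logger.warning("train_ude: diverged simulation, step rejected; "
                           "learning rate scale reduced to %.3g", lr_cut * lr0)
            history.append(last_loss if np.isfinite(last_loss) else TRAIN_BLOWUP)
            continue
        prev_params = params
        M = (1 - w1)[:, None] * X[i0] + w1[:, None] * X[i0 + 1]
        if config.loss_on == "displacement":
            loss, gM_d = _lda_loss_grad(np.diff(M, axis=0), np.diff(Y, axis=0),
                                        config.w_length, config.w_angle)
            gM = np.zeros_like(M)
            gM[1:] += gM_d
            gM[:-1] -= gM_d
        else:
            loss, gM = _lda_loss_grad(M, Y, config.w_length, config.w_angle)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        node_grads = np.zeros_like(X)
        np.add.at(node_grads, i0, (1 - w1)[:, None] * gM)
        np.add.at(node_grads, i0 + 1, w1[:, None] * gM)
        grads = _rk4_backward(params, spec.rate_scale, caches, node_grads, h)

        adam_t += 1
        corr1 = 1 - beta1 ** adam_t
        corr2 = 1 - beta2 ** adam_t
        new_params = []
        for (W, b), (mW, mb), (vW, vb), (gW, gb) in zip(params, mom, vel, grads):
            mW[:] = beta1 * mW + (1 - beta1) * gW
            mb[:] = beta1 * mb + (1 - beta1) * gb
            vW[:] = beta2 * vW + (1 - beta2) * gW ** 2
            vb[:] = beta2 * vb + (1 - beta2) * gb ** 2
            W = W - lr * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
            b = b - lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
            new_params.append((W, b))
        params = new_params
        last_loss = float(loss)
        history.append(last_loss)

    model.params = params
    model.loss_history = history
    return model


@dataclass
class EnsembleResult:
    """A trained ensemble, its mean trajectory, and member diagnostics."""

    members: list
    t_grid: np.ndarray
    member_trajectories: np.ndarray    # (n_members, n_days, 5)
    mean_trajectory: np.ndarray        # (n_days, 5)
    member_mse: np.ndarray             # MSE of each member to the mean

    def __len__(self) -> int:
        return len(self.members)


def train_ensemble(series, drivers: DriverSet, spec: NetworkSpec,
                   config: TrainingConfig, n_members: int = 20,
                   t_grid=None) -> EnsembleResult:
    """Train ``n_members`` networks from distinct derived seeds.

    The ensemble mean is the pointwise average of member trajectories on a
    daily grid. Members whose training halts are reported and skipped; the
    ensemble continues as long as at least half survive.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if t_grid is None:
        t_grid = np.arange(1.0, 366.0)
    t_grid = np.asarray(t_grid, dtype=float)
    member_seeds = np.random.SeedSequence(config.seed).generate_state(n_members) % (2**31)
    members, trajs = [], []
    for m, mseed in enumerate(member_seeds):
        m_spec = NetworkSpec(widths=spec.widths, seed=int(mseed),
                             rate_scale=spec.rate_scale)
        try:
            model = train_ude(series, drivers, m_spec, config)
            traj = simulate_ude(model, model.x0, t_grid, drivers,
                                rtol=config.solver_rtol)
        except (FloatingPointError, RuntimeError) as exc:
            logger.warning("ensemble member %d halted: %s", m, exc)
            continue
        members.append(model)
        trajs.append(traj)
    if len(members) < max(1, n_members // 2):
        raise RuntimeError(f"only {len(members)}/{n_members} ensemble members survived")
    member_trajs = np.stack(trajs)
    mean_traj = member_trajs.mean(axis=0)
    mse = np.mean((member_trajs - mean_traj) ** 2, axis=(1, 2))
    return EnsembleResult(members=members, t_grid=t_grid,
                          member_trajectories=member_trajs,
                          mean_trajectory=mean_traj, member_mse=mse)


def select_representative(ensemble: EnsembleResult) -> UDEModel:
    """The member whose trajectory is closest (MSE) to the ensemble mean."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    best = int(np.argmin(ensemble.member_mse))   # argmin takes first on ties
    return ensemble.members[best]
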