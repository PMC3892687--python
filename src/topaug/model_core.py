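"""Dynamic models: ODE/SDE representation, simulation and structural transforms.

A :class:`DynModel` holds a drift vector field ``f(x, u, theta, t)``, an
optional diagonal diffusion parameterization (one non-negative coefficient
per state equation), an output map ``h(x)`` and parameter metadata.  The same
object serves as a deterministic ODE model (all diffusion entries absent or
zero) and as an SDE model

    dx = f(x, u, theta, t) dt + diag(sigma) dW,

where ``W`` is a vector Wiener process.  The diffusion magnitudes ``sigma``
represent *system noise*: the combined effect of intrinsic randomness and of
structural (topological) uncertainty in the drift.  Structural transforms —
:func:`reformulate_as_sde` and :func:`promote_parameter_to_state` — implement
the augmentation moves used by the workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "DynModel",
    "Dataset",
    "Trajectory",
    "ProportionalNoise",
    "FixedNoise",
    "simulate_ode",
    "simulate_sde",
    "reformulate_as_sde",
    "promote_parameter_to_state",
    "generate_observations",
]


class IntegrationFailure(RuntimeError):
    """Raised when the ODE solver meets a non-finite drift evaluation."""


@dataclass
class Trajectory:
    """A simulated (or inferred) path on a time grid.

    ``states`` has one row per grid point; ``meta`` records solver settings
    and, for stochastic paths, the seed.  ``variances`` is filled by the
    Kalman filter (per-point marginal variance diagonal) and is ``None`` for
    plain simulations.
    """

    times: np.ndarray
    states: np.ndarray
    meta: dict = field(default_factory=dict)
    variances: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states and times must have the same length")


@dataclass
class DynModel:
    """A dynamic model usable both as an ODE and as an SDE.

    Parameters are a flat named vector (``param_names``); diffusion
    magnitudes live inside that vector and are located through
    ``diffusion_params``, a list with one entry per state equation — the
    name of the sigma parameter driving that equation, or ``None`` for a
    deterministic equation.

    ``initial_state`` may be a plain vector or a callable ``theta -> x0``
    when initial conditions are (partly) estimated.
    """

    name: str
    state_names: list[str]
    param_names: list[str]
    drift: Callable[[np.ndarray, Optional[np.ndarray], np.ndarray, float], np.ndarray]
    output_map: Callable[[np.ndarray], np.ndarray]
    observable_names: list[str]
    initial_state: "np.ndarray | Callable[[np.ndarray], np.ndarray]"
    diffusion_params: list[Optional[str]] = field(default_factory=list)
    inputs: Optional[Callable[[float], np.ndarray]] = None
    stoichiometry: Optional[tuple[np.ndarray, Callable]] = None
    drift_jac: Optional[Callable] = None
    output_jac: Optional[Callable] = None
    init_known: bool = True
    t0: float = 0.0  # time at which initial_state applies

    def __post_init__(self) -> None:
        if not self.diffusion_params:
            self.diffusion_params = [None] * self.n_states
        if len(self.diffusion_params) != self.n_states:
            raise ValueError(
                "diffusion_params must have one entry per state equation "
                f"({len(self.diffusion_params)} given, {self.n_states} states)"
            )
        for nm in self.diffusion_params:
            if nm is not None and nm not in self.param_names:
                raise ValueError(f"diffusion parameter {nm!r} not in param_names")

    # -- basic introspection -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def is_stochastic(self) -> bool:
        return any(nm is not None for nm in self.diffusion_params)

    @property
    def sigma_names(self) -> list[str]:
        """Diffusion parameter names in state order (skipping deterministic rows)."""
        return [nm for nm in self.diffusion_params if nm is not None]

    def param_index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def x0(self, theta: np.ndarray) -> np.ndarray:
        if callable(self.initial_state):
            return np.asarray(self.initial_state(np.asarray(theta, float)), float)
        return np.asarray(self.initial_state, dtype=float)

    def u(self, t: float) -> Optional[np.ndarray]:
        return None if self.inputs is None else self.inputs(t)

    def sigma_vector(self, theta: np.ndarray) -> np.ndarray:
        """Per-state diffusion magnitudes (zero for deterministic equations)."""
        theta = np.asarray(theta, dtype=float)
        sig = np.zeros(self.n_states)
        for i, nm in enumerate(self.diffusion_params):
            if nm is not None:
                val = theta[self.param_index(nm)]
                if val < 0:
                    raise ValueError(f"diffusion magnitude {nm} must be >= 0, got {val}")
                sig[i] = val
        return sig

    def check_theta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"theta has shape {theta.shape}, model {self.name!r} expects ({self.n_params},)"
            )
        return theta

    def f(self, x: np.ndarray, theta: np.ndarray, t: float) -> np.ndarray:
        return np.asarray(self.drift(x, self.u(t), theta, t), dtype=float)

    def h(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.output_map(x), dtype=float))


# -- noise models -----------------------------------------------------------


@dataclass(frozen=True)
class ProportionalNoise:
    """Relative (proportional) measurement error: y = h(x) * (1 + rho * eps).

    The stored standard deviation for a generated point is ``rho * |h(x)|``
    (evaluated on the noiseless output).  ``y_floor`` guards the measurement
    variance when outputs approach zero during filtering.
    """

    rho: float
    y_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


@dataclass(frozen=True)
class FixedNoise:
    """Additive Gaussian noise with fixed standard deviation(s) per observable."""

    sd: "float | np.ndarray"


# -- dataset ---------------------------------------------------------------


@dataclass
class Dataset:
    """Discrete-time observations with per-point measurement SDs.

    ``values`` and ``sds`` are (n_times, n_observables); NaN marks an
    observable not measured at that time, which supports case studies with
    different schedules per observable.
    """

    times: np.ndarray
    values: np.ndarray
    sds: np.ndarray
    observable_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        if self.values.shape[0] == 1 and self.times.size > 1:
            self.values = self.values.T
            self.sds = self.sds.T
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if self.values.shape != (self.times.size, len(self.observable_names)):
            raise ValueError("values shape inconsistent with times/observables")
        if self.sds.shape != self.values.shape:
            raise ValueError("sds shape must match values shape")
        observed = ~np.isnan(self.values)
        if np.any(~np.isfinite(self.sds[observed])) or np.any(self.sds[observed] <= 0):
            raise ValueError("measurement SDs must be strictly positive where observed")

    @property
    def n_points(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    def observed_mask(self, k: int) -> np.ndarray:
        return ~np.isnan(self.values[k])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.times):
            for j, name in enumerate(self.observable_names):
                if not np.isnan(self.values[k, j]):
                    rows.append((t, name, self.values[k, j], self.sds[k, j]))
        return pd.DataFrame(rows, columns=["time", "observable", "value", "sd"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rho: Optional[float] = None,
                   y_floor: float = 1e-6) -> "Dataset":
        required = {"time", "observable", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"dataset table needs columns {sorted(required)}")
        if "sd" not in df.columns or df["sd"].isna().all():
            if rho is None:
                raise ValueError("no 'sd' column: a proportional coefficient rho is required")
            df = df.copy()
            df["sd"] = rho * np.maximum(np.abs(df["value"]), y_floor)
        names = list(pd.unique(df["observable"]))
        times = np.sort(df["time"].unique())
        values = np.full((times.size, len(names)), np.nan)
        sds = np.full_like(values, np.nan)
        t_index = {t: k for k, t in enumerate(times)}
        for _, row in df.iterrows():
            k, j = t_index[row["time"]], names.index(row["observable"])
            values[k, j] = row["value"]
            sds[k, j] = row["sd"]
        return cls(times, values, sds, names)

    @classmethod
    def from_csv(cls, path, rho: Optional[float] = None) -> "Dataset":
        return cls.from_frame(pd.read_csv(path), rho=rho)


# -- simulation -------------------------------------------------------------


def simulate_ode(model: DynModel, theta: np.ndarray, time_grid: Sequence[float],
                 rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Deterministic solution of the model's drift on ``time_grid``.

    Diffusion entries in ``theta`` are ignored.  The first grid point carries
    exactly the initial state.
    """
    theta = model.check_theta(theta)
    grid = np.asarray(time_grid, dtype=float)
    x0 = model.x0(theta)

    def rhs(t, x):
        dx = model.f(x, theta, t)
        if not np.all(np.isfinite(dx)):
            bad = model.state_names[int(np.argmax(~np.isfinite(dx)))]
            raise IntegrationFailure(
                f"non-finite drift for state {bad!r} at t={t:.6g} in model {model.name!r}"
            )
        return dx

    sol = solve_ivp(rhs, (grid[0], grid[-1]), x0, t_eval=grid, rtol=rtol,
                    atol=atol, method="LSODA")
    if not sol.success:
        raise IntegrationFailure(f"integration of {model.name!r} failed: {sol.message}")
    states = sol.y.T.copy()
    states[0] = x0
    return Trajectory(grid, states, meta={"rtol": rtol, "atol": atol})


def simulate_sde(model: DynModel, theta: np.ndarray, time_grid: Sequence[float],
                 n_paths: int = 1, seed: int = 0, substeps: int = 10,
                 clip_negative: bool = False) -> list[Trajectory]:
    """Euler–Maruyama sample paths of the SDE on ``time_grid``.

    The integration step is the minimum grid spacing divided by ``substeps``.
    With all diffusion magnitudes zero the scheme reduces to fixed-step Euler
    on the drift, so paths agree with :func:`simulate_ode` up to step-size
    discretization error.  ``clip_negative`` optionally floors states at zero
    after every step (concentrations cannot go negative physically; by
    default paths are left free and moment-based filtering handles signs).
    """
    theta = model.check_theta(theta)
    grid = np.asarray(time_grid, dtype=float)
    sigma = model.sigma_vector(theta)
    h = np.min(np.diff(grid)) / max(substeps, 1)
    rng = np.random.default_rng(seed)
    x0 = model.x0(theta)
    n = model.n_states

    paths = np.empty((n_paths, grid.size, n))
    x = np.tile(x0, (n_paths, 1))
    paths[:, 0] = x
    for k in range(grid.size - 1):
        t, t_next = grid[k], grid[k + 1]
        n_sub = max(1, int(np.ceil((t_next - t) / h - 1e-12)))
        dt = (t_next - t) / n_sub
        sq = np.sqrt(dt)
        for _ in range(n_sub):
            u = model.u(t)
            drift = np.stack([
                np.asarray(model.drift(x[p], u, theta, t), dtype=float)
                for p in range(n_paths)
            ])
            dW = rng.standard_normal((n_paths, n)) * sq
            x = x + drift * dt + sigma * dW
            if clip_negative:
                np.maximum(x, 0.0, out=x)
            t += dt
        paths[:, k + 1] = x
    return [Trajectory(grid, paths[p], meta={"seed": seed, "path": p, "substeps": substeps})
            for p in range(n_paths)]


# -- structural transforms --------------------------------------------------


def reformulate_as_sde(model: DynModel, prefix: str = "sigma") -> DynModel:
    """Attach one non-negative diffusion magnitude per state equation.

    The drift is unchanged; new parameters ``<prefix>_<state>`` are appended
    to ``param_names``.  Applying this to an already-stochastic model is an
    error: the augmentation workflow reformulates a deterministic model once.
    """
    if model.is_stochastic:
        raise ValueError(f"model {model.name!r} is already stochastic")
    new_names = [f"{prefix}_{s}" for s in model.state_names]
    clash = set(new_names) & set(model.param_names)
    if clash:
        raise ValueError(f"diffusion parameter names clash with existing: {sorted(clash)}")
    return replace(
        model,
        name=f"{model.name}_sde",
        param_names=list(model.param_names) + new_names,
        diffusion_params=list(new_names),
    )


def promote_parameter_to_state(model: DynModel, param: str, init: float = 0.0,
                               sigma_name: Optional[str] = None,
                               init_param: Optional[str] = None) -> DynModel:
    """Turn a drift parameter into a diffusion-driven auxiliary state.

    The new state has zero drift and its own diffusion magnitude, so its
    trajectory is shaped purely by the Wiener term — and, once conditioned on
    data through the filter, traces whatever time course the data demand of
    that parameter.  All drift occurrences of the parameter read the new
    state instead.

    When ``init_param`` is given, the promoted state's initial value becomes
    a new estimated parameter of that name (appended before the diffusion
    magnitude); otherwise it is fixed at ``init``.
    """
    if not model.is_stochastic:
        raise ValueError("promote_parameter_to_state expects a stochastic model")
    p_idx = model.param_index(param)
    sigma_name = sigma_name or f"sigma_{param}"
    if sigma_name in model.param_names:
        raise ValueError(f"parameter {sigma_name!r} already exists")

    old_drift, old_jac = model.drift, model.drift_jac
    old_x0, old_n = model.initial_state, model.n_states
    n_old_params = model.n_params

    def full_theta(x_ext, theta_red):
        th = np.empty(n_old_params)
        th[:p_idx] = theta_red[:p_idx]
        th[p_idx] = x_ext[old_n]
        th[p_idx:] = np.concatenate(([x_ext[old_n]], theta_red[p_idx:n_old_params - 1]))
        return th

    def new_drift(x, u, theta, t):
        th = full_theta(x, np.asarray(theta, float))
        dx = np.asarray(old_drift(x[:old_n], u, th, t), dtype=float)
        return np.concatenate([dx, [0.0]])

    new_jac = None
    if old_jac is not None:
        def new_jac(x, u, theta, t, _fd_step=1e-6):
            th = full_theta(x, np.asarray(theta, float))
            A = np.zeros((old_n + 1, old_n + 1))
            A[:old_n, :old_n] = old_jac(x[:old_n], u, th, t)
            # sensitivity of the drift to the promoted parameter, by central FD
            step = _fd_step * max(1.0, abs(x[old_n]))
            thp, thm = th.copy(), th.copy()
            thp[p_idx] += step
            thm[p_idx] -= step
            fp = np.asarray(old_drift(x[:old_n], u, thp, t), float)
            fm = np.asarray(old_drift(x[:old_n], u, thm, t), float)
            A[:old_n, old_n] = (fp - fm) / (2 * step)
            return A

    reduced_params = [p for p in model.param_names if p != param]
    if init_param is not None:
        if init_param in model.param_names:
            raise ValueError(f"parameter {init_param!r} already exists")
        init_idx = len(reduced_params)
        reduced_params = reduced_params + [init_param]
    reduced_params = reduced_params + [sigma_name]

    def new_x0(theta):
        th = np.asarray(theta, float)
        x_init = th[init_idx] if init_param is not None else init
        base = old_x0(full_theta(np.concatenate([np.zeros(old_n), [x_init]]), th)) \
            if callable(old_x0) else np.asarray(old_x0, float)
        return np.concatenate([base, [x_init]])

    new_output = model.output_map  # reads leading states only
    new_output_jac = None
    if model.output_jac is not None:
        old_oj = model.output_jac

        def new_output_jac(x):
            H_old = np.atleast_2d(np.asarray(old_oj(x[:old_n]), dtype=float))
            return np.hstack([H_old, np.zeros((H_old.shape[0], 1))])
    return replace(
        model,
        name=f"{model.name}_aux_{param}",
        state_names=list(model.state_names) + [param],
        param_names=reduced_params,
        drift=new_drift,
        drift_jac=new_jac,
        initial_state=new_x0,
        output_map=new_output,
        output_jac=new_output_jac,
        diffusion_params=list(model.diffusion_params) + [sigma_name],
        stoichiometry=None,
    )


# -- observation generation -------------------------------------------------


def generate_observations(traj: Trajectory, model: DynModel,
                          noise_model: "ProportionalNoise | FixedNoise",
                          seed: int = 0) -> Dataset:
    """Sample noisy observations of ``traj`` through the model's output map.

    Proportional mode: ``y_k = h(x(t_k)) * (1 + rho * eps_k)`` with standard
    normal ``eps_k``; the stored SD is ``rho * |h(x(t_k))|`` from the
    noiseless output.  Fixed mode adds homoskedastic Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    outputs = np.stack([model.h(x) for x in traj.states])
    K, m = outputs.shape
    if isinstance(noise_model, ProportionalNoise):
        rho = noise_model.rho
        values = outputs * (1.0 + rho * rng.standard_normal((K, m)))
        # SDs from the noiseless output; the output magnitude is floored at
        # y_floor so SDs stay strictly positive where the output touches zero
        sds = np.maximum(rho * np.maximum(np.abs(outputs), noise_model.y_floor),
                         1e-12)
    else:
        sd = np.broadcast_to(np.atleast_1d(np.asarray(noise_model.sd, float)), (m,))
        sds = np.tile(sd, (K, 1))
        values = outputs + sds * rng.standard_normal((K, m))
    return Dataset(traj.times, values, sds, list(model.observable_names),
                   meta={"seed": seed, "noise": noise_model.__class__.__name__})
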