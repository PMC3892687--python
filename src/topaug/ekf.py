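"""Continuous-discrete extended Kalman filter for SDE models.

Between observations the state mean and covariance follow the moment ODEs

    dm/dt = f(m, u, theta, t)
    dP/dt = A P + P A' + diag(sigma)^2,    A = df/dx |_m

integrated with a fixed-substep classical Runge–Kutta scheme.  At each
observation the standard EKF update applies with H = dh/dx |_m and the
per-point measurement covariance S_k.  The innovation-form negative
log-likelihood

    J(theta) = sum_k 1/2 [ e_k' Sigma_k^{-1} e_k + ln det(2 pi Sigma_k) ]

is the cost used everywhere downstream: it is a deterministic function of the
parameter point even though the model is stochastic, which is what makes
parameter-space exploration of SDE models tractable.

The relative sizes of the measurement covariance S and the system-noise
magnitudes sigma set the filter's weights of trust: with S negligible the
filtered means track the data; with sigma negligible they track the ODE
solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_core import Dataset, DynModel, IntegrationFailure, Trajectory

__all__ = ["EKFOptions", "FilterResult", "CostValue", "ekf_filter", "cost", "infer_states"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EKFOptions:
    """Numerical knobs for the moment propagation and update steps.

    substeps: RK4 steps per inter-observation interval (accuracy vs speed).
    guard: covariance entries above guard * data-scale**2 flag divergence;
        samplers must survive absurd parameter points, so divergence becomes
        a +inf cost rather than an exception.
    fd_step: relative step for central finite-difference Jacobians, used when
        a model does not register analytic Jacobians.
    p0_scale: initial marginal variance (same for all states); zero means the
        initial state is known exactly.
    """

    substeps: int = 6
    max_step: Optional[float] = None   # upper bound on the RK4 step length
    guard: float = 1e12
    fd_step: float = 1e-6
    p0_scale: float = 0.0


@dataclass
class FilterResult:
    """Per-observation filter quantities plus the total cost."""

    times: np.ndarray
    m_minus: np.ndarray
    P_minus: np.ndarray
    m_plus: np.ndarray
    P_plus: np.ndarray
    innovations: list = field(default_factory=list)   # variable length per time
    innovation_covs: list = field(default_factory=list)
    gains: list = field(default_factory=list)
    nll: float = np.inf
    diverged: bool = False

    def to_frame(self):
        import pandas as pd
        rows = []
        n = self.m_minus.shape[1]
        for k, t in enumerate(self.times):
            for i in range(n):
                rows.append((t, i, self.m_minus[k, i], self.m_plus[k, i],
                             self.P_plus[k, i, i]))
        return pd.DataFrame(rows, columns=["time", "state", "m_minus", "m_plus", "var_plus"])


@dataclass(frozen=True)
class CostValue:
    value: float
    n_points: int
    diverged: bool = False


def _fd_jacobian(model: DynModel, x: np.ndarray, theta: np.ndarray, t: float,
                 rel_step: float) -> np.ndarray:
    n = x.size
    A = np.empty((n, n))
    u = model.u(t)
    for i in range(n):
        step = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        fp = np.asarray(model.drift(xp, u, theta, t), float)
        fm = np.asarray(model.drift(xm, u, theta, t), float)
        A[:, i] = (fp - fm) / (2.0 * step)
    return A


def _fd_output_jacobian(model: DynModel, x: np.ndarray, rel_step: float) -> np.ndarray:
    h0 = model.h(x)
    H = np.empty((h0.size, x.size))
    for i in range(x.size):
        step = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        H[:, i] = (model.h(xp) - model.h(xm)) / (2.0 * step)
    return H


def _propagate(model: DynModel, theta: np.ndarray, m: np.ndarray, P: np.ndarray,
               t_start: float, t_end: float, Q: np.ndarray, opts: EKFOptions,
               mean_only: bool):
    """RK4 on the joint moment system from t_start to t_end."""
    if t_end <= t_start:
        return m, P
    if opts.max_step is not None:
        # step length governed by max_step: short gaps need few substeps
        n_sub = max(2, int(np.ceil((t_end - t_start) / opts.max_step - 1e-12)))
    else:
        n_sub = max(1, opts.substeps)
    dt = (t_end - t_start) / n_sub
    use_analytic = model.drift_jac is not None
    u_of = model.u
    drift = model.drift

    half = 0.5 * dt
    jac = model.drift_jac if use_analytic else \
        (lambda mm, uu, th, tt: _fd_jacobian(model, mm, th, tt, opts.fd_step))

    def rhs(mm, PP, tt, uu):
        A = jac(mm, uu, theta, tt)
        fm = np.asarray(drift(mm, uu, theta, tt), float)
        return fm, A @ PP + PP @ A.T + Q

    t = t_start
    for _ in range(n_sub):
        u1, u2, u3 = u_of(t), u_of(t + half), u_of(t + dt)
        if mean_only:
            k1 = np.asarray(drift(m, u1, theta, t), float)
            k2 = np.asarray(drift(m + half * k1, u2, theta, t + half), float)
            k3 = np.asarray(drift(m + half * k2, u2, theta, t + half), float)
            k4 = np.asarray(drift(m + dt * k3, u3, theta, t + dt), float)
            m = m + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            km1, kP1 = rhs(m, P, t, u1)
            km2, kP2 = rhs(m + half * km1, P + half * kP1, t + half, u2)
            km3, kP3 = rhs(m + half * km2, P + half * kP2, t + half, u2)
            km4, kP4 = rhs(m + dt * km3, P + dt * kP3, t + dt, u3)
            m = m + (dt / 6.0) * (km1 + 2 * km2 + 2 * km3 + km4)
            P = P + (dt / 6.0) * (kP1 + 2 * kP2 + 2 * kP3 + kP4)
            P = 0.5 * (P + P.T)
        t += dt
        if not np.all(np.isfinite(m)):
            raise _Divergence
    return m, P


class _Divergence(Exception):
    pass


def _floor_psd(P: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero (only when the cheap check trips)."""
    if np.any(np.diag(P) < 0):
        w, V = np.linalg.eigh(0.5 * (P + P.T))
        P = (V * np.maximum(w, 0.0)) @ V.T
    return 0.5 * (P + P.T)


def ekf_filter(model: DynModel, theta: np.ndarray, data: Dataset,
               options: Optional[EKFOptions] = None) -> FilterResult:
    """Run the continuous-discrete EKF over ``data``.

    Divergence (non-finite moments or covariance entries beyond the guard)
    yields ``diverged=True`` and an infinite cost instead of an exception, so
    that samplers can evaluate arbitrary parameter points safely.
    """
    opts = options or EKFOptions()
    theta = model.check_theta(theta)
    sigma = model.sigma_vector(theta)
    Q = np.diag(sigma ** 2)
    n = model.n_states

    m = model.x0(theta)
    P = opts.p0_scale * np.eye(n)
    mean_only = not np.any(sigma) and opts.p0_scale == 0.0

    data_scale = np.nanmax(np.abs(data.values))
    guard_level = opts.guard * max(1.0, data_scale) ** 2

    K_obs = data.times.size
    res = FilterResult(
        times=data.times.copy(),
        m_minus=np.full((K_obs, n), np.nan), P_minus=np.full((K_obs, n, n), np.nan),
        m_plus=np.full((K_obs, n), np.nan), P_plus=np.full((K_obs, n, n), np.nan),
    )
    nll = 0.0
    t_prev = model.t0
    if data.times[0] < t_prev - 1e-12:
        raise ValueError("data start before the model's initial time t0")

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            for k in range(K_obs):
                m, P = _propagate(model, theta, m, P, t_prev, data.times[k], Q,
                                  opts, mean_only)
                if not np.all(np.isfinite(m)) or (not mean_only and
                                                  (not np.all(np.isfinite(P)) or
                                                   np.max(np.abs(P)) > guard_level)):
                    raise _Divergence
                res.m_minus[k], res.P_minus[k] = m, P

                mask = data.observed_mask(k)
                if not np.any(mask):
                    res.m_plus[k], res.P_plus[k] = m, P
                    res.innovations.append(np.empty(0))
                    res.innovation_covs.append(np.empty((0, 0)))
                    res.gains.append(np.empty((n, 0)))
                    t_prev = data.times[k]
                    continue

                H_full = (model.output_jac(m) if model.output_jac is not None
                          else _fd_output_jacobian(model, m, opts.fd_step))
                H = H_full[mask]
                y = data.values[k, mask]
                S = np.diag(data.sds[k, mask] ** 2)
                e = y - model.h(m)[mask]
                Sig = H @ P @ H.T + S
                Sig = 0.5 * (Sig + Sig.T)
                try:
                    L = np.linalg.cholesky(Sig)
                except np.linalg.LinAlgError:
                    raise _Divergence
                alpha = np.linalg.solve(Sig, e)
                nll += 0.5 * (e @ alpha + 2.0 * np.sum(np.log(np.diag(L)))
                              + e.size * _LOG_2PI)
                Kg = P @ H.T @ np.linalg.inv(Sig)
                m = m + Kg @ e
                IKH = np.eye(n) - Kg @ H
                P = IKH @ P @ IKH.T + Kg @ S @ Kg.T  # Joseph form
                P = _floor_psd(P)
                if not np.all(np.isfinite(m)) or not np.isfinite(nll):
                    raise _Divergence

                res.m_plus[k], res.P_plus[k] = m, P
                res.innovations.append(e)
                res.innovation_covs.append(Sig)
                res.gains.append(Kg)
                t_prev = data.times[k]
    except (_Divergence, IntegrationFailure):
        res.diverged = True
        res.nll = np.inf
        return res

    res.nll = float(nll)
    return res


def cost(model: DynModel, theta: np.ndarray, data: Dataset,
         options: Optional[EKFOptions] = None) -> CostValue:
    """Innovation-form negative log-likelihood of ``theta``; +inf on divergence.

    Deterministic: identical inputs give bit-identical values.
    """
    try:
        res = ekf_filter(model, theta, data, options)
    except (ValueError, FloatingPointError):
        return CostValue(np.inf, data.n_points, diverged=True)
    if res.diverged or not np.isfinite(res.nll):
        return CostValue(np.inf, data.n_points, diverged=True)
    return CostValue(res.nll, data.n_points, diverged=False)


def infer_states(model: DynModel, theta: np.ndarray, data: Dataset,
                 grid: Optional[Sequence[float]] = None,
                 options: Optional[EKFOptions] = None) -> Trajectory:
    """Filtered state trajectory on ``grid`` (default: the observation times).

    Runs the filter, then re-propagates the updated moments forward between
    observations, snapshotting mean and variance diagonal at the requested
    grid times.  Returns the filtered means with per-point variances.
    """
    opts = options or EKFOptions()
    res = ekf_filter(model, theta, data, opts)
    if res.diverged:
        raise IntegrationFailure(f"filter diverged for model {model.name!r}")
    if grid is None:
        var = np.stack([np.diag(P) for P in res.P_plus])
        return Trajectory(res.times, res.m_plus, meta={"filtered": True}, variances=var)

    grid = np.asarray(grid, dtype=float)
    theta = model.check_theta(theta)
    sigma = model.sigma_vector(theta)
    Q = np.diag(sigma ** 2)
    n = model.n_states
    out_m = np.full((grid.size, n), np.nan)
    out_v = np.full((grid.size, n), np.nan)

    # segment boundaries: t0, observation times; within each segment propagate
    # from the segment-start moments and record grid crossings
    seg_starts = [(model.t0, model.x0(theta), opts.p0_scale * np.eye(n))]
    for k in range(res.times.size):
        seg_starts.append((res.times[k], res.m_plus[k], res.P_plus[k]))
    seg_ends = list(res.times) + [max(grid[-1], res.times[-1])]

    for (t_a, m_a, P_a), t_b in zip(seg_starts, seg_ends):
        sel = (grid > t_a + 1e-12) & (grid <= t_b + 1e-12)
        # grid points exactly at a segment start take the updated moments
        at_start = np.isclose(grid, t_a, rtol=0, atol=1e-9)
        out_m[at_start] = m_a
        out_v[at_start] = np.diag(P_a)
        if not np.any(sel):
            continue
        cur_t, cur_m, cur_P = t_a, m_a.copy(), P_a.copy()
        for i in np.flatnonzero(sel):
            cur_m, cur_P = _propagate(model, theta, cur_m, cur_P, cur_t,
                                      grid[i], Q, opts, mean_only=False)
            cur_t = grid[i]
            out_m[i] = cur_m
            out_v[i] = np.diag(cur_P)

    # a grid point at an observation time gets the *updated* moments
    for k, t_k in enumerate(res.times):
        hit = np.isclose(grid, t_k, rtol=0, atol=1e-9)
        out_m[hit] = res.m_plus[k]
        out_v[hit] = np.diag(res.P_plus[k])

    if np.any(np.isnan(out_m)):
        bad = grid[np.any(np.isnan(out_m), axis=1)]
        raise ValueError(f"grid times outside the filterable range: {bad}")
    return Trajectory(grid, out_m, meta={"filtered": True}, variances=out_v)
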