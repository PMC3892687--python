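"""Glutamine transport in yeast across a metabolic shift.

Extracellular glutamine Q [mM] is consumed by a growing batch culture;
intracellular glutamine C [mM] is fed by permease-mediated uptake and drained
by degradation/consumption r2 = D*C.  The cell-count input enters as
phi(t) = U(t) Vc / Vf, the (dimensionless, logistically growing) ratio of
total cell volume to medium volume, so the external balance is

    dQ/dt = -phi(t) * r1,      dC/dt = r1 - D*C.

Model variants differ in the uptake rate r1:

    mm      r1 = V_max Q/(K_m+Q)                        (single MM permease)
    rmm     + W * V_2 Q/(K_2+Q)  with  dW/dt = k_w (1-W) * 1{Q <= K}
            (a regulated permease pool W in [0,1] that activates when
            external glutamine falls below the threshold K ~ 4 mM)
    e1rmm   + V_3 Q/(K_3+Q)                             (third, constitutive)
    e2rmm   + W * V_4 Q/(K_4+Q), K_4 micromolar         (fourth, regulated)
    mm_ext_W  SDE: mm uptake plus a hypothetical term W*Q/(K_2+Q) where W is
            a diffusion-driven auxiliary state (zero drift, magnitude
            sigma_W) — the augmentation probe used to discover the rMM form.

The activation gate 1{Q <= K} is smoothed by default (logistic in Q with a
small width) so that trajectories and Jacobians stay well-behaved; a hard
gate is available behind a flag.  The bounded form dW/dt = k_w (1-W) keeps
W in [0,1] and reproduces the observed saturation of the activation;
a "capped" literal form (dW/dt = k_w while gated, clipped at 1) is also
provided.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional

import numpy as np

from ..model_core import (Dataset, DynModel, ProportionalNoise,
                          generate_observations, reformulate_as_sde,
                          simulate_ode)
from . import constants as C
from .pk import CaseStudyBundle

__all__ = ["gln_model", "gln_generate", "gln_phi", "GLN_VARIANTS"]

GLN_VARIANTS = ("mm", "rmm", "e1rmm", "e2rmm", "mm_sde", "rmm_sde", "mm_ext_W")


def gln_phi(t: float) -> np.ndarray:
    """Cell-to-medium volume ratio of the logistically growing culture."""
    if np.ndim(t) == 0:
        return np.array([C.GLN_PHI_MAX /
                         (1.0 + math.exp(-C.GLN_PHI_RATE * (float(t) - C.GLN_PHI_TMID)))])
    return C.GLN_PHI_MAX / (1.0 + np.exp(-C.GLN_PHI_RATE * (np.asarray(t) - C.GLN_PHI_TMID)))


def _gate(Q: float, K: float, hard: bool) -> float:
    """Activation gate ~ 1{Q <= K}; smooth logistic by default."""
    if hard:
        return 1.0 if Q <= K else 0.0
    z = (Q - K) / C.GLN_GATE_WIDTH
    # clip to avoid overflow; exp(-40) is zero to double precision here
    return 1.0 / (1.0 + np.exp(np.clip(z, -40.0, 40.0)))


def _gate_dQ(Q: float, K: float, hard: bool) -> float:
    if hard:
        return 0.0
    g = _gate(Q, K, False)
    return -g * (1.0 - g) / C.GLN_GATE_WIDTH


def _make_gln(variant: str, hard_gate: bool = False,
              capped_w: bool = False) -> DynModel:
    has_w = variant in ("rmm", "e1rmm", "e2rmm")
    n_extra_mm = 1 if variant in ("e1rmm", "e2rmm") else 0
    n_extra_reg = 1 if variant == "e2rmm" else 0

    params = ["V_max", "K_m"]
    if has_w:
        params += ["V_2", "K_2"]
    params += ["D"]
    if has_w:
        params += ["k_w", "K"]
    if n_extra_mm:
        params += ["V_3", "K_3"]
    if n_extra_reg:
        params += ["V_4", "K_4"]
    p = {nm: i for i, nm in enumerate(params)}

    # substrate clamped at zero inside the rate laws: uptake vanishes for
    # non-positive external glutamine (also keeps the filter's linearization
    # away from the pole at Q = -K when a filtered mean dips below zero)
    def uptake(Q, W, th):
        Q = max(Q, 0.0)
        r = th[p["V_max"]] * Q / (th[p["K_m"]] + Q)
        if has_w:
            r += W * th[p["V_2"]] * Q / (th[p["K_2"]] + Q)
        if n_extra_mm:
            r += th[p["V_3"]] * Q / (th[p["K_3"]] + Q)
        if n_extra_reg:
            r += W * th[p["V_4"]] * Q / (th[p["K_4"]] + Q)
        return r

    def uptake_grads(Q, W, th):
        """(d r1/dQ, d r1/dW)"""
        if Q < 0.0:
            return 0.0, 0.0
        dQ = th[p["V_max"]] * th[p["K_m"]] / (th[p["K_m"]] + Q) ** 2
        dW = 0.0
        if has_w:
            dQ += W * th[p["V_2"]] * th[p["K_2"]] / (th[p["K_2"]] + Q) ** 2
            dW += th[p["V_2"]] * Q / (th[p["K_2"]] + Q)
        if n_extra_mm:
            dQ += th[p["V_3"]] * th[p["K_3"]] / (th[p["K_3"]] + Q) ** 2
        if n_extra_reg:
            dQ += W * th[p["V_4"]] * th[p["K_4"]] / (th[p["K_4"]] + Q) ** 2
            dW += th[p["V_4"]] * Q / (th[p["K_4"]] + Q)
        return dQ, dW

    if has_w:
        def drift(x, u, th, t):
            Q, Cc, W = x[0], x[1], x[2]
            r1 = uptake(Q, W, th)
            g = _gate(Q, th[p["K"]], hard_gate)
            dW = th[p["k_w"]] * g if capped_w and W < 1.0 else \
                th[p["k_w"]] * (1.0 - W) * g
            if capped_w and W >= 1.0:
                dW = 0.0
            return np.array([-u[0] * r1, r1 - th[p["D"]] * Cc, dW])

        def jac(x, u, th, t):
            Q, Cc, W = x[0], x[1], x[2]
            dQ, dW = uptake_grads(Q, W, th)
            g = _gate(Q, th[p["K"]], hard_gate)
            gq = _gate_dQ(Q, th[p["K"]], hard_gate)
            if capped_w:
                j_wq = th[p["k_w"]] * gq if W < 1.0 else 0.0
                j_ww = 0.0
            else:
                j_wq = th[p["k_w"]] * (1.0 - W) * gq
                j_ww = -th[p["k_w"]] * g
            return np.array([
                [-u[0] * dQ, 0.0, -u[0] * dW],
                [dQ, -th[p["D"]], dW],
                [j_wq, 0.0, j_ww],
            ])

        x0 = np.array([C.GLN_Q0, C.GLN_C0, C.GLN_W0])
        states = ["Q", "C", "W"]
    else:
        def drift(x, u, th, t):
            Q, Cc = x[0], x[1]
            r1 = uptake(Q, 0.0, th)
            return np.array([-u[0] * r1, r1 - th[p["D"]] * Cc])

        def jac(x, u, th, t):
            Q = x[0]
            dQ, _ = uptake_grads(Q, 0.0, th)
            return np.array([[-u[0] * dQ, 0.0], [dQ, -th[p["D"]]]])

        x0 = np.array([C.GLN_Q0, C.GLN_C0])
        states = ["Q", "C"]

    n_obs_states = 2

    def output(x):
        return np.asarray(x[:n_obs_states])

    H = np.zeros((2, len(states)))
    H[0, 0] = H[1, 1] = 1.0

    return DynModel(
        name=f"gln_{variant}",
        state_names=states,
        param_names=params,
        drift=drift,
        drift_jac=jac,
        output_map=output,
        output_jac=lambda x: H,
        observable_names=["Q", "C"],
        initial_state=x0,
        inputs=gln_phi,
        t0=C.GLN_T0,
    )


def _make_mm_ext_w(hard_gate: bool = False) -> DynModel:
    """SDE MM model plus a diffusion-driven hypothetical term W * Q/(K_2+Q).

    W has zero drift; its magnitude and time course are set entirely by its
    diffusion parameter sigma_W and by the data through the filter.  The
    regulated capacity V_2 is absorbed into the scale of W.  The
    concentration balances keep their own system-noise magnitudes (the
    extension is applied to the SDE model): without them, every transient
    misfit would be forced through W, contaminating the inferred activation
    time course with compensation modes.
    """
    params = ["V_max", "K_m", "K_2", "D", "sigma_Q", "sigma_C", "sigma_W"]
    p = {nm: i for i, nm in enumerate(params)}

    def drift(x, u, th, t):
        Q, Cc, W = max(x[0], 0.0), x[1], x[2]
        r1 = th[p["V_max"]] * Q / (th[p["K_m"]] + Q) + W * Q / (th[p["K_2"]] + Q)
        return np.array([-u[0] * r1, r1 - th[p["D"]] * Cc, 0.0])

    def jac(x, u, th, t):
        Q, Cc, W = x[0], x[1], x[2]
        if Q < 0.0:
            dQ, dW = 0.0, 0.0
        else:
            dQ = (th[p["V_max"]] * th[p["K_m"]] / (th[p["K_m"]] + Q) ** 2
                  + W * th[p["K_2"]] / (th[p["K_2"]] + Q) ** 2)
            dW = Q / (th[p["K_2"]] + Q)
        return np.array([
            [-u[0] * dQ, 0.0, -u[0] * dW],
            [dQ, -th[p["D"]], dW],
            [0.0, 0.0, 0.0],
        ])

    H = np.zeros((2, 3))
    H[0, 0] = H[1, 1] = 1.0
    return DynModel(
        name="gln_mm_ext_W",
        state_names=["Q", "C", "W"],
        param_names=params,
        drift=drift,
        drift_jac=jac,
        output_map=lambda x: np.asarray(x[:2]),
        output_jac=lambda x: H,
        observable_names=["Q", "C"],
        initial_state=np.array([C.GLN_Q0, C.GLN_C0, 0.0]),
        diffusion_params=["sigma_Q", "sigma_C", "sigma_W"],
        inputs=gln_phi,
        t0=C.GLN_T0,
    )


def gln_model(variant: str, hard_gate: bool = False,
              capped_w: bool = False) -> CaseStudyBundle:
    """Build a glutamine-transport bundle (see module docstring for variants)."""
    box = {nm: C.GLN_PRIOR_BOX[nm] for nm in C.GLN_PRIOR_BOX}
    if variant == "mm_ext_W":
        m = _make_mm_ext_w(hard_gate)
        return CaseStudyBundle(variant, m, box)
    if variant in ("mm_sde", "rmm_sde"):
        base = _make_gln(variant[:-4], hard_gate, capped_w)
        m = reformulate_as_sde(base)
        if variant == "rmm_sde":
            # the activation pool W is bounded and slow; system noise is only
            # attached to the two concentration balances
            m = replace(m, param_names=[q for q in m.param_names if q != "sigma_W"],
                        diffusion_params=["sigma_Q", "sigma_C", None])
        m.name = f"gln_{variant}"
        return CaseStudyBundle(variant, m, box)
    if variant in ("mm", "rmm", "e1rmm", "e2rmm"):
        m = _make_gln(variant, hard_gate, capped_w)
        theta = (dict(C.GLN_THETA_TRUE) if variant == "rmm" else None)
        return CaseStudyBundle(variant, m, box, theta_true=theta,
                               generate=gln_generate if variant == "rmm" else None)
    raise ValueError(f"unknown glutamine variant {variant!r}; choose from {GLN_VARIANTS}")


def gln_generate(seed: int = 0, rho: Optional[float] = None) -> Dataset:
    """Synthetic dataset: 14 intracellular + 23 extracellular glutamine points.

    Simulates the rMM truth across the metabolic shift at t = 0 and samples
    the two observables on their own schedules with proportional noise;
    bit-reproducible per seed.
    """
    bundle = gln_model("rmm")
    theta = bundle.theta_array()
    all_times = np.union1d(C.GLN_TIMES_EXTRA, C.GLN_TIMES_INTRA)
    grid = np.concatenate([[C.GLN_T0], all_times]) if all_times[0] > C.GLN_T0 \
        else all_times
    traj = simulate_ode(bundle.model, theta, grid)
    keep = np.isin(traj.times, all_times)
    traj.times, traj.states = traj.times[keep], traj.states[keep]

    noise = ProportionalNoise(rho if rho is not None else C.GLN_RHO,
                              y_floor=C.GLN_Y_FLOOR)
    ds = generate_observations(traj, bundle.model, noise, seed=seed)
    # mask each observable down to its own schedule
    extra_mask = np.isin(ds.times, C.GLN_TIMES_EXTRA)
    intra_mask = np.isin(ds.times, C.GLN_TIMES_INTRA)
    ds.values[~extra_mask, 0] = np.nan
    ds.sds[~extra_mask, 0] = np.nan
    ds.values[~intra_mask, 1] = np.nan
    ds.sds[~intra_mask, 1] = np.nan
    ds.meta.update({"case": "gln", "seed": seed, "rho": noise.rho})
    return ds
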