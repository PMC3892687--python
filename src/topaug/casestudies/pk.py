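"""Pharmacokinetic case study: oral drug absorption into blood plasma.

Two compartments: drug amount in the gastrointestinal tract Q [mg] and
concentration in blood plasma C [mg/l].  The data-generating ("truth") model
uses saturating Michaelis–Menten uptake,

    dQ/dt = -V_max Q / (K_m + Q)
    dC/dt = (1/V) V_max Q / (K_m + Q) - (C_L / V) C,

while the starting model of the augmentation workflow replaces the uptake
with mass-action kinetics r1 = k_A Q.  Only C is observed.  The model family
M1..M8 enumerates linear/nonlinear uptake crossed with the four ways of
eliminating the system-noise magnitudes {sigma_Q, sigma_C}:

    M1 linear  + sigma_Q + sigma_C     M5 nonlinear + sigma_Q + sigma_C
    M2 linear  + sigma_Q               M6 nonlinear + sigma_Q
    M3 linear  + sigma_C               M7 nonlinear + sigma_C
    M4 linear  (pure ODE)              M8 nonlinear (pure ODE)

M4 is the initial deterministic linear model; M8 is the final deterministic
nonlinear model (and the generator of the bundled synthetic data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from ..model_core import (DynModel, ProportionalNoise, Dataset,
                          generate_observations, promote_parameter_to_state,
                          reformulate_as_sde, simulate_ode)
from . import constants as C

__all__ = ["CaseStudyBundle", "pk_model", "pk_generate", "PK_VARIANTS"]


@dataclass
class CaseStudyBundle:
    """A bundled model plus everything needed to reproduce its study."""

    model_id: str
    model: DynModel
    box: dict                                  # param -> (lo, hi) log10
    theta_true: Optional[dict] = None          # generators only
    generate: Optional[Callable] = None        # seed -> Dataset
    notes: str = ""

    def box_array(self, names: Optional[list] = None) -> np.ndarray:
        names = names or self.model.param_names
        return np.array([self.box[nm] for nm in names], dtype=float)

    def theta_array(self) -> np.ndarray:
        return np.array([self.theta_true[nm] for nm in self.model.param_names])


# -- drift / jacobian definitions ------------------------------------------


def _mm_drift(x, u, th, t):
    # gut amount clamped at zero inside the rate law: no transport from an
    # empty compartment, and the filter's linearization stays off the pole
    # at Q = -K_m
    Q, Cc = max(x[0], 0.0), x[1]
    v_max, k_m, c_l, V = th[0], th[1], th[2], th[3]
    r1 = v_max * Q / (k_m + Q)
    return np.array([-r1, r1 / V - (c_l / V) * Cc])


def _mm_jac(x, u, th, t):
    Q = x[0]
    v_max, k_m, c_l, V = th[0], th[1], th[2], th[3]
    dr1 = v_max * k_m / (k_m + Q) ** 2 if Q >= 0.0 else 0.0
    return np.array([[-dr1, 0.0], [dr1 / V, -c_l / V]])


def _lin_drift(x, u, th, t):
    Q, Cc = x[0], x[1]
    k_a, c_l, V = th[0], th[1], th[2]
    r1 = k_a * Q
    return np.array([-r1, r1 / V - (c_l / V) * Cc])


def _lin_jac(x, u, th, t):
    k_a, c_l, V = th[0], th[1], th[2]
    return np.array([[-k_a, 0.0], [k_a / V, -c_l / V]])


def _observe_C(x):
    return np.array([x[1]])


_H_C = np.array([[0.0, 1.0]])


def _pk_base(nonlinear: bool) -> DynModel:
    if nonlinear:
        names, drift, jac = ["V_max", "K_m", "C_L", "V"], _mm_drift, _mm_jac
        mid = "mm"
    else:
        names, drift, jac = ["k_A", "C_L", "V"], _lin_drift, _lin_jac
        mid = "linear"
    return DynModel(
        name=f"pk_{mid}",
        state_names=["Q", "C"],
        param_names=names,
        drift=drift,
        drift_jac=jac,
        output_map=_observe_C,
        output_jac=lambda x: _H_C,
        observable_names=["C"],
        initial_state=np.array([C.PK_Q0, C.PK_C0]),
        t0=C.PK_T0,
    )


def _with_sigmas(model: DynModel, keep: tuple) -> DynModel:
    """SDE variant keeping only the named sigma channels (state order Q, C)."""
    sde = reformulate_as_sde(model)
    drop = [nm for nm in sde.sigma_names if nm not in keep]
    if not drop:
        return sde
    from dataclasses import replace
    new_params = [p for p in sde.param_names if p not in drop]
    new_diff = [None if nm in drop else nm for nm in sde.diffusion_params]
    return replace(sde, param_names=new_params, diffusion_params=new_diff,
                   name=sde.name + "_" + "".join("1" if d else "0" for d in new_diff))


_M_SERIES = {
    "M1": (False, ("sigma_Q", "sigma_C")),
    "M2": (False, ("sigma_Q",)),
    "M3": (False, ("sigma_C",)),
    "M4": (False, ()),
    "M5": (True, ("sigma_Q", "sigma_C")),
    "M6": (True, ("sigma_Q",)),
    "M7": (True, ("sigma_C",)),
    "M8": (True, ()),
}

PK_VARIANTS = ("truth", "linear", "linear_sde", "extended", "mm_final",
               "mm_final_sde") + tuple(_M_SERIES)


def pk_model(variant: str) -> CaseStudyBundle:
    """Build a pharmacokinetic bundle.

    Variants: ``truth``/``mm_final`` (nonlinear ODE), ``linear`` (ODE),
    ``linear_sde`` / ``mm_final_sde`` (both sigmas attached), ``extended``
    (linear SDE with k_A promoted to a diffusion-driven state, its initial
    value k_A0 estimated), and ``M1``..``M8``.
    """
    box = {nm: C.PK_PRIOR_BOX[nm] for nm in C.PK_PRIOR_BOX}
    wide = {nm: C.PK_WIDE for nm in C.PK_PRIOR_BOX}

    if variant in ("truth", "mm_final"):
        m = _pk_base(nonlinear=True)
        m.name = "pk_truth" if variant == "truth" else "pk_mm_final"
        return CaseStudyBundle(variant, m, box, theta_true=dict(C.PK_THETA_TRUE),
                               generate=pk_generate)
    if variant == "linear":
        return CaseStudyBundle(variant, _pk_base(nonlinear=False), box)
    if variant == "linear_sde":
        m = _with_sigmas(_pk_base(nonlinear=False), ("sigma_Q", "sigma_C"))
        m.name = "pk_linear_sde"
        return CaseStudyBundle(variant, m, wide)
    if variant == "mm_final_sde":
        m = _with_sigmas(_pk_base(nonlinear=True), ("sigma_Q", "sigma_C"))
        m.name = "pk_mm_final_sde"
        return CaseStudyBundle(variant, m, wide)
    if variant == "extended":
        sde = _with_sigmas(_pk_base(nonlinear=False), ("sigma_Q", "sigma_C"))
        m = promote_parameter_to_state(sde, "k_A", init_param="k_A0",
                                       sigma_name="sigma_k_A")
        m.name = "pk_extended"
        return CaseStudyBundle(variant, m, wide)
    if variant in _M_SERIES:
        nonlinear, keep = _M_SERIES[variant]
        m = _with_sigmas(_pk_base(nonlinear), keep) if keep else _pk_base(nonlinear)
        m.name = f"pk_{variant}"
        return CaseStudyBundle(variant, m, box,
                               theta_true=dict(C.PK_THETA_TRUE) if variant == "M8" else None)
    raise ValueError(f"unknown pharmacokinetic variant {variant!r}; "
                     f"choose from {PK_VARIANTS}")


def pk_generate(seed: int = 0, rho: Optional[float] = None) -> Dataset:
    """Synthetic 20-point dataset of plasma concentration C from the truth model.

    Proportional measurement noise (default rho = 0.1); bit-reproducible per
    seed.
    """
    bundle = pk_model("truth")
    theta = bundle.theta_array()
    traj = simulate_ode(bundle.model, theta, np.concatenate([[C.PK_T0], C.PK_TIMES]))
    traj.times, traj.states = traj.times[1:], traj.states[1:]
    noise = ProportionalNoise(rho if rho is not None else C.PK_RHO,
                              y_floor=C.PK_Y_FLOOR)
    ds = generate_observations(traj, bundle.model, noise, seed=seed)
    ds.meta.update({"case": "pk", "seed": seed, "rho": noise.rho})
    return ds
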