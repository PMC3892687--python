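"""Localizing missing structure: diffusion diagnosis, hidden trajectories, term matching.

Small system-noise magnitudes over the viable space mean the corresponding
drift equation already represents the system well; large (non-eliminable)
magnitudes point at the equation that needs repair.  :func:`diagnose`
automates the visual-inspection step by asking, for each noise magnitude and
each small subset of them, whether a viable parameter point exists with those
magnitudes in the lowest decade(s) of their box.

Once the faulty equation is known, an auxiliary diffusion-driven state is
added (see ``model_core.promote_parameter_to_state``) and its filtered
trajectory — aggregated over viable points with likelihood weights — traces
the time course of the missing mechanism (:func:`infer_hidden`).
:func:`match_term` then fits a small dictionary of simple rate-law families
to that trace and ranks them, suggesting a deterministic replacement term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .ekf import EKFOptions, infer_states
from .model_core import Dataset, DynModel, Trajectory
from .sampling import ViableSample

__all__ = ["DiffusionDiagnosis", "HiddenTrajectory", "diagnose", "infer_hidden",
           "match_term", "TermFit"]


@dataclass
class DiffusionDiagnosis:
    """Which noise magnitudes can be eliminated over the viable space."""

    sigma_ids: list[str]
    eliminable: dict                    # name -> bool | None ("unknown")
    jointly_eliminable: dict            # frozenset of names -> bool
    witnesses: dict                     # same keys -> witness point (log10) or None
    marginal_ranges: dict               # name -> (lo, hi) over viable points
    epsilon_log10: float = 1.0

    def report(self) -> str:
        lines = ["diffusion diagnosis (negligible = within "
                 f"{self.epsilon_log10} decade(s) of the box floor)"]
        for nm in self.sigma_ids:
            flag = self.eliminable[nm]
            word = "unknown" if flag is None else ("eliminable" if flag else "essential")
            rng = self.marginal_ranges.get(nm)
            extra = f"  viable range log10: [{rng[0]:.2f}, {rng[1]:.2f}]" if rng else ""
            lines.append(f"  {nm}: {word}{extra}")
        for key, ok in sorted(self.jointly_eliminable.items(),
                              key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            if len(key) > 1:
                lines.append(f"  {{{', '.join(sorted(key))}}}: "
                             f"{'jointly eliminable' if ok else 'NOT jointly eliminable'}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "sigma_ids": self.sigma_ids,
            "epsilon_log10": self.epsilon_log10,
            "eliminable": {k: v for k, v in self.eliminable.items()},
            "jointly_eliminable": {"+".join(sorted(k)): bool(v)
                                   for k, v in self.jointly_eliminable.items()},
            "marginal_ranges": {k: list(v) for k, v in self.marginal_ranges.items()},
        }


@dataclass
class HiddenTrajectory:
    """Likelihood-weighted band of an auxiliary state across viable points."""

    times: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    state_name: str
    n_points: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "mean": self.mean, "se": self.se})


def diagnose(sample: ViableSample, sigma_ids: Sequence[str],
             epsilon_log10: float = 1.0, max_subset: int = 3,
             costfn: Optional[Callable] = None,
             n_probe: int = 40) -> DiffusionDiagnosis:
    """Check single and joint eliminability of noise magnitudes.

    A subset is (jointly) eliminable when at least one stored viable point has
    *all* its members within ``epsilon_log10`` of the box lower edge, with all
    other parameters free.  Subset size is capped to bound combinatorics.

    When ``costfn`` is given, elimination candidates are probed actively: the
    subset's magnitudes are clamped to the negligibility floor at the best
    viable points and re-evaluated, and viable probes are merged back into the
    sample (re-anchoring the relative cutoff if a better optimum appears).
    Random-walk exploration alone rarely diffuses into a low-noise corner even
    when it is viable; clamped probes test that corner directly.
    """
    sigma_ids = list(sigma_ids)
    for nm in sigma_ids:
        if nm not in sample.param_names:
            raise KeyError(f"unknown sigma parameter {nm!r}")
    idx = {nm: sample.param_names.index(nm) for nm in sigma_ids}

    if costfn is not None and sample.n_viable > 0 and sample.rule is not None:
        subsets = [tuple([nm]) for nm in sigma_ids]
        for size in range(2, min(max_subset, len(sigma_ids)) + 1):
            subsets += list(combinations(sigma_ids, size))
        from .sampling import nm_polish

        vp_all = sample.viable_points()
        order = np.argsort(sample.costs[sample.viable_flags])[:n_probe]
        lo, hi = sample.box[:, 0], sample.box[:, 1]
        probes: list = []
        probe_costs: list = []

        def current_threshold():
            best_probe = min(probe_costs) if probe_costs else np.inf
            best = min(sample.best_cost, best_probe)
            if sample.rule.mode == "sde-relative":
                return best + sample.rule.delta_orders * np.log(10.0)
            return sample.rule.threshold

        def polish_subset(subset, z_start):
            free = [j for j in range(len(sample.param_names))
                    if j not in {idx[nm] for nm in subset}]

            def f_free(zf, z_fixed=z_start.copy(), free=free):
                z = z_fixed.copy()
                width = hi[free] - lo[free]
                zf = np.mod(np.asarray(zf) - lo[free], 2 * width)
                z[free] = lo[free] + np.where(zf > width, 2 * width - zf, zf)
                J = costfn(z)
                probes.append(z)
                probe_costs.append(J)
                return J if np.isfinite(J) else 1e300

            nm_polish(f_free, z_start[free], maxfev=200, restarts=1,
                      step=0.1 * (hi[free] - lo[free]))

        for subset in subsets:
            floor = {nm: sample.box[idx[nm], 0] + 0.5 * epsilon_log10
                     for nm in subset}
            clamped = vp_all[order].copy()
            for nm in subset:
                clamped[:, idx[nm]] = floor[nm]
            costs_c = np.array([costfn(z) for z in clamped])
            probes.extend(clamped)
            probe_costs.extend(costs_c)
            thr = current_threshold()
            if np.any(costs_c <= thr) or not np.any(np.isfinite(costs_c)):
                continue  # witness already found (or nothing to polish from)
            # polish the free dimensions: start from the best clamped
            # candidate and from the best earlier probe re-clamped (its free
            # coordinates are already tuned with fewer magnitudes eliminated)
            starts = [clamped[int(np.nanargmin(np.where(np.isfinite(costs_c),
                                                        costs_c, np.nan)))]]
            prior_probes = np.array(probes[:-len(clamped)]) if \
                len(probes) > len(clamped) else None
            if prior_probes is not None:
                pc = np.array(probe_costs[:-len(clamped)])
                z2 = prior_probes[int(np.nanargmin(
                    np.where(np.isfinite(pc), pc, np.nan)))].copy()
                for nm in subset:
                    z2[idx[nm]] = floor[nm]
                starts.append(z2)
            # neutral start: guards against exploration stuck in a spurious
            # basin whose free coordinates poison the local polish
            z3 = 0.5 * (lo + hi)
            for nm in subset:
                z3[idx[nm]] = floor[nm]
            starts.append(z3)
            for z_start in starts:
                mark = len(probe_costs)
                polish_subset(subset, z_start)
                if np.min(probe_costs[mark:]) <= current_threshold():
                    break  # this subset has its witness
        if probes:
            sample.merge(np.array(probes), np.array(probe_costs), chain_id=-4)

    vp = sample.viable_points()
    vcosts = sample.costs[sample.viable_flags]
    empty = vp.shape[0] == 0

    eliminable: dict = {}
    jointly: dict = {}
    witnesses: dict = {}
    ranges: dict = {}
    for nm in sigma_ids:
        if empty:
            eliminable[nm] = None
            continue
        lo = sample.box[idx[nm], 0]
        ranges[nm] = (float(vp[:, idx[nm]].min()), float(vp[:, idx[nm]].max()))
        hit = vp[:, idx[nm]] <= lo + epsilon_log10
        eliminable[nm] = bool(np.any(hit))
        witnesses[frozenset([nm])] = (vp[hit][np.argmin(vcosts[hit])]
                                      if np.any(hit) else None)
        jointly[frozenset([nm])] = eliminable[nm]

    if not empty:
        for size in range(2, min(max_subset, len(sigma_ids)) + 1):
            for subset in combinations(sigma_ids, size):
                mask = np.ones(vp.shape[0], dtype=bool)
                for nm in subset:
                    mask &= vp[:, idx[nm]] <= sample.box[idx[nm], 0] + epsilon_log10
                key = frozenset(subset)
                jointly[key] = bool(np.any(mask))
                witnesses[key] = (vp[mask][np.argmin(vcosts[mask])]
                                  if np.any(mask) else None)

    return DiffusionDiagnosis(sigma_ids, eliminable, jointly, witnesses, ranges,
                              epsilon_log10=epsilon_log10)


def infer_hidden(model_ext: DynModel, sample: ViableSample, data: Dataset,
                 grid: Sequence[float], state: Optional[str] = None,
                 subsample: int = 200, seed: int = 0,
                 options: Optional[EKFOptions] = None) -> HiddenTrajectory:
    """Weighted-mean trajectory of an auxiliary state over the viable sample.

    Runs the Kalman filter at each viable point (a seeded subsample when the
    viable set is large), extracts the auxiliary state's filtered mean, and
    aggregates with likelihood weights into mean +/- weighted SE.
    """
    if sample.n_viable == 0:
        raise ValueError("sample has no viable points")
    aux_candidates = [s for s in model_ext.state_names
                      if model_ext.diffusion_params[model_ext.state_names.index(s)]
                      is not None]
    if state is None:
        if not aux_candidates:
            raise ValueError(f"model {model_ext.name!r} has no diffusion-driven state")
        state = aux_candidates[-1]
    s_idx = model_ext.state_names.index(state)

    grid = np.asarray(grid, dtype=float)
    idx = np.flatnonzero(sample.viable_flags)
    w = sample.weights[idx]
    if subsample is not None and subsample < idx.size:
        rng = np.random.default_rng(seed)
        keep = rng.choice(idx.size, size=subsample, replace=False)
        idx, w = idx[keep], w[keep]
    w = w / w.sum()

    trajs = np.empty((idx.size, grid.size))
    ok = np.ones(idx.size, dtype=bool)
    for j, i in enumerate(idx):
        theta = 10.0 ** sample.points[i]
        try:
            traj = infer_states(model_ext, theta, data, grid=grid, options=options)
            trajs[j] = traj.states[:, s_idx]
        except Exception:
            ok[j] = False
    if not np.any(ok):
        raise RuntimeError("state inference failed at every viable point")
    trajs, w = trajs[ok], w[ok] / w[ok].sum()

    mu = w @ trajs
    se = np.sqrt((w ** 2) @ (trajs - mu) ** 2)
    return HiddenTrajectory(grid, mu, se, state, n_points=int(ok.sum()))


# -- term dictionary matching ----------------------------------------------


@dataclass
class TermFit:
    family: str
    params: dict
    score: float        # small-sample-corrected information score (lower = better)
    rss: float
    predictions: np.ndarray = field(repr=False, default=None)


def _aicc(n: int, k: int, rss: float) -> float:
    rss = max(rss, 1e-300)
    pen = 2 * k + (2 * k * (k + 1) / (n - k - 1) if n > k + 1 else np.inf)
    return n * np.log(rss / n) + pen


def _fit_constant(z, y, w):
    a = np.sum(w * y) / np.sum(w)
    return {"a": float(a)}, np.full_like(y, a)


def _fit_linear(z, y, w):
    a = np.sum(w * z * y) / max(np.sum(w * z * z), 1e-300)
    return {"a": float(a)}, a * z

def _fit_saturating(z, y, w):
    # y = a / (b + z); multi-start over decades of b
    sw = np.sqrt(w)
    span = max(np.max(z) - np.min(z), 1e-12)

    def resid(p):
        a, log_b = p
        return sw * (a / (np.exp(log_b) + z) - y)

    best = None
    scale = np.median(np.abs(y)) + 1e-12
    for b0 in span * np.array([0.01, 0.1, 0.3, 1.0, 3.0]):
        p0 = np.array([scale * (b0 + np.median(z)), np.log(b0)])
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=400)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None, None
    a, b = best.x[0], float(np.exp(best.x[1]))
    return {"a": float(a), "b": b}, a / (b + z)


def _fit_switch(z, y, w):
    # y = a * 1{z < b}; scan candidate thresholds at data midpoints
    zs = np.unique(z)
    best = None
    for b in 0.5 * (zs[1:] + zs[:-1]):
        on = z < b
        if not np.any(on):
            continue
        a = np.sum(w[on] * y[on]) / np.sum(w[on])
        pred = np.where(on, a, 0.0)
        rss = np.sum(w * (y - pred) ** 2)
        if best is None or rss < best[0]:
            best = (rss, {"a": float(a), "b": float(b)}, pred)
    if best is None:
        return None, None
    return best[1], best[2]


_FAMILIES = {
    "constant": (_fit_constant, 1),
    "linear": (_fit_linear, 1),
    "saturating": (_fit_saturating, 2),
    "switch": (_fit_switch, 2),
}


def match_term(hidden: HiddenTrajectory, covariates: dict,
               dictionary: Optional[Sequence[str]] = None) -> list[TermFit]:
    """Rank simple rate-law families against the inferred hidden trajectory.

    Each family is a one-covariate closed form (constant a; linear a*z;
    saturating a/(b+z); switch a*1{z<b}).  Fits are weighted least squares
    with weights 1/SE^2 of the hidden mean, scored by a small-sample-corrected
    information criterion (parameter-count penalized).  If the hidden
    trajectory is (numerically) constant, only the constant family is
    returned.
    """
    dictionary = list(dictionary or _FAMILIES)
    unknown = set(dictionary) - set(_FAMILIES)
    if unknown:
        raise KeyError(f"unknown term families: {sorted(unknown)}")
    y = hidden.mean
    n = y.size
    w = 1.0 / np.maximum(hidden.se, 1e-12) ** 2
    w = w / w.sum() * n

    spread = np.max(y) - np.min(y)
    degenerate = spread <= 1e-10 * max(1.0, np.max(np.abs(y)))

    fits: list[TermFit] = []
    for cov_name, cov in (covariates or {"_time": None}).items():
        if cov is None:
            z = hidden.times.astype(float)
        elif isinstance(cov, Trajectory):
            z = np.interp(hidden.times, cov.times, cov.states[:, 0]
                          if cov.states.ndim > 1 else cov.states)
        else:
            z = np.asarray(cov, dtype=float)
        for fam in dictionary:
            if degenerate and fam != "constant":
                continue
            fit_fn, k = _FAMILIES[fam]
            params, pred = fit_fn(z, y, w)
            if params is None:
                continue
            rss = float(np.sum(w * (y - pred) ** 2))
            fits.append(TermFit(family=fam if cov_name == "_time"
                                else f"{fam}({cov_name})",
                                params=params, score=_aicc(n, k, rss),
                                rss=rss, predictions=pred))
    fits.sort(key=lambda f: f.score)
    return fits
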