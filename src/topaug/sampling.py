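"""Viable-parameter-space exploration and characterization.

All sampling happens in log10 parameter space (parameters are positive rate
constants, volumes and noise magnitudes spanning many decades).  The
exploration phase runs several Metropolis–Hastings chains on the flattened
target exp(-max(J(theta), cutoff)): below the cutoff the target is constant,
so chains wander uniformly over the viable region; above it the likelihood
gradient pulls them toward viability.  Chains start from the best points of a
Latin-hypercube scan of the box.  The second phase fits covariance ellipsoids
to clusters of viable points and expands them while they stay mostly viable,
mapping the extent of each viable region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import qmc

from .model_core import Dataset, DynModel, simulate_ode
from .viability import ViabilityRule, classify, sde_cutoff

__all__ = [
    "ViableSample", "EllipsoidRegion", "ExploreSettings", "explore",
    "characterize", "project", "weighted_prediction",
    "estimate_viable_fraction", "make_costfn",
]


@dataclass
class ExploreSettings:
    """Knobs for the broad Metropolis–Hastings exploration phase.

    Each chain runs ``n_anneal`` steps of plain Metropolis on exp(-J) first —
    a descent phase that locates the high-likelihood region and anchors the
    relative viability cutoff — before switching to the flattened target,
    under which it wanders the viable region uniformly for coverage.
    """

    n_chains: int = 4
    n_steps: int = 500
    n_anneal: int = 150         # descent steps per chain before flattening
    n_init: int = 128           # Latin-hypercube scan size
    init_scale: float = 0.5     # initial proposal SD, log10 units
    target_accept: float = 0.25
    adapt_every: int = 25
    polish_evals: int = 300     # Nelder-Mead budget to pin the optimum (0 = off)


@dataclass
class ViableSample:
    """All evaluated parameter points (log10) with costs and viability flags."""

    param_names: list[str]
    points: np.ndarray
    costs: np.ndarray
    box: np.ndarray                     # (d, 2) log10 bounds
    viable_flags: np.ndarray = None
    weights: np.ndarray = None
    rule: Optional[ViabilityRule] = None
    seed: Optional[int] = None
    chain_ids: np.ndarray = None
    status: str = "ok"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.costs = np.asarray(self.costs, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.viable_flags is None:
            self.viable_flags = np.zeros(self.costs.size, dtype=bool)
        if self.weights is None:
            self.weights = np.zeros(self.costs.size)
        if self.chain_ids is None:
            self.chain_ids = np.full(self.costs.size, -1)

    @property
    def n_viable(self) -> int:
        return int(np.sum(self.viable_flags))

    @property
    def best_cost(self) -> float:
        finite = np.isfinite(self.costs)
        return float(np.min(self.costs[finite])) if np.any(finite) else np.inf

    @property
    def best_point(self) -> np.ndarray:
        return self.points[int(np.nanargmin(np.where(np.isfinite(self.costs),
                                                     self.costs, np.nan)))]

    def viable_points(self) -> np.ndarray:
        return self.points[self.viable_flags]

    def merge(self, points: np.ndarray, costs: np.ndarray, chain_id: int = -2) -> None:
        points = np.atleast_2d(points)
        self.points = np.vstack([self.points, points])
        self.costs = np.concatenate([self.costs, costs])
        self.chain_ids = np.concatenate([self.chain_ids,
                                         np.full(len(costs), chain_id)])
        if self.rule is not None:
            if self.rule.mode == "sde-relative" and np.isfinite(self.best_cost):
                # a better optimum re-anchors the relative cutoff
                self.rule.threshold = sde_cutoff(self.best_cost,
                                                self.rule.delta_orders)
            classify(self, self.rule)
        else:
            self.viable_flags = np.concatenate(
                [self.viable_flags, np.zeros(len(costs), dtype=bool)])
            self.weights = np.zeros(self.costs.size)

    # -- serialization: columnar CSV + JSON sidecar ---------------------------
    def to_csv(self, path, sidecar_path=None) -> None:
        df = pd.DataFrame(self.points, columns=self.param_names)
        df["cost"] = self.costs
        df["viable"] = self.viable_flags
        df["weight"] = self.weights
        df["chain"] = self.chain_ids
        df.to_csv(path, index=False)
        if sidecar_path is not None:
            rule = None
            if self.rule is not None:
                rule = {"mode": self.rule.mode, "alpha": self.rule.alpha,
                        "delta_orders": self.rule.delta_orders,
                        "threshold": self.rule.threshold}
            with open(sidecar_path, "w") as fh:
                json.dump({"param_names": self.param_names,
                           "box": self.box.tolist(), "seed": self.seed,
                           "rule": rule, "status": self.status}, fh, indent=2)


@dataclass
class EllipsoidRegion:
    """A viable region approximated as {z : (z-c)' shape^-1 (z-c) <= radius^2}."""

    center: np.ndarray
    shape: np.ndarray
    radius: float
    member_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def contains(self, z: np.ndarray) -> bool:
        d = z - self.center
        return float(d @ np.linalg.solve(self.shape, d)) <= self.radius ** 2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform draws inside the ellipsoid."""
        dim = self.center.size
        L = np.linalg.cholesky(self.shape)
        g = rng.standard_normal((n, dim))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        r = rng.random(n) ** (1.0 / dim)
        return self.center + self.radius * (r[:, None] * g) @ L.T

    def volume(self) -> float:
        """Lebesgue volume (unit-ball volume * radius^d * sqrt(det shape))."""
        from scipy.special import gammaln
        d = self.center.size
        log_ball = 0.5 * d * np.log(np.pi) - gammaln(0.5 * d + 1)
        sign, logdet = np.linalg.slogdet(self.shape)
        return float(np.exp(log_ball + d * np.log(self.radius) + 0.5 * logdet))


def make_costfn(model: DynModel, data: Dataset, options=None) -> Callable:
    """Cost as a function of a log10 parameter vector."""
    from .ekf import cost

    def costfn(z: np.ndarray) -> float:
        return cost(model, 10.0 ** np.asarray(z, dtype=float), data, options).value

    return costfn


def _reflect(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect a proposal back into the box (repeat until inside)."""
    width = hi - lo
    z = np.mod(z - lo, 2 * width)
    z = np.where(z > width, 2 * width - z, z)
    return lo + z


def nm_polish(f, z0: np.ndarray, maxfev: int, restarts: int = 1,
              step: "float | np.ndarray | None" = None) -> np.ndarray:
    """Nelder-Mead with simplex restarts (recovers from simplex collapse).

    ``f`` must be finite-ified (return a large number instead of inf).
    ``step`` sets the initial simplex edge lengths explicitly — scipy's
    default simplex degenerates for coordinates near zero, which stalls the
    descent.  Returns the final point; all evaluations should be recorded by
    ``f`` itself if the caller wants the trail.
    """
    from scipy.optimize import minimize

    z = np.asarray(z0, dtype=float)
    d = z.size
    for r in range(restarts + 1):
        options = {"maxfev": maxfev, "fatol": 1e-8, "xatol": 1e-5}
        if step is not None and r == 0:
            simplex = np.tile(z, (d + 1, 1))
            simplex[1:] += np.diag(np.broadcast_to(step, (d,)) * np.ones(d))
            options["initial_simplex"] = simplex
        res = minimize(f, z, method="Nelder-Mead", options=options)
        z = res.x
    return z


def explore(costfn: Callable, box, settings: Optional[ExploreSettings] = None,
            seed: int = 0, rule: Optional[ViabilityRule] = None,
            param_names: Optional[list] = None) -> ViableSample:
    """Broad multi-chain MH exploration of the box; returns every evaluated point.

    ``rule`` decides viability: 'sde-relative' anchors the cutoff to the best
    cost seen (updated adaptively during the run), 'ode-expected-likelihood'
    uses its fixed pre-bound threshold.  With no rule, a default
    sde-relative rule at 5 orders of magnitude is used.
    """
    settings = settings or ExploreSettings()
    box = np.asarray(box, dtype=float)
    d = box.shape[0]
    lo, hi = box[:, 0], box[:, 1]
    if not np.all(hi > lo):
        raise ValueError("box upper bounds must exceed lower bounds")
    param_names = param_names or [f"p{i}" for i in range(d)]
    rule = rule or ViabilityRule(mode="sde-relative", delta_orders=5.0)

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=d, seed=rng)
    init = lo + sampler.random(settings.n_init) * (hi - lo)
    init_costs = np.array([costfn(z) for z in init])

    all_pts = [init]
    all_costs = [init_costs]
    all_chain = [np.full(settings.n_init, -1)]

    best = np.min(init_costs) if np.any(np.isfinite(init_costs)) else np.inf

    def running_cutoff() -> float:
        if rule.mode == "ode-expected-likelihood":
            return rule.threshold
        return best + rule.delta_orders * np.log(10.0) if np.isfinite(best) else np.inf

    order = np.argsort(init_costs)
    starts = init[order[:settings.n_chains]]
    start_costs = init_costs[order[:settings.n_chains]]

    # pin the optimum before chains launch: a deterministic Nelder-Mead
    # descent from the best scan point anchors the relative cutoff and gives
    # the first chain a start inside the viable region
    if settings.polish_evals > 0 and np.any(np.isfinite(init_costs)):
        trail_p, trail_c = [], []

        def f(z):
            zc = _reflect(z, lo, hi)
            J = costfn(zc)
            trail_p.append(zc)
            trail_c.append(J)
            return J if np.isfinite(J) else 1e300

        nm_polish(f, init[order[0]], maxfev=settings.polish_evals, restarts=1,
                  step=0.1 * (hi - lo))
        trail_c = np.array(trail_c)
        all_pts.append(np.array(trail_p))
        all_costs.append(trail_c)
        all_chain.append(np.full(trail_c.size, -3))
        i_best = int(np.argmin(trail_c))
        if trail_c[i_best] < start_costs[0]:
            starts[0] = trail_p[i_best]
            start_costs[0] = trail_c[i_best]
            best = min(best, float(trail_c[i_best]))

    for c in range(settings.n_chains):
        z, J = starts[c % len(starts)].copy(), start_costs[c % len(starts)]
        scale = settings.init_scale
        accepted = 0
        pts = np.empty((settings.n_steps, d))
        costs = np.empty(settings.n_steps)
        for s in range(settings.n_steps):
            z_new = _reflect(z + scale * rng.standard_normal(d), lo, hi)
            J_new = costfn(z_new)
            best = min(best, J_new)
            if s < settings.n_anneal:
                # descent phase: plain Metropolis on exp(-J)
                log_a = J - J_new if np.isfinite(J_new) else -np.inf
                if not np.isfinite(J):
                    log_a = 0.0 if np.isfinite(J_new) else -np.inf
            else:
                cut = running_cutoff()
                log_a = -max(J_new, cut) + max(J, cut) if np.isfinite(cut) \
                    else (0.0 if J_new < J else -np.inf)
            if np.log(rng.random()) < log_a:
                z, J = z_new, J_new
                accepted += 1
            pts[s], costs[s] = z_new, J_new
            if (s + 1) % settings.adapt_every == 0:
                rate = accepted / (s + 1)
                scale = float(np.clip(scale * np.exp(rate - settings.target_accept),
                                      1e-3, np.max(hi - lo)))
        all_pts.append(pts)
        all_costs.append(costs)
        all_chain.append(np.full(settings.n_steps, c))

    # deterministic polish: pin down the optimum that anchors the relative
    # cutoff (the MH phases locate the basin; Nelder-Mead sharpens it), and
    # keep its evaluation trail — it often contains boundary witnesses
    flat_costs = np.concatenate(all_costs)
    if settings.polish_evals > 0 and np.any(np.isfinite(flat_costs)):
        flat_pts = np.vstack(all_pts)
        z0 = flat_pts[int(np.nanargmin(np.where(np.isfinite(flat_costs),
                                                flat_costs, np.nan)))]
        trail_p, trail_c = [], []

        def f(z):
            zc = _reflect(z, lo, hi)
            J = costfn(zc)
            trail_p.append(zc)
            trail_c.append(J)
            return J if np.isfinite(J) else 1e300

        nm_polish(f, z0, maxfev=settings.polish_evals, restarts=1,
                  step=0.05 * (hi - lo))
        all_pts.append(np.array(trail_p))
        all_costs.append(np.array(trail_c))
        all_chain.append(np.full(len(trail_c), -3))
        best = min(best, float(np.min(trail_c)))

    sample = ViableSample(
        param_names=param_names,
        points=np.vstack(all_pts),
        costs=np.concatenate(all_costs),
        box=box,
        seed=seed,
        chain_ids=np.concatenate(all_chain),
    )
    if not np.any(np.isfinite(sample.costs)):
        sample.status = "no viable points: cost infinite everywhere evaluated"
        sample.rule = rule
        return sample
    if rule.mode == "sde-relative":
        rule.threshold = sde_cutoff(sample.best_cost, rule.delta_orders)
    classify(sample, rule)
    if sample.n_viable == 0:
        sample.status = "no viable points"
    return sample


def estimate_viable_fraction(costfn: Callable, box, threshold: float,
                             n: int = 20000, seed: int = 0) -> float:
    """Uniform Monte-Carlo estimate of the viable volume fraction of the box."""
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    z = box[:, 0] + rng.random((n, box.shape[0])) * (box[:, 1] - box[:, 0])
    costs = np.array([costfn(p) for p in z])
    return float(np.mean(costs <= threshold))


def characterize(sample: ViableSample, costfn: Callable,
                 cutoff: Optional[float] = None, gap: float = 1.0,
                 n_test: int = 200, min_viable_frac: float = 0.5,
                 expand_factor: float = 1.25, max_expansions: int = 10,
                 seed: int = 0) -> list[EllipsoidRegion]:
    """Cluster viable points and expand a covariance ellipsoid around each cluster.

    Single-linkage clustering in log10 space is cut at ``gap`` (log10 units);
    each cluster's ellipsoid grows by ``expand_factor`` per iteration while at
    least ``min_viable_frac`` of ``n_test`` uniform draws inside it remain
    viable.  Newly evaluated viable draws are merged back into ``sample``.
    """
    if cutoff is None:
        if sample.rule is None or sample.rule.threshold is None:
            raise ValueError("no cutoff given and sample has no bound rule")
        cutoff = sample.rule.threshold
    vp = sample.viable_points()
    d = sample.box.shape[0]
    if vp.shape[0] < d + 1:
        sample.status = "too few viable points to characterize"
        return []

    rng = np.random.default_rng(seed)
    if vp.shape[0] > 1:
        labels = fcluster(linkage(vp, method="single"), t=gap, criterion="distance")
    else:
        labels = np.array([1])

    lo, hi = sample.box[:, 0], sample.box[:, 1]
    regions = []
    viable_idx = np.flatnonzero(sample.viable_flags)
    for lab in np.unique(labels):
        members = vp[labels == lab]
        if members.shape[0] < 2:
            continue
        center = members.mean(axis=0)
        cov = np.cov(members.T) + 1e-6 * np.eye(d)
        # initial radius: enclose the members
        dev = members - center
        mah = np.sqrt(np.einsum("ij,ij->i", dev, np.linalg.solve(cov, dev.T).T))
        radius = float(np.max(mah)) + 1e-9
        region = EllipsoidRegion(center, cov, radius,
                                 member_idx=viable_idx[labels == lab])
        for _ in range(max_expansions):
            trial = EllipsoidRegion(center, cov, region.radius * expand_factor)
            draws = trial.sample(n_test, rng)
            inside = np.all((draws >= lo) & (draws <= hi), axis=1)
            costs = np.full(n_test, np.inf)
            costs[inside] = [costfn(z) for z in draws[inside]]
            ok = costs <= cutoff
            if np.any(ok):
                sample.merge(draws[ok], costs[ok])
            if np.mean(ok) >= min_viable_frac:
                region = EllipsoidRegion(center, cov, trial.radius,
                                         member_idx=region.member_idx)
            else:
                break
        regions.append(region)
    return regions


def project(sample: ViableSample, dims: Sequence[str], bins: int = 20) -> dict:
    """Viable points restricted to ``dims`` plus a 2-D occupancy grid.

    The occupancy grid (only for exactly two dims) marks which cells of the
    box contain at least one viable point — the machine-readable version of
    the viable-space projection plots used to judge which noise magnitudes
    are negligible.
    """
    idx = [sample.param_names.index(d) if d in sample.param_names
           else _raise_unknown(d, sample.param_names) for d in dims]
    vp = sample.viable_points()
    table = pd.DataFrame(vp[:, idx], columns=list(dims))
    table["cost"] = sample.costs[sample.viable_flags]
    out = {"table": table}
    if len(idx) == 2:
        rng0 = tuple(sample.box[idx[0]])
        rng1 = tuple(sample.box[idx[1]])
        Hc, xe, ye = np.histogram2d(vp[:, idx[0]], vp[:, idx[1]],
                                    bins=bins, range=[rng0, rng1])
        out.update({"occupancy": Hc > 0, "x_edges": xe, "y_edges": ye})
    return out


def _raise_unknown(name, names):
    raise KeyError(f"unknown parameter dimension {name!r}; have {names}")


def weighted_prediction(model: DynModel, sample: ViableSample,
                        grid: Sequence[float], data: Optional[Dataset] = None,
                        subsample: Optional[int] = None, seed: int = 0) -> pd.DataFrame:
    """Likelihood-weighted mean prediction band across viable points.

    For each grid time, the deterministic model output is averaged over the
    viable parameter points with their likelihood weights; the band half-width
    is the weighted standard error of that mean,
    sqrt(sum_i w_i^2 (x_i - mu)^2) / sum_i w_i  (weights renormalized over the
    evaluated subset).
    """
    if sample.n_viable == 0:
        raise ValueError("sample has no viable points")
    grid = np.asarray(grid, dtype=float)
    idx = np.flatnonzero(sample.viable_flags)
    w = sample.weights[idx]
    if subsample is not None and subsample < idx.size:
        rng = np.random.default_rng(seed)
        keep = rng.choice(idx.size, size=subsample, replace=False)
        idx, w = idx[keep], w[keep]
    w = w / w.sum()

    preds = []
    for i in idx:
        theta = 10.0 ** sample.points[i]
        traj = simulate_ode(model, theta, np.concatenate([[model.t0], grid])
                            if grid[0] > model.t0 else grid)
        states = traj.states[-grid.size:]
        preds.append(np.stack([model.h(x) for x in states]))
    preds = np.stack(preds)                        # (n_pts, T, n_obs)
    mu = np.einsum("i,itj->tj", w, preds)
    se = np.sqrt(np.einsum("i,itj->tj", w ** 2, (preds - mu) ** 2))

    frames = []
    for j, name in enumerate(model.observable_names):
        frames.append(pd.DataFrame({"time": grid, "observable": name,
                                    "mean": mu[:, j], "se": se[:, j]}))
    return pd.concat(frames, ignore_index=True)
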