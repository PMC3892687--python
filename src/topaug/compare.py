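"""Bayes-factor model comparison via Monte-Carlo marginal likelihoods.

The marginal likelihood of a model is the likelihood integrated over its
parameter space under the declared prior.  Priors here are uniform on the
same log10 boxes used for sampling, so the box choice is an explicit part of
the comparison configuration.  Plain Monte Carlo with log-sum-exp
stabilization estimates

    m(M) = E_prior[ exp(-J(theta)) ],

reported as log10 with a delta-method standard error.  Bayes factors are
marginal-likelihood ratios; with equal prior model probabilities the Bayes
factor equals the posterior-probability ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .ekf import EKFOptions, cost
from .model_core import Dataset, DynModel

__all__ = ["ModelComparison", "marginal_likelihood", "marginal_likelihood_from_cost",
           "bayes_factor", "posterior_probs"]

_LOG10 = float(np.log(10.0))


@dataclass
class ModelComparison:
    """Per-model marginal likelihoods (log10, with MC SEs) and posteriors."""

    model_ids: list[str]
    log10_ml: np.ndarray
    mc_se: np.ndarray
    posterior: np.ndarray
    prior_model_probs: np.ndarray
    n_draws: int
    seed: int

    def log10_bayes_factor(self, i: "int | str", j: "int | str") -> float:
        i = self.model_ids.index(i) if isinstance(i, str) else i
        j = self.model_ids.index(j) if isinstance(j, str) else j
        return float(self.log10_ml[i] - self.log10_ml[j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"model": self.model_ids, "log10_ml": self.log10_ml,
                             "mc_se": self.mc_se, "posterior": self.posterior})

    def report(self) -> str:
        df = self.to_frame()
        lines = [f"model comparison (n_draws={self.n_draws}, seed={self.seed})"]
        for _, r in df.iterrows():
            lines.append(f"  {r['model']:>10}  log10 ML = {r['log10_ml']:9.3f} "
                         f"+/- {r['mc_se']:.3f}   P = {r['posterior']:.4f}")
        return "\n".join(lines)


def marginal_likelihood_from_cost(costfn: Callable, box, n_draws: int = 1000,
                                  seed: int = 0, log10_box: bool = True,
                                  regions: Optional[Sequence] = None
                                  ) -> tuple[float, float]:
    """log10 marginal likelihood of a cost function under a uniform box prior.

    ``costfn`` maps a parameter vector (linear scale when ``log10_box`` and
    the draws are exponentiated, else raw) to a negative log-likelihood.
    Returns (log10 estimate, delta-method MC SE in log10 units).  All-diverged
    draws give (-inf, inf).

    With ``regions`` (EllipsoidRegion list from the viable-space
    characterization), a stratified/defensive importance-sampling mode is
    used: half the draws come from the prior, half uniformly from the
    ellipsoids, and each draw is reweighted by prior density over mixture
    density.  This keeps the estimator unbiased while concentrating draws
    where the likelihood mass lives — plain prior sampling badly undersamples
    narrow viable regions at affordable draw counts.
    """
    box = np.atleast_2d(np.asarray(box, dtype=float))
    rng = np.random.default_rng(seed)
    d = box.shape[0]
    vol_box = float(np.prod(box[:, 1] - box[:, 0]))

    if not regions:
        z = box[:, 0] + rng.random((n_draws, d)) * (box[:, 1] - box[:, 0])
        imp_w = np.ones(n_draws)
    else:
        n_prior = n_draws // 2
        n_reg = n_draws - n_prior
        z_prior = box[:, 0] + rng.random((n_prior, d)) * (box[:, 1] - box[:, 0])
        k = len(regions)
        counts = np.bincount(rng.integers(0, k, size=n_reg), minlength=k)
        z_reg = np.vstack([reg.sample(int(c), rng)
                           for reg, c in zip(regions, counts) if c > 0])
        z = np.vstack([z_prior, z_reg])
        vols = np.array([reg.volume() for reg in regions])
        in_box = np.all((z >= box[:, 0]) & (z <= box[:, 1]), axis=1)
        p_prior = np.where(in_box, 1.0 / vol_box, 0.0)
        q_reg = np.zeros(z.shape[0])
        for reg, v in zip(regions, vols):
            dev = z - reg.center
            mah2 = np.einsum("ij,ij->i", dev, np.linalg.solve(reg.shape, dev.T).T)
            q_reg += (mah2 <= reg.radius ** 2) / (k * v)
        q_mix = 0.5 * np.where(in_box, 1.0 / vol_box, 0.0) + 0.5 * q_reg
        with np.errstate(divide="ignore", invalid="ignore"):
            imp_w = np.where(q_mix > 0, p_prior / q_mix, 0.0)

    theta = 10.0 ** z if log10_box else z
    a = np.array([-costfn(th) if w > 0 else -np.inf
                  for th, w in zip(theta, imp_w)])   # log-likelihoods
    finite = np.isfinite(a)
    if not np.any(finite):
        return -np.inf, np.inf
    M = np.max(a[finite])
    wgt = np.where(finite, imp_w * np.exp(np.where(finite, a, -np.inf) - M), 0.0)
    mean_w = wgt.mean()
    if mean_w <= 0:
        return -np.inf, np.inf
    var_w = wgt.var(ddof=1) if n_draws > 1 else np.inf
    log10_ml = (M + np.log(mean_w)) / _LOG10
    se = float(np.sqrt(var_w / len(wgt)) / (mean_w * _LOG10))
    return float(log10_ml), se


def marginal_likelihood(model: DynModel, data: Dataset, prior_box,
                        n_draws: int = 1000, seed: int = 0,
                        options: Optional[EKFOptions] = None,
                        regions: Optional[Sequence] = None) -> tuple[float, float]:
    """log10 marginal likelihood of ``model`` with a uniform log10-box prior.

    A dataset with zero observed points has marginal likelihood 1 (log10 = 0):
    the empty product carries no evidence.  ``regions`` switches on the
    stratified importance-sampling mode (see
    :func:`marginal_likelihood_from_cost`).
    """
    if data.n_points == 0:
        return 0.0, 0.0
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    prior_box = np.atleast_2d(np.asarray(prior_box, dtype=float))
    if prior_box.shape[0] != model.n_params:
        raise ValueError(f"prior box has {prior_box.shape[0]} rows, "
                         f"model {model.name!r} has {model.n_params} parameters")

    def costfn(theta):
        return cost(model, theta, data, options).value

    return marginal_likelihood_from_cost(costfn, prior_box, n_draws=n_draws,
                                         seed=seed, log10_box=True,
                                         regions=regions)


def bayes_factor(model_i: DynModel, model_j: DynModel, data: Dataset,
                 priors: dict, n_draws: int = 1000, seed: int = 0,
                 options: Optional[EKFOptions] = None,
                 regions: Optional[dict] = None) -> tuple[float, float]:
    """log10 Bayes factor B_ij and its combined MC SE.

    Antisymmetric by construction (a model against itself gives exactly 0:
    the same seed produces the same draws).
    """
    regions = regions or {}
    mi, si = marginal_likelihood(model_i, data, priors[model_i.name],
                                 n_draws=n_draws, seed=seed, options=options,
                                 regions=regions.get(model_i.name))
    mj, sj = marginal_likelihood(model_j, data, priors[model_j.name],
                                 n_draws=n_draws, seed=seed, options=options,
                                 regions=regions.get(model_j.name))
    se = float(np.sqrt(si ** 2 + sj ** 2)) if np.isfinite(si) and np.isfinite(sj) else np.inf
    return mi - mj, se


def posterior_probs(models: Sequence[DynModel], data: Dataset, priors: dict,
                    prior_model_probs: Optional[Sequence[float]] = None,
                    n_draws: int = 1000, seed: int = 0,
                    options: Optional[EKFOptions] = None,
                    regions: Optional[dict] = None) -> ModelComparison:
    """Posterior model probabilities p_i ∝ prior_i * marginal_i.

    With equal model priors, p_i/p_j equals the Bayes factor B_ij to Monte
    Carlo accuracy.  Each model gets its own derived seed so that draw counts
    do not couple models.
    """
    n_models = len(models)
    if prior_model_probs is None:
        prior_model_probs = np.full(n_models, 1.0 / n_models)
    prior_model_probs = np.asarray(prior_model_probs, dtype=float)
    if abs(prior_model_probs.sum() - 1.0) > 1e-9:
        raise ValueError("prior model probabilities must sum to 1")

    seeds = np.random.SeedSequence(seed).generate_state(n_models) % (2 ** 31)
    log10_ml = np.empty(n_models)
    mc_se = np.empty(n_models)
    for i, m in enumerate(models):
        log10_ml[i], mc_se[i] = marginal_likelihood(
            m, data, priors[m.name], n_draws=n_draws, seed=int(seeds[i]),
            options=options, regions=(regions or {}).get(m.name))

    with np.errstate(invalid="ignore"):
        log_post = np.log(prior_model_probs) / _LOG10 + log10_ml
    finite = np.isfinite(log_post)
    post = np.zeros(n_models)
    if np.any(finite):
        shifted = log_post - np.max(log_post[finite])
        post[finite] = 10.0 ** shifted[finite]
        post /= post.sum()

    return ModelComparison([m.name for m in models], log10_ml, mc_se, post,
                           prior_model_probs, n_draws, seed)


def posterior_probs_explored(models: Sequence[DynModel], data: Dataset,
                             priors: dict, n_draws: int = 1000, seed: int = 0,
                             options: Optional[EKFOptions] = None,
                             settings=None, delta_orders: float = 5.0,
                             gap: float = 1.5, n_test: int = 80,
                             max_expansions: int = 3,
                             prior_model_probs: Optional[Sequence[float]] = None
                             ) -> ModelComparison:
    """Posterior probabilities with per-model viable-space exploration.

    For every model: explore its prior box, characterize the viable region
    as ellipsoids, then estimate the marginal likelihood by stratified
    importance sampling anchored on those ellipsoids.  This is the
    recommended route for models with more than a handful of parameters,
    where plain prior sampling is dominated by single lucky draws.
    """
    from .sampling import ExploreSettings, characterize, explore, make_costfn
    from .viability import ViabilityRule

    settings = settings or ExploreSettings(n_chains=3, n_steps=250,
                                           n_anneal=100, n_init=64,
                                           polish_evals=200)
    regions = {}
    for m in models:
        cf = make_costfn(m, data, options)
        rule = ViabilityRule(mode="sde-relative", delta_orders=delta_orders)
        sample = explore(cf, priors[m.name], settings, seed=seed, rule=rule,
                         param_names=list(m.param_names))
        regions[m.name] = characterize(sample, cf, gap=gap, n_test=n_test,
                                       max_expansions=max_expansions, seed=seed)
    return posterior_probs(models, data, priors, n_draws=n_draws, seed=seed,
                           options=options, regions=regions,
                           prior_model_probs=prior_model_probs)
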