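"""Viability criteria: which parameter points are compatible with the data.

Two modes are supported.

ODE mode ("expected log-likelihood"): under a correct model with Gaussian
measurement noise, the standardized squared-residual sum is chi-squared with
N degrees of freedom (N = number of data points), so the expected cost and
its spread are known in closed form.  A point is viable when its cost lies
within ``alpha`` standard deviations of the expectation:

    J(theta) <= 1/2 (N + alpha * sqrt(2N)) + sum_k 1/2 ln det(2 pi S_k).

SDE mode ("relative"): the chi-squared argument does not carry over once
system noise enters the likelihood, so viability is instead anchored to the
best cost found: points within ``delta_orders`` orders of likelihood
magnitude of the optimum are viable,

    J(theta) <= J_best + delta_orders * ln(10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .model_core import Dataset

__all__ = ["ViabilityRule", "ode_threshold", "sde_cutoff", "classify",
           "innovation_sign_test", "likelihood_weights"]


@dataclass
class ViabilityRule:
    """A viability decision rule, bound to a concrete cost threshold.

    ``mode`` is 'ode-expected-likelihood' (uses ``alpha``) or 'sde-relative'
    (uses ``delta_orders``); ``threshold`` is filled by :func:`ode_threshold`
    or :func:`sde_cutoff`.
    """

    mode: str
    alpha: float = 3.0
    delta_orders: float = 5.0
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("ode-expected-likelihood", "sde-relative"):
            raise ValueError(f"unknown viability mode {self.mode!r}")
        if self.alpha < 0 or self.delta_orders < 0:
            raise ValueError("alpha and delta_orders must be >= 0")


def ode_threshold(data: Dataset, alpha: float) -> float:
    """Upper cost bound for ODE-model viability at ``alpha`` standard deviations.

    The chi-squared(N) sum has mean N and variance 2N; halving maps it to
    cost units, and the Gaussian normalization constants are added back.
    """
    if data.n_points == 0:
        raise ValueError("cannot form a viability threshold from zero data points")
    observed = ~np.isnan(data.values)
    n = int(observed.sum())
    log_norm = 0.5 * float(np.sum(np.log(2.0 * np.pi * data.sds[observed] ** 2)))
    return 0.5 * (n + alpha * np.sqrt(2.0 * n)) + log_norm


def sde_cutoff(best_cost: float, delta_orders: float) -> float:
    """Cost cutoff ``delta_orders`` likelihood orders of magnitude above the optimum."""
    if not np.isfinite(best_cost):
        raise ValueError("best_cost must be finite to anchor an SDE cutoff")
    return best_cost + delta_orders * np.log(10.0)


def likelihood_weights(costs: np.ndarray, viable: np.ndarray) -> np.ndarray:
    """Normalized likelihood weights w_i ∝ exp(J_best - J_i) over viable points.

    Non-viable points get weight zero.  Returns an all-zero vector when no
    point is viable.
    """
    costs = np.asarray(costs, dtype=float)
    w = np.zeros_like(costs)
    if not np.any(viable):
        return w
    best = np.min(costs[viable])
    w[viable] = np.exp(best - costs[viable])
    return w / w.sum()


def classify(sample, rule: ViabilityRule):
    """Set viability flags and likelihood weights on a ViableSample in place.

    Flags are ``J(theta) <= rule.threshold``; weights follow
    :func:`likelihood_weights`.  Returns the same sample for chaining.
    """
    if rule.threshold is None:
        raise ValueError("rule has no bound threshold; call ode_threshold/sde_cutoff first")
    costs = np.asarray(sample.costs, dtype=float)
    sample.viable_flags = np.isfinite(costs) & (costs <= rule.threshold)
    sample.weights = likelihood_weights(costs, sample.viable_flags)
    sample.rule = rule
    return sample


def innovation_sign_test(innovations: list, alternative: str = "two-sided") -> dict:
    """Sign test for systematic over/underestimation.

    Collects the signs of all scalar innovation components across time points
    and tests whether positive and negative signs are balanced (binomial
    p = 0.5).  ``alternative='greater'`` tests specifically for
    underestimation (an excess of positive innovations, data above the model),
    ``'less'`` for overestimation.  A small p-value warns that the model is
    systematically biased — an aspect the viability criterion alone does not
    capture.  Reported as a diagnostic, never as a viability veto.
    """
    signs = np.concatenate([np.sign(np.atleast_1d(e)) for e in innovations
                            if np.atleast_1d(e).size]) \
        if len(innovations) else np.empty(0)
    signs = signs[signs != 0]
    n = signs.size
    if n == 0:
        return {"n": 0, "n_positive": 0, "p_value": 1.0, "biased": False}
    n_pos = int(np.sum(signs > 0))
    p = stats.binomtest(n_pos, n, 0.5, alternative=alternative).pvalue
    return {"n": int(n), "n_positive": n_pos, "p_value": float(p),
            "biased": bool(p < 0.05),
            "direction": "underestimates" if n_pos > n - n_pos else "overestimates"}
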