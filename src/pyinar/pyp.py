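"""Pitman-Yor process mathematics and hyperparameter elicitation.

The Pitman-Yor (PY) process is a two-parameter generalization of the
Dirichlet process, with concentration parameter ``tau > -sigma`` and
discount parameter ``0 <= sigma < 1``.  Draws from a PY-distributed random
measure are almost surely discrete, so a sample of n variables exhibits
ties: the number of distinct values K defines a random partition whose law
depends on (tau, sigma, n).

This module provides

* the sequential predictive (urn) rule,
* the exact distribution and expectation of the number of clusters K,
* numerical inversion of E[K] = k0 for the concentration parameter, and
* elicitation of the Gamma(a0, b0) base measure by minimizing the
  Kullback-Leibler divergence from a Uniform[0, lambda_max] reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "PYHyperparams",
    "ElicitationConfig",
    "py_predictive_weights",
    "expected_num_clusters",
    "num_clusters_pmf",
    "solve_tau",
    "kl_uniform_to_gamma",
    "elicit_base_measure",
]


@dataclass(frozen=True)
class PYHyperparams:
    """Hyperparameters of a PY(tau, sigma, G0) prior with Gamma(a0, b0) base.

    Parameters
    ----------
    tau
        Concentration parameter; must exceed ``-sigma``.
    sigma
        Discount parameter in ``[0, 1)``; ``sigma = 0`` recovers the
        Dirichlet process.
    a0, b0
        Shape and rate of the Gamma base measure (both positive).
    """

    tau: float
    sigma: float
    a0: float
    b0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma < 1.0:
            raise ValueError(f"discount sigma must be in [0, 1), got {self.sigma}")
        if not self.tau > -self.sigma:
            raise ValueError(
                f"concentration tau must exceed -sigma = {-self.sigma}, got {self.tau}"
            )
        if not (self.a0 > 0 and self.b0 > 0):
            raise ValueError("Gamma base measure requires a0 > 0 and b0 > 0")


@dataclass(frozen=True)
class ElicitationConfig:
    """Settings for eliciting (tau, a0, b0) from interpretable quantities.

    ``k0`` is the prior expected number of clusters among ``n`` PY draws;
    ``lambda_max`` is the reference scale for the base measure (the support
    of the uniform reference distribution, not a truncation point).
    """

    k0: int
    sigma: float
    lambda_max: float
    n: int

    def __post_init__(self) -> None:
        if not 1 <= self.k0 <= self.n:
            raise ValueError(f"k0 must lie in [1, n={self.n}], got {self.k0}")
        if not self.lambda_max > 0:
            raise ValueError("lambda_max must be positive")
        if not 0.0 <= self.sigma < 1.0:
            raise ValueError(f"discount sigma must be in [0, 1), got {self.sigma}")


def py_predictive_weights(
    hyper: PYHyperparams, multiplicities: Sequence[int]
) -> tuple[float, np.ndarray]:
    """Predictive (urn) weights for the next PY draw given n observations.

    Given k distinct observed atoms with multiplicities ``n_1, ..., n_k``
    summing to n, the next draw is new with probability
    ``(tau + k*sigma) / (tau + n)`` and repeats observation i (belonging to
    an atom of multiplicity ``n_i``) with probability
    ``(1 - sigma/n_i) / (tau + n)``.

    Parameters
    ----------
    hyper
        PY hyperparameters (the base measure is irrelevant to the weights).
    multiplicities
        Size of each distinct atom among the previous observations.

    Returns
    -------
    new_value_weight : float
        Probability of drawing a fresh value from the base measure.
    per_observation_weights : ndarray
        One weight per previous *observation* (atom weights repeated by
        multiplicity); together with ``new_value_weight`` they sum to one.
    """
    mult = np.asarray(multiplicities, dtype=float)
    if mult.size == 0 or np.any(mult < 1):
        raise ValueError("multiplicities must be a non-empty list of positive counts")
    n = mult.sum()
    k = mult.size
    tau, sigma = hyper.tau, hyper.sigma
    new_w = (tau + k * sigma) / (tau + n)
    per_atom = (1.0 - sigma / mult) / (tau + n)
    per_obs = np.repeat(per_atom, mult.astype(int))
    return new_w, per_obs


def expected_num_clusters(tau: float, sigma: float, n: int) -> float:
    """Prior expectation of the number of clusters among n PY(tau, sigma) draws.

    Uses the closed forms

    * ``sigma = 0``:  ``tau * (psi(tau + n) - psi(tau))`` with psi the
      digamma function;
    * ``sigma > 0``:  ``(tau + sigma)_n / (sigma * (tau + 1)_{n-1}) - tau/sigma``

    where ``(x)_n = Gamma(x + n) / Gamma(x)`` is the rising factorial,
    evaluated in log-gamma space to avoid overflow.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    _check_py_params(tau, sigma)
    if n == 1:
        return 1.0
    # the sigma > 0 ratio form is (R - tau)/sigma with R -> tau as sigma -> 0:
    # catastrophic cancellation for tiny sigma, so route to the DP limit there
    if sigma == 0.0 or (sigma < 1e-12 and tau > 0):
        return tau * (special.digamma(tau + n) - special.digamma(tau))
    log_ratio = (
        special.gammaln(tau + sigma + n)
        - special.gammaln(tau + sigma)
        - (special.gammaln(tau + n) - special.gammaln(tau + 1.0))
    )
    return math.exp(log_ratio) / sigma - tau / sigma


def _log_generalized_stirling(n: int, sigma: float) -> np.ndarray:
    """log of S_sigma(n, k) = C(n, k; sigma) / sigma^k for k = 1..n.

    C(n, k; sigma) is the generalized factorial coefficient.  The scaled
    array S satisfies the triangular recurrence

        S(n+1, k) = (n - k*sigma) * S(n, k) + S(n, k-1),  S(1, 1) = 1,

    whose entries are strictly positive for 0 <= sigma < 1 (the factor
    ``n - k*sigma`` is positive whenever k <= n), so the whole computation
    is carried out with log-add-exp.  At sigma = 0 the recurrence yields
    unsigned Stirling numbers of the first kind, which is exactly the
    Dirichlet-process limit of the cluster-count distribution.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    log_s = np.full(n + 1, -np.inf)
    log_s[1] = 0.0
    for m in range(1, n):
        ks = np.arange(1, m + 1)
        factors = m - ks * sigma
        if np.any(factors <= 0):  # impossible for sigma < 1; guards recurrence misuse
            raise FloatingPointError("negative factor in generalized-Stirling recurrence")
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = log_s[1 : m + 1] + np.log(factors)
        new[2 : m + 2] = np.logaddexp(new[2 : m + 2], log_s[1 : m + 1])
        log_s = new
    return log_s[1:]


def num_clusters_pmf(n: int, tau: float, sigma: float) -> np.ndarray:
    """Exact pmf of the number of clusters K over k = 1..n.

    Implements ``Pr{K = k} = prod_{i=1}^{k-1}(tau + i*sigma) /
    ((tau + 1)_{n-1} * sigma^k) * C(n, k; sigma)`` with the generalized
    factorial coefficients folded into a positive, log-space recurrence;
    the ``sigma = 0`` case is the Dirichlet-process limit (unsigned
    Stirling numbers) obtained from the same recurrence.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    _check_py_params(tau, sigma)
    if n == 1:
        return np.array([1.0])
    ks = np.arange(1, n + 1)
    if sigma == 0.0:
        log_prefactor = (ks - 1) * math.log(tau)
    else:
        # cumulative log prod_{i=1}^{k-1} (tau + i*sigma); all factors positive
        log_terms = np.log(tau + np.arange(1, n) * sigma)
        log_prefactor = np.concatenate(([0.0], np.cumsum(log_terms)))
    log_rising = special.gammaln(tau + 1.0 + n - 1) - special.gammaln(tau + 1.0)
    log_pmf = log_prefactor + _log_generalized_stirling(n, sigma) - log_rising
    return np.exp(log_pmf)


def solve_tau(k0: float, sigma: float, n: int, *, xtol: float = 1e-10) -> float:
    """Concentration tau such that the prior expected cluster count is k0.

    E[K] is continuous and strictly increasing in tau on ``(-sigma, inf)``,
    ranging from 1 (as ``tau -> -sigma``) to n (as ``tau -> inf``), so the
    equation ``E[K] = k0`` has a unique root for ``1 < k0 < n``, found by
    bracketing and Brent's method.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= sigma < 1.0:
        raise ValueError(f"discount sigma must be in [0, 1), got {sigma}")
    if not 1.0 < k0 < n:
        raise ValueError(
            f"k0 = {k0} is outside the attainable open interval (1, {n}) of E[K]"
        )
    lo = -sigma + 1e-10
    hi = max(1.0, -sigma + 1.0)
    while expected_num_clusters(hi, sigma, n) < k0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the solution of E[K] = k0")
    root = optimize.brentq(
        lambda t: expected_num_clusters(t, sigma, n) - k0, lo, hi, xtol=xtol
    )
    return float(root)


def kl_uniform_to_gamma(a0: float, b0: float, lambda_max: float) -> float:
    """KL divergence of Uniform[0, lambda_max] from a Gamma(a0, b0) density.

    Closed form:

        -log(lmax) - a0*log(b0) + log Gamma(a0)
        - (a0 - 1)*(log(lmax) - 1) + b0*lmax/2.
    """
    if not (a0 > 0 and b0 > 0 and lambda_max > 0):
        raise ValueError("a0, b0 and lambda_max must all be positive")
    return (
        -math.log(lambda_max)
        - a0 * math.log(b0)
        + special.gammaln(a0)
        - (a0 - 1.0) * (math.log(lambda_max) - 1.0)
        + b0 * lambda_max / 2.0
    )


def elicit_base_measure(lambda_max: float) -> tuple[float, float]:
    """Gamma(a0, b0) base measure closest (in KL) to Uniform[0, lambda_max].

    Stationarity of the closed-form divergence in b0 gives the profile
    identity ``b0 = 2 * a0 / lambda_max``, reducing the problem to a 1-D
    bounded minimization over ``log a0``; the optimal shape a0 does not
    depend on lambda_max (only the rate rescales).
    """
    if not lambda_max > 0:
        raise ValueError("lambda_max must be positive")

    def profile(log_a0: float) -> float:
        a0 = math.exp(log_a0)
        return kl_uniform_to_gamma(a0, 2.0 * a0 / lambda_max, lambda_max)

    res = optimize.minimize_scalar(
        profile, bounds=(math.log(1e-3), math.log(1e3)), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"base-measure elicitation did not converge: {res}")
    a0 = math.exp(res.x)
    return a0, 2.0 * a0 / lambda_max


def _check_py_params(tau: float, sigma: float) -> None:
    if not 0.0 <= sigma < 1.0:
        raise ValueError(f"discount sigma must be in [0, 1), got {sigma}")
    if not tau > -sigma:
        raise ValueError(f"concentration tau must exceed -sigma = {-sigma}, got {tau}")
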