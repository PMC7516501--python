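"""Core data structures and the generalized INAR(p) model.

The generalized INAR(p) process is defined by the functional relation

    Y_t = alpha_1 o Y_{t-1} + ... + alpha_p o Y_{t-p} + Z_t,   t >= p + 1,

where ``o`` is binomial thinning (``alpha o Y`` is a Binomial(Y, alpha)
count of "survivors") and the innovations Z_t are conditionally independent
Poisson(lambda_t).  When all lambda_t coincide this is the classical
(homogeneous) INAR(p) model; letting the rates vary over time — and a
fortiori letting a Pitman-Yor prior cluster them — yields the
semi-parametric extension this package implements.

Besides the model containers, this module provides a simulator (including
the three-component Poisson-mixture innovation design used throughout the
package's validation suite) and ``loglik_direct``, an exact likelihood
evaluated by exhaustive enumeration over latent maturation configurations.
The exact likelihood is exponential in p and serves as a correctness oracle
for the data-augmented sampler, not as a production code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "CountSeries",
    "ThinningVector",
    "InnovationRates",
    "MaturationMatrix",
    "MixtureInnovationSpec",
    "SimulationResult",
    "binomial_thinning",
    "simulate_inar",
    "loglik_direct",
    "augmented_loglik",
]

# guard rails for the enumeration oracle (exponential in p)
_ORACLE_MAX_ORDER = 3
_ORACLE_MAX_COUNT = 30


@dataclass(frozen=True)
class CountSeries:
    """An observed non-negative integer time series y_1..y_T with model order p.

    Epoch indices are 1-based throughout the public API: ``values[0]`` is
    y_1 and the modelled epochs are t = p+1, ..., T.
    """

    values: np.ndarray
    order: int = 1

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("series values must be integers")
            vals = np.round(vals).astype(np.int64)
        if np.any(vals < 0):
            raise ValueError("series values must be non-negative")
        if self.order < 1:
            raise ValueError("model order p must be at least 1")
        if len(vals) <= self.order:
            raise ValueError(
                f"series length T = {len(vals)} must exceed the order p = {self.order}"
            )
        object.__setattr__(self, "values", vals.astype(np.int64))

    @property
    def T(self) -> int:
        return len(self.values)

    @property
    def n_epochs(self) -> int:
        """Number of modelled epochs, T - p."""
        return self.T - self.order

    def to_csv(self, path: str | Path) -> None:
        """Write the series as a two-column CSV (t, y) with a header row."""
        df = pd.DataFrame({"t": np.arange(1, self.T + 1), "y": self.values})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, order: int = 1) -> "CountSeries":
        """Read a (t, y) CSV written by :meth:`to_csv`.

        The time index must be the gap-free sequence 1..T and the counts
        must be non-negative integers; anything else raises ``ValueError``.
        """
        df = pd.read_csv(path)
        if not {"t", "y"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 't' and 'y', got {list(df.columns)}")
        if df["y"].isna().any():
            raise ValueError(f"{path}: missing values in the count column")
        t = df["t"].to_numpy()
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise ValueError(f"{path}: time index must be the gap-free sequence 1..T")
        y = df["y"].to_numpy()
        if not np.allclose(y, np.round(y)):
            raise ValueError(f"{path}: counts must be integers")
        return cls(values=np.round(y).astype(np.int64), order=order)


@dataclass(frozen=True)
class ThinningVector:
    """Thinning probabilities (alpha_1..alpha_p) with implicit remainder.

    The non-explosive region requires ``sum(alpha) < 1``; the remainder
    ``alpha_{p+1} = 1 - sum(alpha)`` is the implicit last coordinate of the
    Dirichlet prior placed on alpha.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("each thinning parameter must lie in [0, 1]")
        object.__setattr__(self, "alpha", a)

    @property
    def order(self) -> int:
        return len(self.alpha)

    @property
    def remainder(self) -> float:
        return 1.0 - float(self.alpha.sum())


@dataclass(frozen=True)
class InnovationRates:
    """Positive Poisson innovation rates lambda_t for t = p+1..T."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if np.any(r <= 0):
            raise ValueError("innovation rates must be strictly positive")
        object.__setattr__(self, "rates", r)


@dataclass(frozen=True)
class MixtureInnovationSpec:
    """Finite Poisson mixture for the innovations Z_t.

    The default three equal-weight components with rates (1, 8, 15) are the
    reference simulation design used by the validation suite.
    """

    weights: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))
    rates: np.ndarray = field(default_factory=lambda: np.array([1.0, 8.0, 15.0]))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if w.shape != r.shape:
            raise ValueError("weights and rates must have the same length")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if np.any(r <= 0):
            raise ValueError("mixture rates must be positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "rates", r)

    @property
    def mean(self) -> float:
        return float(self.weights @ self.rates)


@dataclass(frozen=True)
class SimulationResult:
    """Simulated series together with its latent generating quantities."""

    series: CountSeries
    true_rates: InnovationRates
    true_components: np.ndarray  # mixture component label per epoch p+1..T


def binomial_thinning(alpha_i: float, count: int, rng: np.random.Generator) -> int:
    """One realization of ``alpha_i o count``, a Binomial(count, alpha_i) draw."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if not 0.0 <= alpha_i <= 1.0:
        raise ValueError("thinning probability must lie in [0, 1]")
    if count == 0:
        return 0
    return int(rng.binomial(count, alpha_i))


def simulate_inar(
    alpha: ThinningVector | Sequence[float] | float,
    innovations: MixtureInnovationSpec | InnovationRates | float,
    T: int,
    initial: Sequence[int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulationResult:
    """Simulate a generalized INAR(p) path of length T.

    Parameters
    ----------
    alpha
        Thinning parameters; the order p is their length.
    innovations
        Either a :class:`MixtureInnovationSpec` (each Z_t's rate is drawn
        from the mixture, and the latent component label is recorded for
        later cluster-recovery scoring), an :class:`InnovationRates` vector
        of length T - p, or a single constant rate.
    T
        Total series length, initial values included.
    initial
        The p initial counts y_1..y_p.  Defaults to Poisson draws with mean
        ``mean_rate / (1 - sum(alpha))``, the stationary mean of the
        homogeneous model (or ``mean_rate`` if alpha is explosive).
    rng
        Seed or Generator; fixed seeds give bit-identical output.
    """
    if not isinstance(alpha, ThinningVector):
        alpha = ThinningVector(np.atleast_1d(np.asarray(alpha, dtype=float)))
    p = alpha.order
    if T <= p:
        raise ValueError(f"T = {T} must exceed the order p = {p}")
    rng = np.random.default_rng(rng)
    n = T - p

    if isinstance(innovations, MixtureInnovationSpec):
        components = rng.choice(len(innovations.rates), size=n, p=innovations.weights)
        rates = innovations.rates[components]
        mean_rate = innovations.mean
    else:
        if isinstance(innovations, InnovationRates):
            rates = innovations.rates
        else:
            rates = np.full(n, float(innovations))
        if len(rates) != n:
            raise ValueError(f"need T - p = {n} innovation rates, got {len(rates)}")
        components = np.zeros(n, dtype=np.int64)
        mean_rate = float(np.mean(rates))

    total_alpha = alpha.alpha.sum()
    if total_alpha >= 1.0:
        warnings.warn(
            f"sum(alpha) = {total_alpha:.3f} >= 1: the simulated process is explosive",
            stacklevel=2,
        )
    if initial is None:
        stat_mean = mean_rate / (1.0 - total_alpha) if total_alpha < 1.0 else mean_rate
        initial = rng.poisson(stat_mean, size=p)
    initial = np.asarray(initial, dtype=np.int64)
    if initial.shape != (p,):
        raise ValueError(f"need exactly p = {p} initial values")

    y = np.empty(T, dtype=np.int64)
    y[:p] = initial
    z = rng.poisson(rates)
    for t in range(p, T):
        survived = sum(
            binomial_thinning(alpha.alpha[i], int(y[t - 1 - i]), rng) for i in range(p)
        )
        y[t] = survived + z[t - p]
    return SimulationResult(
        series=CountSeries(values=y, order=p),
        true_rates=InnovationRates(rates=np.asarray(rates, dtype=float)),
        true_components=np.asarray(components, dtype=np.int64),
    )


def _epoch_loglik(
    yt: int, lags: np.ndarray, alpha: np.ndarray, lam: float
) -> float:
    """log p(y_t | y_{t-1..t-p}) by log-sum-exp over all maturation vectors."""
    p = len(alpha)
    ranges = [range(int(min(yt, lags[i])) + 1) for i in range(p)]
    terms = []
    for m in itertools.product(*ranges):
        s = sum(m)
        if s > yt:
            continue
        log_term = -lam + special.xlogy(yt - s, lam) - special.gammaln(yt - s + 1)
        for i in range(p):
            log_term += (
                special.gammaln(lags[i] + 1)
                - special.gammaln(m[i] + 1)
                - special.gammaln(lags[i] - m[i] + 1)
                + special.xlogy(m[i], alpha[i])
                + special.xlogy(lags[i] - m[i], 1.0 - alpha[i])
            )
        terms.append(log_term)
    return float(special.logsumexp(terms))


def loglik_direct(
    y: CountSeries,
    alpha: ThinningVector | Sequence[float] | float,
    rates: InnovationRates | Sequence[float] | float,
) -> float:
    """Exact log-likelihood of the generalized INAR(p) model.

    Evaluates, epoch by epoch, the convolution of the thinned lag counts
    with the Poisson innovation by enumerating every admissible maturation
    configuration and log-sum-exp-ing the terms.  The cost is exponential
    in p, so orders above 3 or counts above 30 are rejected: this function
    is the sampler's correctness oracle, not a fitting path.
    """
    if not isinstance(alpha, ThinningVector):
        alpha = ThinningVector(np.atleast_1d(np.asarray(alpha, dtype=float)))
    if not isinstance(rates, InnovationRates):
        rates = InnovationRates(np.atleast_1d(np.asarray(rates, dtype=float)))
    p = alpha.order
    if p != y.order:
        raise ValueError("alpha length and series order disagree")
    if len(rates.rates) != y.n_epochs:
        raise ValueError(f"need T - p = {y.n_epochs} rates, got {len(rates.rates)}")
    if p > _ORACLE_MAX_ORDER or y.values.max() > _ORACLE_MAX_COUNT:
        raise ValueError(
            f"enumeration oracle limited to p <= {_ORACLE_MAX_ORDER} "
            f"and counts <= {_ORACLE_MAX_COUNT}"
        )
    total = 0.0
    vals = y.values
    for t in range(p, y.T):
        lags = vals[t - np.arange(1, p + 1)]
        total += _epoch_loglik(int(vals[t]), lags, alpha.alpha, rates.rates[t - p])
    return total


def augmented_loglik(
    y: CountSeries,
    alpha: np.ndarray,
    rates: np.ndarray,
    m: np.ndarray,
) -> float:
    """Complete-data log-likelihood log p(y, m | alpha, lambda).

    ``m`` is the (p, T - p) maturation matrix; summing exp of this over all
    admissible m recovers ``exp(loglik_direct)``, which is the
    data-augmentation validity property the test suite checks.
    """
    p = y.order
    vals = y.values
    total = 0.0
    for t in range(p, y.T):
        j = t - p
        s = int(m[:, j].sum())
        yt = int(vals[t])
        if s > yt:
            return -np.inf
        total += -rates[j] + special.xlogy(yt - s, rates[j]) - special.gammaln(yt - s + 1)
        for i in range(p):
            lag = int(vals[t - 1 - i])
            if m[i, j] > lag:
                return -np.inf
            total += (
                special.gammaln(lag + 1)
                - special.gammaln(m[i, j] + 1)
                - special.gammaln(lag - m[i, j] + 1)
                + special.xlogy(m[i, j], alpha[i])
                + special.xlogy(lag - m[i, j], 1.0 - alpha[i])
            )
    return float(total)


@dataclass(frozen=True)
class MaturationMatrix:
    """Latent maturations m_{i,t}, rows i = 1..p, columns t = p+1..T.

    m_{i,t} counts the epoch-(t-i) individuals that survive thinning into
    epoch t, so ``0 <= m_{i,t} <= y_{t-i}`` and the survivors cannot exceed
    the observed count: ``sum_i m_{i,t} <= y_t``.
    """

    m: np.ndarray
    series: CountSeries

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=np.int64)
        p, n = m.shape
        y = self.series
        if p != y.order or n != y.n_epochs:
            raise ValueError("maturation matrix shape must be (p, T - p)")
        vals = y.values
        for i in range(p):
            lag = vals[p - 1 - i : y.T - 1 - i]
            if np.any(m[i] < 0) or np.any(m[i] > lag):
                raise ValueError("maturations must satisfy 0 <= m_it <= y_{t-i}")
        if np.any(m.sum(axis=0) > vals[p:]):
            raise ValueError("maturations must satisfy sum_i m_it <= y_t")
        object.__setattr__(self, "m", m)
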