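"""Data-augmented marginal Gibbs sampler for the PY-INAR(p) model.

The model places a Pitman-Yor process prior PY(tau, sigma, Gamma(a0, b0))
on the innovation rates lambda_{p+1..T} and a Dirichlet prior (with last
hyperparameter fixed at 1) on the thinning vector alpha, which confines all
prior mass to the non-explosive region ``sum(alpha) < 1``.  Marginalizing
the random measure yields Polya-urn full conditionals for each lambda_t;
augmenting with latent maturations m_{i,t} ~ Binomial(y_{t-i}, alpha_i)
makes the alpha and lambda conditionals conjugate.

One sweep of the sampler updates, in order:

1. every maturation m_{i,t} from its exact discrete conditional,
2. each alpha_i from a right-truncated Beta,
3. each lambda_t from its urn-scheme mixture conditional (a fresh
   Gamma(y_t - m_t + a0, b0 + 1) draw, or one of the other epochs' atoms),
4. the shared value of every cluster from its pooled Gamma conditional
   (the Escobar-West style acceleration step).

Setting ``homogeneous=True`` collapses steps 3-4 to a single shared rate
with conjugate update Gamma(a0 + sum residuals, b0 + T - p), recovering the
classical Bayesian INAR(p) model as the baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .inar import CountSeries, ThinningVector
from .pyp import PYHyperparams

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "GibbsState",
    "PosteriorDraws",
    "sample_truncated_beta",
    "sample_lambda_t",
    "lambda_site_log_weights",
    "sample_alpha",
    "sample_maturation",
    "refresh_cluster_values",
    "run_gibbs",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Chain-length and prior settings for :func:`run_gibbs`.

    ``dirichlet_a`` holds the first p Dirichlet hyperparameters of the
    alpha prior (all 1 by default); the implicit last hyperparameter
    a_{p+1} is fixed at 1, which is what makes the alpha_i conditionals
    exactly right-truncated Betas.
    """

    n_iter: int = 6000
    n_burn: int = 1000
    thin: int = 1
    seed: int | None = None
    dirichlet_a: np.ndarray | None = None
    store_rates: bool = True
    track_coclustering: bool = True
    homogeneous: bool = False

    def __post_init__(self) -> None:
        if not self.n_iter > self.n_burn >= 0:
            raise ValueError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def alpha_prior(self, p: int) -> np.ndarray:
        if self.dirichlet_a is None:
            return np.ones(p)
        a = np.asarray(self.dirichlet_a, dtype=float)
        if a.shape == (p + 1,):
            if not np.isclose(a[-1], 1.0):
                raise ValueError(
                    "the last Dirichlet hyperparameter a_{p+1} must equal 1 "
                    "for the truncated-Beta alpha conditional to hold"
                )
            a = a[:p]
        if a.shape != (p,):
            raise ValueError(f"dirichlet_a must have length p = {p} (or p + 1)")
        if np.any(a <= 0):
            raise ValueError("Dirichlet hyperparameters must be positive")
        return a


@dataclass
class GibbsState:
    """Mutable sampler state: (alpha, lambda, m) plus the cluster view.

    The rates are stored through their partition: ``labels[t]`` indexes
    ``cluster_values``; ``cluster_sizes[j]`` counts its occupants nu_j.
    Every lambda_t equals exactly one cluster atom by construction.
    """

    alpha: np.ndarray
    m: np.ndarray  # (p, n) maturations
    labels: np.ndarray  # (n,) cluster index per epoch
    cluster_values: list[float]
    cluster_sizes: list[int]

    @property
    def k(self) -> int:
        return len(self.cluster_values)

    @property
    def rates(self) -> np.ndarray:
        return np.asarray(self.cluster_values)[self.labels]

    @classmethod
    def initial(cls, y: CountSeries, alpha0: np.ndarray | None = None) -> "GibbsState":
        """Valid starting state: alpha_i = 1/(2p), m = 0, one shared cluster.

        The single initial cluster at mean(y) (floored at a small positive
        value for all-zero series) gives a fast burn-in from the interior
        of the parameter space.
        """
        p, n = y.order, y.n_epochs
        if alpha0 is None:
            alpha0 = np.full(p, 1.0 / (2 * p))
        lam0 = max(float(y.values.mean()), 0.1)
        return cls(
            alpha=np.asarray(alpha0, dtype=float),
            m=np.zeros((p, n), dtype=np.int64),
            labels=np.zeros(n, dtype=np.int64),
            cluster_values=[lam0],
            cluster_sizes=[n],
        )

    def check_invariants(self, y: CountSeries) -> None:
        """Raise AssertionError if any state invariant is violated."""
        p, n = y.order, y.n_epochs
        assert self.m.shape == (p, n)
        assert sum(self.cluster_sizes) == n
        counts = np.bincount(self.labels, minlength=self.k)
        assert np.array_equal(counts, np.asarray(self.cluster_sizes))
        assert all(s > 0 for s in self.cluster_sizes)
        assert all(v > 0 for v in self.cluster_values)
        assert np.all(self.alpha >= 0) and self.alpha.sum() < 1.0
        vals = y.values
        for i in range(p):
            lag = vals[p - 1 - i : y.T - 1 - i]
            assert np.all(self.m[i] >= 0) and np.all(self.m[i] <= lag)
        assert np.all(self.m.sum(axis=0) <= vals[p:])


@dataclass
class PosteriorDraws:
    """Retained MCMC output of :func:`run_gibbs`.

    ``loglik`` is the complete-data log-likelihood log p(y, m | alpha,
    lambda) at each retained draw.  ``cocluster_counts[r, t]`` counts the
    retained draws in which epochs r and t share a rate atom; dividing by
    ``n_retained`` gives the posterior co-clustering probability.
    """

    alpha: np.ndarray  # (R, p)
    k: np.ndarray  # (R,)
    loglik: np.ndarray  # (R,)
    rates: np.ndarray | None  # (R, n) or None
    cocluster_counts: np.ndarray | None  # (n, n) or None
    order: int
    n_epochs: int
    seed: int | None = None

    @property
    def n_retained(self) -> int:
        return len(self.k)

    def k_mode(self) -> int:
        """Posterior mode of the number of clusters."""
        vals, counts = np.unique(self.k, return_counts=True)
        return int(vals[np.argmax(counts)])

    def to_csv(self, path: str | Path, rates_path: str | Path | None = None) -> None:
        """One row per retained iteration: alpha's, k, loglik (rates apart)."""
        cols = {f"alpha{i + 1}": self.alpha[:, i] for i in range(self.order)}
        cols["k"] = self.k
        cols["loglik"] = self.loglik
        pd.DataFrame(cols).to_csv(path, index=False)
        if rates_path is not None:
            if self.rates is None:
                raise ValueError("rate draws were not stored for this run")
            lam_cols = {
                f"lambda{t}": self.rates[:, t - self.order - 1]
                for t in range(self.order + 1, self.order + self.n_epochs + 1)
            }
            pd.DataFrame(lam_cols).to_csv(rates_path, index=False)


def sample_truncated_beta(
    a: float, b: float, bound: float, rng: np.random.Generator
) -> float:
    """Draw from Beta(a, b) right-truncated to (0, bound).

    Inverse-CDF sampling through the regularized incomplete beta function;
    when the truncated mass is numerically negligible (or the inversion
    lands outside the support) the draw falls back to rejection and,
    failing that, to the small-x power-law approximation of the Beta
    density on (0, bound).
    """
    if bound <= 0:
        raise ValueError("truncation bound must be positive")
    if bound >= 1.0:
        return float(rng.beta(a, b))
    mass = float(special.betainc(a, b, bound))
    if mass > 1e-12:
        x = float(special.betaincinv(a, b, rng.random() * mass))
        if 0.0 < x < bound:
            return x
    for _ in range(1000):
        x = float(rng.beta(a, b))
        if x < bound:
            return x
    # density ~ x^(a-1) near 0 when the bound sits deep in the lower tail
    return bound * rng.random() ** (1.0 / a)


def sample_alpha(
    state: GibbsState, y: CountSeries, config: SamplerConfig, rng: np.random.Generator
) -> ThinningVector:
    """One sweep of the thinning-vector conditionals (updates state in place).

    Each alpha_i | all others is Beta(a_i + sum_t m_{i,t},
    1 + sum_t (y_{t-i} - m_{i,t})) right-truncated to
    (0, 1 - sum_{j != i} alpha_j); for p = 1 the bound is 1 and the draw is
    an ordinary Beta.
    """
    p = y.order
    a_prior = config.alpha_prior(p)
    vals = y.values
    for i in range(p):
        lag = vals[p - 1 - i : y.T - 1 - i]
        shape1 = a_prior[i] + float(state.m[i].sum())
        shape2 = 1.0 + float((lag - state.m[i]).sum())
        bound = 1.0 - (state.alpha.sum() - state.alpha[i])
        if bound <= 0:
            raise RuntimeError("non-explosive invariant violated before alpha update")
        state.alpha[i] = sample_truncated_beta(shape1, shape2, bound, rng)
    return ThinningVector(state.alpha.copy())


def _maturation_log_weights(
    yt: int, lag: int, other: int, alpha_i: float, lam_t: float
) -> np.ndarray:
    """Unnormalized log conditional of m_{i,t} on its support 0..min(yt-other, lag).

    ``other`` is the sum of the maturations at the remaining lags of epoch
    t.  The conditional is proportional to
    ``[m! (yt - other - m)! (lag - m)!]^{-1} (alpha_i / (lambda_t (1 - alpha_i)))^m``.
    """
    hi = min(yt - other, lag)
    ms = np.arange(hi + 1)
    if alpha_i <= 0.0:
        out = np.full(hi + 1, -np.inf)
        out[0] = 0.0
        return out
    if alpha_i >= 1.0:
        out = np.full(hi + 1, -np.inf)
        out[hi] = 0.0
        return out
    g = math.log(alpha_i) - math.log(lam_t) - math.log1p(-alpha_i)
    return (
        -special.gammaln(ms + 1)
        - special.gammaln(yt - other - ms + 1)
        - special.gammaln(lag - ms + 1)
        + ms * g
    )


def sample_maturation(
    i: int, t: int, state: GibbsState, y: CountSeries, rng: np.random.Generator
) -> int:
    """Exact draw of the single maturation m_{i,t} (1-based lag i, epoch t).

    Enumerates the (small) support and samples the normalized categorical;
    updates the state in place and returns the drawn value.
    """
    p = y.order
    if not 1 <= i <= p:
        raise ValueError(f"lag index must be in 1..{p}")
    if not p + 1 <= t <= y.T:
        raise ValueError(f"epoch must be in {p + 1}..{y.T}")
    col = t - p - 1
    yt = int(y.values[t - 1])
    lag = int(y.values[t - 1 - i])
    other = int(state.m[:, col].sum() - state.m[i - 1, col])
    lam_t = state.cluster_values[state.labels[col]]
    logw = _maturation_log_weights(yt, lag, other, float(state.alpha[i - 1]), lam_t)
    w = np.exp(logw - logw.max())
    draw = int(rng.choice(len(w), p=w / w.sum()))
    state.m[i - 1, col] = draw
    return draw


def _maturation_sweep(
    state: GibbsState,
    y: CountSeries,
    rates: np.ndarray,
    lag_matrix: np.ndarray,
    glt: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Vectorized systematic scan of all maturations.

    For a fixed lag i the sites (i, t) are conditionally independent across
    t, so each lag is updated as one batched exact categorical draw via the
    Gumbel-max trick; lags are scanned in order i = 1..p.
    """
    p, n = state.m.shape
    y_t = y.values[p:]
    for i in range(p):
        other = state.m.sum(axis=0) - state.m[i]
        cap = y_t - other
        lag = lag_matrix[i]
        sup = np.minimum(cap, lag)
        hi = int(sup.max(initial=0))
        alpha_i = float(state.alpha[i])
        if hi == 0 or alpha_i <= 0.0:
            state.m[i] = 0
            continue
        ms = np.arange(hi + 1)
        valid = ms[None, :] <= sup[:, None]
        cap_idx = np.clip(cap[:, None] - ms[None, :], 0, None)
        lag_idx = np.clip(lag[:, None] - ms[None, :], 0, None)
        g = math.log(alpha_i) - np.log(rates) - math.log1p(-alpha_i)
        logw = -(glt[ms][None, :] + glt[cap_idx] + glt[lag_idx]) + ms[None, :] * g[:, None]
        logw = np.where(valid, logw, -np.inf)
        gumb = rng.gumbel(size=logw.shape)
        state.m[i] = np.argmax(logw + gumb, axis=1)


def lambda_site_log_weights(
    t: int,
    state: GibbsState,
    hyper: PYHyperparams,
    y: CountSeries,
    grouped: bool = True,
    include_residual_factorial: bool = False,
) -> tuple[float, np.ndarray]:
    """Unnormalized log weights of the lambda_t full conditional.

    With epoch t (1-based) removed from its cluster, the conditional is a
    mixture of a fresh Gamma(y_t - m_t + a0, b0 + 1) component with weight

        w_t = (tau + k_minus * sigma) * b0^a0 * Gamma(y_t - m_t + a0)
              / (Gamma(a0) * (b0 + 1)^(y_t - m_t + a0))

    and point masses at the other epochs' atoms.  ``grouped=True`` returns
    one weight (n_j^{-t} - sigma) * lam_j^(y_t - m_t) * exp(-lam_j) per
    cluster j; ``grouped=False`` returns one weight (1 - sigma/n_r) * ...
    per epoch r != t, whose within-cluster sums coincide with the grouped
    form.  The residual factorial 1/(y_t - m_t)! multiplies *every*
    component, hence cancels on normalization; it can be switched on to
    verify that cancellation numerically.

    Returns ``(log fresh weight, log atom weights)``; cluster weights are
    indexed like ``state.cluster_values`` with emptied clusters at -inf.
    """
    p = y.order
    col = t - p - 1
    d = int(y.values[t - 1] - state.m[:, col].sum())
    j_t = state.labels[col]
    sizes = np.asarray(state.cluster_sizes, dtype=float)
    sizes_minus = sizes.copy()
    sizes_minus[j_t] -= 1
    k_minus = int(np.count_nonzero(sizes_minus))
    a0, b0, tau, sigma = hyper.a0, hyper.b0, hyper.tau, hyper.sigma
    log_fresh = (
        math.log(tau + k_minus * sigma)
        + a0 * math.log(b0)
        - special.gammaln(a0)
        + special.gammaln(d + a0)
        - (d + a0) * math.log(b0 + 1.0)
    )
    vals = np.asarray(state.cluster_values)
    extra = -special.gammaln(d + 1) if include_residual_factorial else 0.0
    if grouped:
        with np.errstate(divide="ignore", invalid="ignore"):
            log_atoms = np.where(
                sizes_minus > 0,
                np.log(np.maximum(sizes_minus - sigma, 1e-300))
                + d * np.log(vals)
                - vals,
                -np.inf,
            )
        return log_fresh + extra, log_atoms + extra
    # one weight per epoch r != t; n_r counts occupants of r's cluster in lambda^{-t}
    n_r = sizes_minus[state.labels]
    lam_r = vals[state.labels]
    safe_n = np.where(n_r > 0, n_r, 1.0)  # epochs of an emptied cluster get -inf
    log_obs = np.where(
        n_r > 0,
        np.log1p(-sigma / safe_n) + d * np.log(lam_r) - lam_r,
        -np.inf,
    )
    log_obs[col] = -np.inf
    return log_fresh + extra, log_obs + extra


def _remove_from_cluster(state: GibbsState, col: int) -> None:
    j = state.labels[col]
    state.cluster_sizes[j] -= 1
    if state.cluster_sizes[j] == 0:
        last = len(state.cluster_values) - 1
        if j != last:
            state.cluster_values[j] = state.cluster_values[last]
            state.cluster_sizes[j] = state.cluster_sizes[last]
            state.labels[state.labels == last] = j
        state.cluster_values.pop()
        state.cluster_sizes.pop()


def sample_lambda_t(
    t: int,
    state: GibbsState,
    hyper: PYHyperparams,
    y: CountSeries,
    rng: np.random.Generator,
) -> float:
    """One urn-scheme update of lambda_t (1-based epoch); state updated in place.

    Epoch t is detached from its cluster, the mixture conditional is
    normalized in log space with a max shift, and t either joins an
    existing cluster or opens a new one with a fresh
    Gamma(y_t - m_t + a0, b0 + 1) atom.
    """
    p = y.order
    col = t - p - 1
    _remove_from_cluster(state, col)
    d = int(y.values[t - 1] - state.m[:, col].sum())
    a0, b0, tau, sigma = hyper.a0, hyper.b0, hyper.tau, hyper.sigma
    k_minus = len(state.cluster_values)
    log_fresh = (
        math.log(tau + k_minus * sigma)
        + a0 * math.log(b0)
        - special.gammaln(a0)
        + special.gammaln(d + a0)
        - (d + a0) * math.log(b0 + 1.0)
    )
    logw = [log_fresh]
    for v, s in zip(state.cluster_values, state.cluster_sizes):
        logw.append(math.log(s - sigma) + d * math.log(v) - v)
    logw = np.asarray(logw)
    shift = logw.max()
    if not np.isfinite(shift):
        raise FloatingPointError("all lambda_t mixture weights underflowed")
    w = np.exp(logw - shift)
    u = rng.random() * w.sum()
    choice = int(np.searchsorted(np.cumsum(w), u))
    choice = min(choice, len(w) - 1)
    if choice == 0:
        value = float(rng.gamma(d + a0, 1.0 / (b0 + 1.0)))
        state.cluster_values.append(value)
        state.cluster_sizes.append(1)
        state.labels[col] = len(state.cluster_values) - 1
    else:
        j = choice - 1
        state.cluster_sizes[j] += 1
        state.labels[col] = j
        value = state.cluster_values[j]
    return value


def refresh_cluster_values(
    state: GibbsState,
    hyper: PYHyperparams,
    y: CountSeries,
    rng: np.random.Generator,
) -> GibbsState:
    """Redraw every cluster atom from its pooled conjugate conditional.

    lambda*_j | all others ~ Gamma(a0 + sum of residuals y_t - m_t over the
    cluster, b0 + nu_j).  Memberships are untouched; only the shared values
    move, which markedly improves mixing of the partition chain.
    """
    p = y.order
    resid = y.values[p:] - state.m.sum(axis=0)
    k = state.k
    shape = hyper.a0 + np.bincount(state.labels, weights=resid, minlength=k)
    rate = hyper.b0 + np.asarray(state.cluster_sizes, dtype=float)
    new_vals = rng.gamma(shape, 1.0 / rate)
    state.cluster_values = [float(v) for v in new_vals]
    return state


def _complete_data_loglik(
    y: CountSeries, alpha: np.ndarray, rates: np.ndarray, m: np.ndarray,
    lag_matrix: np.ndarray, glt: np.ndarray,
) -> float:
    p = y.order
    resid = y.values[p:] - m.sum(axis=0)
    ll = float(np.sum(-rates + special.xlogy(resid, rates) - glt[resid]))
    for i in range(p):
        lag = lag_matrix[i]
        ll += float(
            np.sum(
                glt[lag]
                - glt[m[i]]
                - glt[lag - m[i]]
                + special.xlogy(m[i], alpha[i])
                + special.xlogy(lag - m[i], 1.0 - alpha[i])
            )
        )
    return ll


class _SamplerCore:
    """Precomputed tables plus the one-full-iteration sweep.

    Factored out of :func:`run_gibbs` so sampler-correctness checks (e.g.
    joint-distribution tests that alternate parameter sweeps with data
    regeneration) can drive single sweeps on an externally managed state.
    """

    def __init__(self, y: CountSeries, hyper: PYHyperparams, config: SamplerConfig):
        self.y = y
        self.hyper = hyper
        self.config = config
        p, vals = y.order, y.values
        self.lag_matrix = np.stack([vals[p - 1 - i : y.T - 1 - i] for i in range(p)])
        # factorial table: glt[j] = log j!  (= gammaln(j + 1))
        self.glt = special.gammaln(np.arange(int(vals.max()) + 2, dtype=float) + 1.0)
        self.gl_res = special.gammaln(np.arange(int(vals.max()) + 1) + hyper.a0)
        self.log_b0p1 = math.log(hyper.b0 + 1.0)
        self.fresh_const = hyper.a0 * math.log(hyper.b0) - float(special.gammaln(hyper.a0))

    def sweep(self, state: GibbsState, rng: np.random.Generator) -> None:
        """One full iteration: maturations, alpha, all lambda_t, refresh."""
        y, hyper, config = self.y, self.hyper, self.config
        tau, sigma, a0, b0 = hyper.tau, hyper.sigma, hyper.a0, hyper.b0
        p, n = y.order, y.n_epochs
        _maturation_sweep(state, y, state.rates, self.lag_matrix, self.glt, rng)
        sample_alpha(state, y, config, rng)

        resid = y.values[p:] - state.m.sum(axis=0)
        if config.homogeneous:
            lam = float(rng.gamma(a0 + float(resid.sum()), 1.0 / (b0 + n)))
            state.cluster_values = [lam]
            state.cluster_sizes = [n]
            state.labels[:] = 0
            return
        values, sizes, labels = state.cluster_values, state.cluster_sizes, state.labels
        gl_res, log_b0p1, fresh_const = self.gl_res, self.log_b0p1, self.fresh_const
        uniforms = rng.random(n)
        for col in range(n):
            _remove_from_cluster(state, col)
            d = int(resid[col])
            k_minus = len(values)
            best = fresh_const + gl_res[d] - (d + a0) * log_b0p1 + math.log(
                tau + k_minus * sigma
            )
            logw = [best]
            for v, s in zip(values, sizes):
                lw = math.log(s - sigma) + d * math.log(v) - v
                logw.append(lw)
                if lw > best:
                    best = lw
            total = 0.0
            cum = []
            for lw in logw:
                total += math.exp(lw - best)
                cum.append(total)
            u = uniforms[col] * total
            choice = 0
            while cum[choice] < u:
                choice += 1
            if choice == 0:
                values.append(float(rng.gamma(d + a0, 1.0 / (b0 + 1.0))))
                sizes.append(1)
                labels[col] = len(values) - 1
            else:
                sizes[choice - 1] += 1
                labels[col] = choice - 1
        refresh_cluster_values(state, hyper, y, rng)


def run_gibbs(
    y: CountSeries,
    hyper: PYHyperparams,
    config: SamplerConfig | None = None,
    initial_state: GibbsState | None = None,
) -> PosteriorDraws:
    """Run the full data-augmented Gibbs sampler and collect retained draws.

    Per iteration: all maturations (systematic scan), the thinning vector,
    all lambda_t in epoch order, then the cluster-value refresh.  Post
    burn-in, every ``thin``-th iteration records alpha, the number of
    clusters k, the complete-data log-likelihood, optionally the full rate
    vector, and the pairwise co-clustering tallies.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    p, n = y.order, y.n_epochs
    state = initial_state or GibbsState.initial(y)
    core = _SamplerCore(y, hyper, config)

    n_retained = (config.n_iter - config.n_burn - 1) // config.thin + 1
    out_alpha = np.empty((n_retained, p))
    out_k = np.empty(n_retained, dtype=np.int64)
    out_ll = np.empty(n_retained)
    out_rates = np.empty((n_retained, n)) if config.store_rates else None
    cocluster = (
        np.zeros((n, n), dtype=np.int64) if config.track_coclustering else None
    )

    log_every = max(1, config.n_iter // 5)
    r = 0
    for it in range(config.n_iter):
        core.sweep(state, rng)
        if (it + 1) % log_every == 0:
            logger.info(
                "sweep %d/%d: k=%d, alpha=%s",
                it + 1, config.n_iter, state.k, np.round(state.alpha, 3),
            )
        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            rates = state.rates
            out_alpha[r] = state.alpha
            out_k[r] = state.k
            out_ll[r] = _complete_data_loglik(
                y, state.alpha, rates, state.m, core.lag_matrix, core.glt
            )
            if out_rates is not None:
                out_rates[r] = rates
            if cocluster is not None:
                cocluster += state.labels[:, None] == state.labels[None, :]
            r += 1

    return PosteriorDraws(
        alpha=out_alpha,
        k=out_k,
        loglik=out_ll,
        rates=out_rates,
        cocluster_counts=cocluster,
        order=p,
        n_epochs=n,
        seed=config.seed,
    )
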