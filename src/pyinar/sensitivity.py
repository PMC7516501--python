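"""Prior-sensitivity scan over the base-measure scale and elbow detection.

The Gamma(a0, b0) base measure is parameterized through a single reference
scale lambda_max (see :func:`pyinar.pyp.elicit_base_measure`).  Pushing
lambda_max to either extreme drives the probability of opening new
clusters to zero, so the scale is chosen by scanning a grid: for each
lambda_max the sampler is run and the posterior expected number of
clusters E[K | y] recorded; the chosen value sits at the "elbow" where the
curve levels off.

Two automatic operationalizations of the visual judgment are provided.
:func:`detect_elbow` is the generic knee finder: maximum distance to the
end-point chord after min-max normalization of both axes (scale-free, like
the visual judgment).  :func:`elbow_scan` itself selects the scale by a
*leveling-off* criterion better matched to this curve's shape: after an
isotonic (non-increasing) smoothing that strips Monte-Carlo noise, the
chosen lambda_max is the smallest grid point whose smoothed E[K | y] lies
within half a cluster of the most diffuse grid point.  The knee of this
curve sits mid-descent, where the posterior cluster count is still
dropping fast; the leveling point is where further spreading of the base
measure stops changing the answer, which is what the sensitivity analysis
is after.  Both rules and the half-cluster tolerance are design choices of
this package; see ``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .gibbs import SamplerConfig, run_gibbs
from .inar import CountSeries
from .pyp import PYHyperparams, elicit_base_measure, solve_tau

__all__ = ["ElbowCurve", "elbow_scan", "detect_elbow", "default_lambda_max_grid"]

logger = logging.getLogger(__name__)


@dataclass
class ElbowCurve:
    """E[K | y] as a function of the base-measure scale lambda_max."""

    lambda_max_grid: np.ndarray
    posterior_expected_k: np.ndarray
    chosen_lambda_max: float
    distinct_elbow: bool
    failed_points: list[int] = field(default_factory=list)
    posterior_k_se: np.ndarray | None = None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "lambda_max": self.lambda_max_grid,
                "E_K_posterior": self.posterior_expected_k,
            }
        ).to_csv(path, index=False)


def default_lambda_max_grid(y: CountSeries, n_points: int = 8) -> np.ndarray:
    """Log-spaced lambda_max grid spanning [max(y)/10, 20*max(y)].

    The left end squeezes the base measure against the data scale; the
    right end is diffuse enough that E[K | y] has levelled off for count
    data (innovation rates cannot much exceed the largest observed count,
    so scales an order of magnitude above it are effectively flat).
    """
    top = max(float(y.values.max()), 1.0)
    return np.geomspace(top / 10.0, 20.0 * top, n_points)


def detect_elbow(x: np.ndarray, fx: np.ndarray) -> tuple[float, bool]:
    """Locate the elbow of a curve by maximum distance to the end-point chord.

    Both axes are min-max normalized to [0, 1] first, making the rule
    invariant to affine rescaling of either axis.  Returns the abscissa of
    the elbow and a flag that is False when no distinct elbow exists (a
    straight or monotone-increasing curve); ties break toward smaller x.
    """
    x = np.asarray(x, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if len(x) < 4:
        raise ValueError("elbow detection needs at least 4 curve points")
    if len(x) != len(fx):
        raise ValueError("x and f(x) must have equal length")
    x_rng = x[-1] - x[0]
    f_rng = fx.max() - fx.min()
    if x_rng <= 0 or f_rng <= 0:
        return float(x[0]), False
    xn = (x - x[0]) / x_rng
    fn = (fx - fx.min()) / f_rng
    # distance from each point to the chord joining the first and last points
    dx, dy = xn[-1] - xn[0], fn[-1] - fn[0]
    dist = np.abs(dy * (xn - xn[0]) - dx * (fn - fn[0])) / np.hypot(dx, dy)
    interior = dist[1:-1]
    idx = 1 + int(np.argmax(interior))  # argmax ties break toward smaller x
    distinct = bool(interior[idx - 1] > 1e-9) and not _is_monotone_increasing(fx)
    if not distinct:
        idx = 1
    return float(x[idx]), distinct


def _is_monotone_increasing(fx: np.ndarray) -> bool:
    return bool(np.all(np.diff(fx) >= 0))


def leveling_point(
    x: np.ndarray, fx: np.ndarray, tol: float = 0.5
) -> tuple[float, bool]:
    """Smallest x at which a noisy decreasing curve has levelled off.

    The curve is first smoothed by isotonic (non-increasing) regression;
    the leveling point is the first x whose smoothed value lies within
    ``tol`` of the smoothed minimum.  With E[K | y] on the ordinate,
    ``tol`` is in clusters: the default declares the curve level once
    spreading the base measure further moves the posterior expected
    cluster count by less than half a cluster.  Returns the abscissa and
    a flag that is False when the curve never drops by more than ``tol``
    (no distinct elbow).
    """
    x = np.asarray(x, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if len(x) < 4:
        raise ValueError("leveling detection needs at least 4 curve points")
    iso = optimize.isotonic_regression(fx, increasing=False).x
    distinct = bool(iso.max() - iso.min() > tol)
    idx = int(np.argmax(iso - iso.min() <= tol))  # first index inside the plateau
    return float(x[idx]), distinct


def elbow_scan(
    y: CountSeries,
    k0: int,
    sigma: float,
    grid: np.ndarray | None = None,
    config: SamplerConfig | None = None,
) -> ElbowCurve:
    """Scan a lambda_max grid and locate the elbow of E[K | y].

    At each grid point the base measure (a0, b0) is elicited from
    lambda_max, tau is solved so the prior expected cluster count equals
    k0, and one Gibbs run yields E[K | y] as the mean of the retained k
    draws.  A sampler failure at a grid point flags the point and the scan
    continues.
    """
    if grid is None:
        grid = default_lambda_max_grid(y)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 4:
        raise ValueError("the lambda_max grid needs at least 4 points")
    if np.any(np.diff(grid) < 0):
        raise ValueError("the lambda_max grid must be non-decreasing")
    config = config or SamplerConfig()
    n = y.n_epochs
    tau = solve_tau(k0, sigma, n)
    ek = np.full(len(grid), np.nan)
    se = np.full(len(grid), np.nan)
    failed: list[int] = []
    for idx, lmax in enumerate(grid):
        try:
            a0, b0 = elicit_base_measure(float(lmax))
            hyper = PYHyperparams(tau=tau, sigma=sigma, a0=a0, b0=b0)
            draws = run_gibbs(y, hyper, config)
            ek[idx] = float(draws.k.mean())
            se[idx] = float(draws.k.std(ddof=1) / np.sqrt(draws.n_retained))
            logger.info(
                "elbow scan: lambda_max=%.4g -> E[K|y]=%.3f", lmax, ek[idx]
            )
        except Exception:  # noqa: BLE001 - flag the point, keep scanning
            logger.exception("elbow scan failed at lambda_max=%.4g", lmax)
            failed.append(idx)
    ok = ~np.isnan(ek)
    if ok.sum() < 4:
        raise RuntimeError("too few successful grid points to locate an elbow")
    if np.allclose(grid[ok], grid[ok][0]):
        return ElbowCurve(grid, ek, float(grid[ok][0]), False, failed, se)
    chosen, distinct = leveling_point(grid[ok], ek[ok])
    return ElbowCurve(grid, ek, chosen, distinct, failed, se)
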