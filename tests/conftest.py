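import numpy as np
import pytest

from pyinar import CountSeries, MixtureInnovationSpec, simulate_inar


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def reference_sim():
    """The standard validation design: INAR(1), alpha=0.15, T=1000,
    innovations an equal-weight mixture of Poisson(1), Poisson(8), Poisson(15)."""
    return simulate_inar(0.15, MixtureInnovationSpec(), T=1000, rng=20240118)


@pytest.fixture
def small_series():
    return CountSeries(values=np.array([2, 3, 1, 4, 0, 2, 3, 1]), order=1)


def sequential_urn_k(tau, sigma, n, reps, rng):
    """Independent Monte-Carlo oracle: cluster counts from the PY urn scheme."""
    ks = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        sizes = []
        for i in range(n):
            k = len(sizes)
            w = np.concatenate(([tau + k * sigma], np.asarray(sizes) - sigma)) \
                if sizes else np.array([tau + k * sigma])
            u = rng.random() * w.sum()
            j = int(np.searchsorted(np.cumsum(w), u))
            if j == 0:
                sizes.append(1)
            else:
                sizes[j - 1] += 1
        ks[r] = len(sizes)
    return ks
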