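import numpy as np
import pytest

from nldfc import Coupling, RoiTimeSeries, SimulationSpec, gen_coupled, zscore


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_series(rng):
    """A z-scored 3-region series with autocorrelated noise, T=120."""
    T, N = 120, 3
    e = rng.standard_normal((T, N))
    x = np.empty_like(e)
    x[0] = e[0]
    for t in range(1, T):
        x[t] = 0.7 * x[t - 1] + np.sqrt(1 - 0.49) * e[t]
    return zscore(RoiTimeSeries(x, tr=2.3, labels=("A", "B", "C")))


@pytest.fixture
def coupled_series():
    """Driver r0 -> receiver r1 at lag 2 TR, independent r2; mild noise."""
    spec = SimulationSpec(
        n_regions=3, n_timepoints=300, noise_scale=0.1,
        couplings=(Coupling("r0", "r1", lag_tr=2.0, share=1.0),), seed=11)
    series, truth = gen_coupled(spec)
    return series, truth


def naive_pearson(a, b):
    """Textbook Pearson correlation, written as explicit sums (test oracle)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((a[i] - ma) * (b[i] - mb) for i in range(n))
    va = sum((a[i] - ma) ** 2 for i in range(n))
    vb = sum((b[i] - mb) ** 2 for i in range(n))
    return cov / np.sqrt(va * vb)
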