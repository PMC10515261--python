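import numpy as np
import pytest

from riskcast.transform import MergedSeries


def make_merged(values, times=None, sources=None, scaled=False) -> MergedSeries:
    """Wrap a plain value sequence as a MergedSeries with unit time steps."""
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    if sources is None:
        sources = [("sim",)] * len(values)
    return MergedSeries(times=times, values=values, sources=sources, scaled=scaled)


def brute_force_acer(R, k, lam):
    """Independent O(N·k) window enumerator for the conditional exceedance
    counts: windows of k consecutive events whose first k−1 values are ≤ lam,
    counting how many end in a value > lam."""
    R = list(R)
    numer = denom = 0
    for j in range(k - 1, len(R)):
        if all(v <= lam for v in R[j - k + 1 : j]):
            denom += 1
            if R[j] > lam:
                numer += 1
    return numer, denom


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
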