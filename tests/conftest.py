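import numpy as np
import pytest

from scmwpls.grid import RegionSet, SpectraSet, SpectralRegion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectra_set(X, high_cm1=8000.0, step_cm1=8.0):
    """Wrap a plain matrix as a single-segment SpectraSet."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    region = SpectralRegion(high_cm1, high_cm1 - step_cm1 * (p - 1))
    return SpectraSet(
        step_cm1, RegionSet([region]), X, [f"s{i:03d}" for i in range(n)]
    )


def planted_signal_problem(rng, n=60, p=100, lo=40, hi=60, noise=0.05):
    """Spectra where only channels lo..hi carry the response.

    Returns (SpectraSet, y, planted channel index range inclusive).
    """
    y = rng.normal(size=n)
    X = rng.normal(scale=1.0, size=(n, p)) * 0.1
    width = hi - lo + 1
    profile = np.exp(-0.5 * ((np.arange(width) - width / 2) / (width / 5)) ** 2)
    X[:, lo : hi + 1] += np.outer(y, profile)
    X += rng.normal(scale=noise, size=(n, p)) * 0.0  # planted noise is in X
    return make_spectra_set(X), y, (lo, hi)


def region_channels(regions, step=8.0):
    """Set of (rounded) wavenumbers covered by a region set."""
    out = set()
    for r in regions:
        v = r.high_cm1
        while v >= r.low_cm1 - 1e-9:
            out.add(round(v))
            v -= step
    return out


def jaccard(regions_a, regions_b, step=8.0):
    a, b = region_channels(regions_a, step), region_channels(regions_b, step)
    return len(a & b) / len(a | b)
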