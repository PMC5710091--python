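"""Shared fixtures and the independent brute-force binomial oracle.

The oracle evaluates binomial CDFs by explicit summation of pmf terms with
exact integer binomial coefficients (``math.comb``) -- deliberately
independent of the scipy-backed implementation it is used to check.
"""

import math

import pytest
from hypothesis import settings

from afquantile import DatabaseSpec, DiseaseModel
from afquantile.simulate import make_fig1_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def brute_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def brute_cdf(k: int, n: int, p: float) -> float:
    if k < 0:
        return 0.0
    return sum(brute_pmf(i, n, p) for i in range(0, min(k, n) + 1))


def brute_quantile(level: float, n: int, p: float) -> int:
    """Smallest k with CDF(k) >= level, by linear scan."""
    acc = 0.0
    for k in range(0, n + 1):
        acc += brute_pmf(k, n, p)
        if acc >= level:
            return k
    return n


def brute_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) by summation of the upper pmf terms."""
    return sum(brute_pmf(i, n, p) for i in range(k, n + 1))


@pytest.fixture
def fig1_model() -> DiseaseModel:
    """Toy-example disease model: Pd = 1/10,000, AR, situation a."""
    return DiseaseModel(prevalence=1e-4, inheritance="AR", situation="a")


@pytest.fixture
def fig1_db() -> DatabaseSpec:
    return DatabaseSpec(individuals=50)


@pytest.fixture
def fig1_paths(tmp_path):
    """The toy dataset written to disk: candidates, database, config."""
    return make_fig1_fixture(tmp_path / "fig1")
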