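"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pytest

from diamotion import phantom


@pytest.fixture(scope="session")
def default_params() -> phantom.PhantomParams:
    return phantom.PhantomParams()


@pytest.fixture(scope="session")
def default_pair(default_params):
    """Default 3 mm adult-thorax phantom pair (built once per session)."""
    return phantom.build_phantom_pair(default_params)


@pytest.fixture(scope="session")
def default_truth(default_params):
    return phantom.analytic_truth(default_params)


@pytest.fixture(scope="session")
def small_phantom():
    """Deterministic scaled-down 1 mm phantom with its analytic truth."""
    rng = np.random.default_rng(20240501)
    params = phantom.sample_phantom_params(rng, spacing=1.0)
    return params, phantom.build_phantom_pair(params), phantom.analytic_truth(params)


def mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group a: pairs (i, j) with a_i > b_j (ties count half)."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def brute_force_mw_pvalue(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Independent oracle: walks every C(n_a+n_b, n_a) split of the pooled
    sample, computes U for each, and doubles the smaller tail probability
    (capped at 1).  Only intended for small n.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = pooled.size
    na = a.size
    u_obs = mannwhitney_u(a, b)
    us = []
    idx = set(range(n))
    for pick in combinations(range(n), na):
        rest = sorted(idx - set(pick))
        us.append(mannwhitney_u(pooled[list(pick)], pooled[rest]))
    us = np.asarray(us)
    total = comb(n, na)
    assert us.size == total
    lower = (us <= u_obs).sum() / total
    upper = (us >= u_obs).sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
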