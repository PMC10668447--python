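"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from vrsearch.simulate import AgentParams, make_fixture_cohort, quick_game


# ---------------------------------------------------------------- oracles

def brute_quartiles(values: np.ndarray, q: float) -> float:
    """Independent linear-interpolation quantile (no numpy.quantile)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def brute_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    q1 = brute_quartiles(values, 0.25)
    q3 = brute_quartiles(values, 0.75)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def perm_p_ranksum(x, y, n_perm: int = 20000, seed: int = 0) -> float:
    """Two-sided permutation p for the rank-sum statistic |R_x − E[R_x]|."""
    rng = np.random.default_rng(seed)
    comb = np.concatenate([x, y])
    n1, n = len(x), len(comb)
    ranks = sps.rankdata(comb)
    obs = abs(ranks[:n1].sum() - n1 * (n + 1) / 2)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)[:n1]
        hits += abs(ranks[idx].sum() - n1 * (n + 1) / 2) >= obs - 1e-9
    return hits / n_perm


def perm_p_signed_rank(x, y, n_perm: int = 20000, seed: int = 0) -> float:
    """Sign-flip permutation p for the smaller signed-rank sum."""
    rng = np.random.default_rng(seed)
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    hits = 0
    for _ in range(n_perm):
        s = rng.random(len(d)) < 0.5
        wp = ranks[s].sum()
        hits += min(wp, ranks.sum() - wp) <= obs + 1e-9
    return hits / n_perm


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def fixture_cohort():
    """Tiny hand-built cohort plus the hand-computed expected metric table."""
    return make_fixture_cohort()


@pytest.fixture(scope="session")
def small_game():
    """Scaled-down game + low-frame-rate agent base for simulation tests."""
    return quick_game(duration_scale=0.04, frame_rate=10.0)


@pytest.fixture(scope="session")
def fast_agent():
    return AgentParams(frame_rate=10.0)
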