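"""Shared fixtures and independent oracle helpers.

Oracles here are deliberately written with naive loops / textbook formulas
and never call the package code paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from speechtrf.features import AnnotationTier, Event


# ---------------------------------------------------------------------------
# oracle implementations (independent of the package internals)
# ---------------------------------------------------------------------------

def loop_lagged_design(feats: dict[str, np.ndarray], lags: np.ndarray) -> np.ndarray:
    """Index-loop lagged design with trailing bias column."""
    n = len(next(iter(feats.values())))
    cols = []
    for x in feats.values():
        for tau in lags:
            col = np.zeros(n)
            for t in range(n):
                if 0 <= t - tau < n:
                    col[t] = x[t - tau]
            cols.append(col)
    cols.append(np.ones(n))
    return np.column_stack(cols)


def ridge_oracle(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Brute-force penalized normal equations (bias column unpenalized)."""
    P = np.eye(X.shape[1])
    P[-1, -1] = 0.0
    return np.linalg.solve(X.T @ X + lam * P, X.T @ Y)


def pearson_oracle(a: np.ndarray, b: np.ndarray) -> float:
    n = len(a)
    sa, sb = a.sum(), b.sum()
    num = n * float(a @ b) - sa * sb
    den = math.sqrt(n * float(a @ a) - sa**2) * math.sqrt(n * float(b @ b) - sb**2)
    return num / den


def rankdata_oracle(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    sx = x[order]
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def ranksum_z_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook two-sided rank-sum z without tie correction."""
    from scipy.stats import norm

    n1, n2 = len(x), len(y)
    ranks = rankdata_oracle(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    z = (r1 - mu) / sd
    return z, 2 * norm.sf(abs(z))


def signed_rank_z_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook two-sided signed-rank z (zeros dropped, no correction)."""
    from scipy.stats import norm

    d = x - y
    d = d[d != 0]
    n = len(d)
    ranks = rankdata_oracle(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    z = (w_plus - mu) / sd
    return z, 2 * norm.sf(abs(z))


def by_oracle(p: np.ndarray) -> np.ndarray:
    """Closed-form Benjamini-Yekutieli step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    q = c * m * p[order] / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def loop_convolve(reg: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(N*L) causal convolution truncated to len(reg)."""
    n, L = len(reg), len(kernel)
    out = np.zeros(n)
    for t in range(n):
        for tau in range(min(L, t + 1)):
            out[t] += kernel[tau] * reg[t - tau]
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_tiers():
    """Three words, seven phonemes, hand-built and exactly nested."""
    words = [Event(0.10, 0.40, "cat"), Event(0.45, 0.80, "sat"), Event(0.90, 1.20, "mat")]
    phons = [
        Event(0.10, 0.20, "k"), Event(0.20, 0.40, "at"),
        Event(0.45, 0.55, "s"), Event(0.55, 0.65, "a"), Event(0.65, 0.80, "t"),
        Event(0.90, 1.05, "m"), Event(1.05, 1.20, "at"),
    ]
    return (
        AnnotationTier("word", words, source_id="toy"),
        AnnotationTier("phoneme", phons, source_id="toy"),
    )


@pytest.fixture(scope="session")
def small_sim_config():
    from speechtrf.synthetic import SimulationConfig

    return SimulationConfig(
        n_subjects=2, n_trials=3, trial_duration_s=20.0, fs=100.0,
        n_channels=4, snr_db=5.0, seed=99,
    )


@pytest.fixture(scope="session")
def small_subject(small_sim_config):
    from speechtrf.synthetic import simulate_subject

    return simulate_subject(small_sim_config, 0)
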