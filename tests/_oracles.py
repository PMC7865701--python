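"""Independent brute-force oracles used only by tests.

These never call the code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def ranksum_exact_oracle(x, y) -> tuple[float, float]:
    """One-sided ("x stochastically smaller") rank-sum p by full enumeration.

    Enumerates all C(n, n_x) assignments of the pooled ranks to the x
    positions; p = fraction of assignments whose Mann-Whitney U is <= the
    observed U. Valid only for tie-free data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = stats.rankdata(pooled)
    nx = x.size
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    n = pooled.size
    count = 0
    total = 0
    all_ranks = np.arange(1, n + 1)
    for combo in itertools.combinations(range(n), nx):
        u = all_ranks[list(combo)].sum() - nx * (nx + 1) / 2
        count += u <= u_obs
        total += 1
    return float(u_obs), count / total


def kruskal_oracle(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from the rank formula, written directly."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie_term


def km_empirical_oracle(times) -> callable:
    """Empirical survival function (valid KM oracle when nothing is censored)."""
    times = np.sort(np.asarray(times, dtype=float))

    def s(t: float) -> float:
        return float((times > t).mean())

    return s
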