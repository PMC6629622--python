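"""Independent brute-force reference implementations used only by tests.

These deliberately use the most literal formulations (explicit loops over
states and intervals, direct ANOVA sums of squares, exhaustive partitions)
so they share no code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from capnoseq.states import MISSING, STATE_ALPHABET


def brute_distribution(states, n_intervals=1):
    """Per-interval occupancy proportions by direct counting."""
    chunks = np.array_split(np.asarray(states, dtype=object), n_intervals)
    rows = []
    for chunk in chunks:
        counts = []
        for s in STATE_ALPHABET:
            counts.append(sum(1 for c in chunk if c == s))
        total = sum(counts)
        rows.append([c / total if total else 0.0 for c in counts])
    return np.array(rows)


def brute_chi2(states_x, states_y, marginal, n_intervals=1):
    """sqrt(sum over intervals and states of (p-q)^2/m) / sqrt(K)."""
    px = brute_distribution(states_x, n_intervals)
    qy = brute_distribution(states_y, n_intervals)
    acc = 0.0
    for i in range(n_intervals):
        for j, s in enumerate(STATE_ALPHABET):
            if s in marginal:
                acc += (px[i, j] - qy[i, j]) ** 2 / marginal[s]
    return np.sqrt(acc) / np.sqrt(n_intervals)


def brute_euclid(states_x, states_y, n_intervals=1):
    px = brute_distribution(states_x, n_intervals)
    qy = brute_distribution(states_y, n_intervals)
    acc = 0.0
    for i in range(n_intervals):
        for j in range(len(STATE_ALPHABET)):
            acc += (px[i, j] - qy[i, j]) ** 2
    return np.sqrt(acc) / np.sqrt(n_intervals)


def brute_marginal(list_of_states):
    counts = dict.fromkeys(STATE_ALPHABET, 0)
    total = 0
    for states in list_of_states:
        for c in states:
            if c != MISSING:
                counts[c] += 1
                total += 1
    return {s: c / total for s, c in counts.items() if c > 0}


def anova_f(y, groups):
    """Classical one-way ANOVA F by direct sums of squares."""
    y = np.asarray(y, dtype=float)
    levels = sorted(set(groups))
    grand = y.mean()
    ss_between = sum(
        np.sum(groups == g) * (y[groups == g].mean() - grand) ** 2 for g in levels
    )
    ss_within = sum(
        np.sum((y[groups == g] - y[groups == g].mean()) ** 2) for g in levels
    )
    df_b = len(levels) - 1
    df_w = len(y) - len(levels)
    return (ss_between / df_b) / (ss_within / df_w)


def best_two_partition_1d(x):
    """Exhaustive minimum within-cluster sum-of-squares 2-partition."""
    n = len(x)
    x = np.asarray(x, dtype=float)
    best, best_ss = None, np.inf
    for size in range(1, n // 2 + 1):
        for left in combinations(range(n), size):
            mask = np.zeros(n, dtype=bool)
            mask[list(left)] = True
            ss = np.sum((x[mask] - x[mask].mean()) ** 2)
            ss += np.sum((x[~mask] - x[~mask].mean()) ** 2)
            if ss < best_ss - 1e-12:
                best_ss, best = ss, mask.copy()
    return best, best_ss
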