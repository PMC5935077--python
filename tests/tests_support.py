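"""Shared brute-force oracles used by the test suite."""

import itertools

import numpy as np


def brute_force_isotonic(y):
    """Monotone least-squares fit by enumerating all block partitions.

    Independent of any PAVA implementation: every way of cutting the
    sequence into contiguous blocks is tried; block means that come out
    non-decreasing are candidate fits and the smallest SSE wins.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    best, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        blocks, start = [], 0
        for i, c in enumerate(cuts, start=1):
            if c:
                blocks.append((start, i))
                start = i
        blocks.append((start, n))
        means = [y[a:b].mean() for a, b in blocks]
        if any(means[i] > means[i + 1] for i in range(len(means) - 1)):
            continue
        fit = np.concatenate([[m] * (b - a) for (a, b), m in zip(blocks, means)])
        sse = float(np.sum((fit - y) ** 2))
        if sse < best_sse - 1e-15:
            best, best_sse = fit, sse
    return best
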