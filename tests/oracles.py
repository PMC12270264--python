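"""Independent reference implementations used only to check the package.

Each oracle is a direct transcription of the defining formula, written
without reusing any code path from the package (plain Python loops, no
cumulative-sum vectorization), so agreement is informative.
"""

from __future__ import annotations

import numpy as np


def ks_running_sum(order, members):
    """Unweighted KS running sum of a gene set along a ranking.

    At position i the deviation is (#hits <= i)/#hits - (#misses <= i)/#misses,
    accumulated by explicit counting.  Returns (running, ES) where ES is the
    deviation of maximal absolute value (positive preferred on exact ties).
    """
    members = set(members)
    n_hit = sum(1 for g in order if g in members)
    n_miss = len(order) - n_hit
    running = []
    hits = misses = 0
    for g in order:
        if g in members:
            hits += 1
        else:
            misses += 1
        running.append(hits / n_hit - misses / n_miss)
    es = 0.0
    for value in running:
        if abs(value) > abs(es) or (value > 0 and value == -es):
            es = value
    return np.array(running), es


def bh_stepup(p_values):
    """Benjamini-Hochberg step-up by the textbook recipe (explicit loops)."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(prev, p[i] * m / rank)
        q[i] = min(value, 1.0)
        prev = value
    return np.array(q)


def tail_count_pvalue(obs, null, conservative=False):
    """Sign-matched permutation tail probability by explicit counting."""
    count = 0
    for value in null:
        if obs >= 0 and value >= obs:
            count += 1
        elif obs < 0 and value <= obs:
            count += 1
    if conservative:
        return (count + 1) / (len(null) + 1)
    return count / len(null)
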