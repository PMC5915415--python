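"""Independent brute-force oracles used only by the test suite.

Each oracle is implemented from the definition of the operation it
checks, deliberately ignoring the package's own algorithms.
"""

from __future__ import annotations

import numpy as np


def brute_force_clusters(positions: list[int], window: int) -> list[frozenset[int]]:
    """Transitive closure of the relation |a - b| <= window, O(n^2).

    Returns the partition of (possibly duplicated) positions as a set of
    frozensets of distinct position values.
    """
    uniq = sorted(set(positions))
    n = len(uniq)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if abs(uniq[i] - uniq[j]) <= window:
                union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(uniq[i])
    return sorted((frozenset(g) for g in groups.values()), key=min)


def brute_force_a_rich(
    seq: str, min_run: int = 7, window: int = 10, window_count: int = 8
) -> bool:
    """Exhaustive A-rich test: every substring run, every window."""
    s = seq.upper()
    n = len(s)
    for i in range(n):
        for j in range(i + min_run, n + 1):
            if set(s[i:j]) == {"A"}:
                return True
    w = min(window, n)
    for i in range(n - w + 1):
        if s[i : i + w].count("A") >= window_count:
            return True
    return False


def textbook_chi_square(table: np.ndarray) -> tuple[float, int]:
    """Pearson statistic from the definition, cell by cell, with the
    continuity correction for 2x2 tables."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    stat = 0.0
    yates = obs.shape == (2, 2)
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            expected = obs[i].sum() * obs[:, j].sum() / total
            diff = abs(obs[i, j] - expected)
            if yates:
                diff = max(diff - 0.5, 0.0)
            stat += diff**2 / expected
    return stat, (obs.shape[0] - 1) * (obs.shape[1] - 1)
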