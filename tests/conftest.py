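"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity with plain Python
loops and ``math`` calls so they share no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from hesrank.data_model import DecisionMatrix, Indicator


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def small_matrix() -> DecisionMatrix:
    """3 countries x 2 benefit indicators with distinct spreads."""
    return DecisionMatrix(
        countries=("A", "B", "C"),
        indicators=(
            Indicator("i1", "Indicator 1"),
            Indicator("i2", "Indicator 2"),
        ),
        scores=np.array([[10.0, 55.0], [30.0, 50.0], [20.0, 45.0]]),
        region="test",
        period="t0",
    )


def make_matrix(scores, directions=None, **kwargs) -> DecisionMatrix:
    scores = np.asarray(scores, dtype=float)
    m, n = scores.shape
    directions = directions or ["benefit"] * n
    return DecisionMatrix(
        countries=tuple(f"c{i}" for i in range(m)),
        indicators=tuple(
            Indicator(f"i{j}", f"I{j}", d) for j, d in enumerate(directions)
        ),
        scores=scores,
        **kwargs,
    )


# ----------------------------------------------------------------- oracles

def entropy_weights_oracle(scores) -> list[float]:
    """Straight transcription of the entropy weighting recipe."""
    scores = [list(map(float, row)) for row in scores]
    m, n = len(scores), len(scores[0])
    weights = []
    divs = []
    for j in range(n):
        col = [scores[i][j] for i in range(m)]
        total = sum(col)
        ent = 0.0
        for g in col:
            p = g / total
            if p > 0:
                ent -= p * math.log(p)
        ent /= math.log(m)
        divs.append(1.0 - ent)
    total_div = sum(divs)
    return [d / total_div for d in divs]


def cocoso_oracle(scores, weights, directions, lam=0.5):
    """Straight transcription of the CoCoSo recipe; returns all stages."""
    scores = [list(map(float, row)) for row in scores]
    m, n = len(scores), len(scores[0])
    r = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col = [scores[i][j] for i in range(m)]
        lo, hi = min(col), max(col)
        for i in range(m):
            if hi == lo:
                r[i][j] = 1.0
            elif directions[j] == "benefit":
                r[i][j] = (scores[i][j] - lo) / (hi - lo)
            else:
                r[i][j] = (scores[i][j] - hi) / (lo - hi)
    S = [sum(weights[j] * r[i][j] for j in range(n)) for i in range(m)]
    P = []
    for i in range(m):
        p = 0.0
        for j in range(n):
            p += 1.0 if (r[i][j] == 0 and weights[j] == 0) else r[i][j] ** weights[j]
        P.append(p)
    tot = sum(P[i] + S[i] for i in range(m))
    k_a = [(P[i] + S[i]) / tot for i in range(m)]
    k_b = [S[i] / min(S) + P[i] / min(P) for i in range(m)]
    denom = lam * max(S) + (1 - lam) * max(P)
    k_c = [(lam * S[i] + (1 - lam) * P[i]) / denom for i in range(m)]
    C = [
        (k_a[i] * k_b[i] * k_c[i]) ** (1.0 / 3.0)
        + (k_a[i] + k_b[i] + k_c[i]) / 3.0
        for i in range(m)
    ]
    return S, P, k_a, k_b, k_c, C


def best_contiguous_partition(values, K):
    """Exhaustive search over contiguous K-partitions of the sorted values.

    Returns (labels_in_input_order, wcss) of the best split.
    """
    values = list(map(float, values))
    order = sorted(range(len(values)), key=lambda i: values[i])
    x = [values[i] for i in order]
    m = len(x)
    best_cost, best_bounds = float("inf"), None
    for cuts in itertools.combinations(range(1, m), K - 1):
        bounds = (0, *cuts, m)
        cost = 0.0
        for lo, hi in zip(bounds, bounds[1:]):
            seg = x[lo:hi]
            mu = sum(seg) / len(seg)
            cost += sum((v - mu) ** 2 for v in seg)
        if cost < best_cost:
            best_cost, best_bounds = cost, bounds
    labels = [0] * m
    for k, (lo, hi) in enumerate(zip(best_bounds, best_bounds[1:])):
        for pos in range(lo, hi):
            labels[order[pos]] = k
    return labels, best_cost


def wcss(values, labels) -> float:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for k in np.unique(labels):
        seg = values[labels == k]
        total += float(((seg - seg.mean()) ** 2).sum())
    return total


def same_partition(labels_a, labels_b) -> bool:
    """Whether two labelings induce the same partition (up to renaming)."""
    groups_a = {}
    groups_b = {}
    for i, (a, b) in enumerate(zip(labels_a, labels_b)):
        groups_a.setdefault(a, set()).add(i)
        groups_b.setdefault(b, set()).add(i)
    return sorted(map(frozenset, groups_a.values())) == sorted(
        map(frozenset, groups_b.values())
    )
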