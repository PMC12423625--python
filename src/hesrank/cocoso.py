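"""Combined Compromise Solution (CoCoSo) ranking.

CoCoSo aggregates three compromise strategies into one composite score
per alternative:

1. min-max normalise the decision matrix (direction-aware, so that 1 is
   always best);
2. form the additive weighted sequence S_i = sum_j w_j r_ij (weighted-sum
   model) and the exponential weighted sequence P_i = sum_j r_ij^{w_j}
   (weighted-product flavour);
3. blend them into three appraisal scores

       k_a,i = (P_i + S_i) / sum_i (P_i + S_i)          (share of total)
       k_b,i = S_i / min S  +  P_i / min P              (relative to worst)
       k_c,i = (lam*S_i + (1-lam)*P_i)
               / (lam*max S + (1-lam)*max P)            (relative to best)

4. combine them into the composite

       C_i = (k_a k_b k_c)^(1/3) + (k_a + k_b + k_c) / 3

   and rank in descending C_i.

The balance parameter ``lam`` (0 <= lam <= 1, default 0.5) trades the
additive sequence off against the exponential one inside k_c.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DecisionMatrix
from .entropy import WeightVector

__all__ = [
    "MinMaxMatrix",
    "CoCoSoResult",
    "DegenerateMinimumError",
    "minmax_normalize",
    "comparability_sequences",
    "appraisal_scores",
    "composite_scores",
    "rank_alternatives",
    "run_cocoso",
    "write_ranking_csv",
]


class DegenerateMinimumError(ValueError):
    """min S or min P is zero: k_b's denominators vanish."""


@dataclass(frozen=True)
class MinMaxMatrix:
    """Direction-aware min-max normalised scores r_ij in [0, 1]."""

    values: np.ndarray
    indicator_ids: tuple[str, ...]
    column_minima: np.ndarray
    column_maxima: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise ValueError("normalised scores must lie in [0, 1]")


@dataclass(frozen=True)
class CoCoSoResult:
    """Per-alternative CoCoSo quantities and final ranking.

    ``rank[i]`` is the position of ``countries[i]`` (1 = best composite
    score).  Ties are broken alphabetically by country name and flagged
    in ``tied``.
    """

    countries: tuple[str, ...]
    S: np.ndarray
    P: np.ndarray
    k_a: np.ndarray
    k_b: np.ndarray
    k_c: np.ndarray
    lam: float
    C: np.ndarray
    rank: np.ndarray
    tied: bool
    region: str = ""
    period: str = ""

    def to_frame(self) -> pd.DataFrame:
        """country, S, P, k_a, k_b, k_c, C, rank — sorted by input order."""
        return pd.DataFrame(
            {
                "country": list(self.countries),
                "S": self.S,
                "P": self.P,
                "k_a": self.k_a,
                "k_b": self.k_b,
                "k_c": self.k_c,
                "C": self.C,
                "rank": self.rank,
            }
        )

    def ordered_countries(self) -> list[str]:
        """Country names from rank 1 to rank m."""
        order = np.argsort(self.rank)
        return [self.countries[i] for i in order]


def minmax_normalize(matrix: DecisionMatrix) -> MinMaxMatrix:
    """Min-max normalise each column so that 1 is best, 0 is worst.

    Benefit criteria map the column maximum to 1; cost criteria map the
    column minimum to 1.  A constant column normalises to 1 for every
    alternative: a criterion that does not discriminate treats all
    alternatives as equally best, which keeps it neutral in both the
    additive and the exponential sequence.
    """
    scores = matrix.scores
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = hi - lo
    values = np.ones_like(scores)
    for j, ind in enumerate(matrix.indicators):
        if span[j] == 0:
            continue
        if ind.direction == "benefit":
            values[:, j] = (scores[:, j] - lo[j]) / span[j]
        else:
            values[:, j] = (scores[:, j] - hi[j]) / (lo[j] - hi[j])
    return MinMaxMatrix(
        values=values,
        indicator_ids=matrix.indicator_ids,
        column_minima=lo,
        column_maxima=hi,
    )


def comparability_sequences(
    norm: MinMaxMatrix, weights: WeightVector | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Additive (S) and exponential (P) weighted sequences.

    S_i = sum_j w_j r_ij;  P_i = sum_j r_ij^{w_j} with 0^0 := 1 (a
    zero-weight criterion contributes 1 uniformly).
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    r = norm.values
    if w.shape[0] != r.shape[1]:
        raise ValueError(
            f"{w.shape[0]} weights for {r.shape[1]} criteria"
        )
    S = r @ w
    with np.errstate(divide="ignore"):
        powered = np.where((r == 0) & (w == 0), 1.0, r ** w)
    P = powered.sum(axis=1)
    return S, P


def appraisal_scores(
    S: np.ndarray,
    P: np.ndarray,
    lam: float = 0.5,
    epsilon_guard: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three appraisal scores k_a, k_b, k_c.

    Raises :class:`DegenerateMinimumError` when min S or min P is zero
    (an alternative worst on every criterion) unless ``epsilon_guard``
    floors k_b's denominators at 1e-12; the guard is off by default since
    silently inflating 1/min distorts k_b.
    """
    S = np.asarray(S, float)
    P = np.asarray(P, float)
    if S.shape != P.shape or S.size < 2:
        raise ValueError("S and P must be equal-length vectors, m >= 2")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    min_s, min_p = S.min(), P.min()
    if (min_s <= 0 or min_p <= 0) and not epsilon_guard:
        raise DegenerateMinimumError(
            f"min S = {min_s}, min P = {min_p}: k_b undefined; enable "
            "epsilon_guard to floor the denominators at 1e-12"
        )
    eps = 1e-12
    k_a = (P + S) / (P + S).sum()
    k_b = S / max(min_s, eps) + P / max(min_p, eps)
    k_c = (lam * S + (1 - lam) * P) / (lam * S.max() + (1 - lam) * P.max())
    return k_a, k_b, k_c


def composite_scores(
    k_a: np.ndarray,
    k_b: np.ndarray,
    k_c: np.ndarray,
    variant: str = "canonical",
) -> np.ndarray:
    """Combine the appraisal scores into the composite C_i.

    ``variant="canonical"`` (default) is the standard CoCoSo composite
    C_i = (k_a k_b k_c)^{1/3} + (k_a + k_b + k_c)/3.  The
    ``"arith_only"`` variant, (k_a+k_b+k_c)^{1/3} + (k_a+k_b+k_c)/3,
    exists purely for auditing against implementations that dropped the
    geometric mean.
    """
    k_a, k_b, k_c = (np.asarray(k, float) for k in (k_a, k_b, k_c))
    if not (k_a.shape == k_b.shape == k_c.shape):
        raise ValueError("appraisal scores must have equal length")
    if min(k_a.min(), k_b.min(), k_c.min()) < 0:
        raise ValueError("appraisal scores must be non-negative")
    if variant == "canonical":
        return np.cbrt(k_a * k_b * k_c) + (k_a + k_b + k_c) / 3.0
    if variant == "arith_only":
        total = k_a + k_b + k_c
        return np.cbrt(total) + total / 3.0
    raise ValueError(f"unknown composite variant {variant!r}")


def rank_alternatives(
    C: np.ndarray, countries: Sequence[str]
) -> tuple[np.ndarray, bool]:
    """Rank positions (1 = largest C); ties broken alphabetically.

    Returns ``(rank, tied)`` where ``tied`` flags whether any two scores
    were exactly equal.
    """
    C = np.asarray(C, float)
    if not np.all(np.isfinite(C)):
        raise ValueError("composite scores must be finite")
    order = sorted(range(len(C)), key=lambda i: (-C[i], countries[i]))
    rank = np.empty(len(C), dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    tied = len(np.unique(C)) < len(C)
    return rank, tied


def run_cocoso(
    matrix: DecisionMatrix,
    weights: WeightVector,
    lam: float = 0.5,
    variant: str = "canonical",
    epsilon_guard: bool = False,
) -> CoCoSoResult:
    """End-to-end CoCoSo ranking of a decision matrix under given weights."""
    if tuple(weights.indicator_ids) != matrix.indicator_ids:
        raise ValueError(
            f"weight indicators {list(weights.indicator_ids)} do not match "
            f"matrix indicators {list(matrix.indicator_ids)}"
        )
    norm = minmax_normalize(matrix)
    S, P = comparability_sequences(norm, weights)
    k_a, k_b, k_c = appraisal_scores(S, P, lam=lam, epsilon_guard=epsilon_guard)
    C = composite_scores(k_a, k_b, k_c, variant=variant)
    rank, tied = rank_alternatives(C, matrix.countries)
    return CoCoSoResult(
        countries=matrix.countries,
        S=S,
        P=P,
        k_a=k_a,
        k_b=k_b,
        k_c=k_c,
        lam=lam,
        C=C,
        rank=rank,
        tied=tied,
        region=matrix.region,
        period=matrix.period,
    )


def write_ranking_csv(result: CoCoSoResult, path: str | Path) -> Path:
    path = Path(path)
    frame = result.to_frame()
    frame.insert(0, "region", result.region)
    frame.insert(1, "period", result.period)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path
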