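"""Objective criterion weighting via Shannon entropy.

Each criterion column is turned into a proportion distribution over the
alternatives, its Shannon entropy Ent_j = -(1/ln m) * sum_i n_ij ln n_ij
is computed, and the divergences d_j = 1 - Ent_j are normalised into
weights W_j = d_j / sum_k d_k.  Criteria on which the alternatives differ
more (lower entropy of the column proportions) receive larger weights, so
the weighting is fully data driven: no expert judgement enters.

Conventions: 0 * ln 0 := 0 (scores of exactly zero are legal on the GHSI
scale); an all-constant matrix (every divergence zero) raises rather than
silently returning uniform weights, because the weight formula is 0/0
there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DecisionMatrix

__all__ = [
    "ProportionMatrix",
    "WeightVector",
    "DegenerateColumnError",
    "NoInformationError",
    "proportion_normalize",
    "entropy_values",
    "divergence_weights",
    "compute_entropy_weights",
    "weights_to_frame",
    "write_weights_csv",
]


class DegenerateColumnError(ValueError):
    """A criterion column sums to zero (or is negative) and carries no signal."""


class NoInformationError(ValueError):
    """Every criterion has zero divergence; entropy weights are undefined."""


@dataclass(frozen=True)
class ProportionMatrix:
    """Column-stochastic share matrix n_ij = g_ij / sum_i g_ij."""

    values: np.ndarray
    indicator_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        sums = values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"columns must sum to 1, got sums {sums}")
        if values.min() < 0 or values.max() > 1:
            raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class WeightVector:
    """Per-criterion entropy, divergence and normalised weight.

    ``weights`` sums to 1; a criterion with zero divergence (constant
    column) gets weight exactly 0.
    """

    indicator_ids: tuple[str, ...]
    entropy: np.ndarray
    divergence: np.ndarray
    weights: np.ndarray
    region: str = ""
    period: str = ""

    def __post_init__(self) -> None:
        for name in ("entropy", "divergence", "weights"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = len(self.indicator_ids)
        if not (self.entropy.shape == self.divergence.shape
                == self.weights.shape == (n,)):
            raise ValueError("entropy/divergence/weights must have one value "
                             "per indicator")
        # 2e-3 admits display-rounded published tables (rows summing to
        # 0.999-1.001); freshly computed weights sum to 1 within 1e-9,
        # which the entropy tests assert directly.
        if abs(self.weights.sum() - 1.0) > 2e-3:
            raise ValueError(f"weights must sum to 1, got {self.weights.sum()}")
        if self.weights.min() < 0:
            raise ValueError("weights must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.indicator_ids))


def proportion_normalize(matrix: DecisionMatrix) -> ProportionMatrix:
    """Normalise each criterion column into a proportion distribution.

    Raises :class:`DegenerateColumnError` if any column contains a
    negative score or sums to zero.
    """
    scores = matrix.scores
    neg = np.argwhere(scores < 0)
    if neg.size:
        i, j = neg[0]
        raise DegenerateColumnError(
            f"negative score at country {matrix.countries[i]!r}, "
            f"indicator {matrix.indicator_ids[j]!r}; proportions undefined"
        )
    sums = scores.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise DegenerateColumnError(
            f"indicator {matrix.indicator_ids[zero[0]]!r} sums to zero: "
            "every country scores 0 on it"
        )
    return ProportionMatrix(values=scores / sums, indicator_ids=matrix.indicator_ids)


def entropy_values(norm: ProportionMatrix) -> np.ndarray:
    """Shannon entropy of each column, normalised to [0, 1] by ln m."""
    m = norm.values.shape[0]
    if m < 2:
        raise ValueError("entropy needs at least 2 alternatives (ln m > 0)")
    p = norm.values
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    ent = -plogp.sum(axis=0) / np.log(m)
    # clip the ~1e-16 excursions from float summation
    return np.clip(ent, 0.0, 1.0)


def divergence_weights(
    entropy: Sequence[float] | np.ndarray,
    indicator_ids: Sequence[str] | None = None,
    region: str = "",
    period: str = "",
) -> WeightVector:
    """Normalise divergences 1 - Ent_j into weights summing to 1."""
    ent = np.asarray(entropy, dtype=float)
    if ent.min() < 0 or ent.max() > 1:
        raise ValueError(f"entropies must lie in [0, 1], got {ent}")
    div = 1.0 - ent
    total = div.sum()
    if total <= 0:
        raise NoInformationError(
            "every criterion has entropy 1 (all columns constant); "
            "entropy weights are undefined"
        )
    if indicator_ids is None:
        indicator_ids = tuple(f"c{j + 1}" for j in range(ent.size))
    return WeightVector(
        indicator_ids=tuple(indicator_ids),
        entropy=ent,
        divergence=div,
        weights=div / total,
        region=region,
        period=period,
    )


def compute_entropy_weights(matrix: DecisionMatrix) -> WeightVector:
    """Full entropy weighting of a decision matrix.

    Composition of :func:`proportion_normalize`, :func:`entropy_values`
    and :func:`divergence_weights`; computed independently per
    (region, period) dataset.
    """
    norm = proportion_normalize(matrix)
    ent = entropy_values(norm)
    return divergence_weights(
        ent, matrix.indicator_ids, region=matrix.region, period=matrix.period
    )


def weights_to_frame(weight_vectors: Sequence[WeightVector]) -> pd.DataFrame:
    """One row per (region, period): W_j columns plus companion Ent_j columns."""
    rows = []
    for wv in weight_vectors:
        row: dict[str, object] = {"region": wv.region, "period": wv.period}
        row.update(zip(wv.indicator_ids, wv.weights))
        row.update({f"entropy_{i}": e for i, e in zip(wv.indicator_ids, wv.entropy)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_weights_csv(weight_vectors: Sequence[WeightVector], path: str | Path) -> Path:
    path = Path(path)
    weights_to_frame(weight_vectors).to_csv(path, index=False, float_format="%.17g")
    return path
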