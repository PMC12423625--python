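"""Cross-period and cross-regional comparison analytics.

Three comparisons sit downstream of the weighting / ranking / tiering
stages:

* weight deltas between two assessment periods (late minus early), which
  show how the data-driven prioritisation of indicators shifted;
* rank-shift classification of each country as improved / stable /
  declined between two rankings (a *smaller* rank number is better);
* per-tier mean profiles over a sub-indicator panel, which characterise
  what separates the performance tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import TierAssignment
from .cocoso import CoCoSoResult
from .data_model import AlignmentError, SubIndicatorPanel
from .entropy import WeightVector

__all__ = [
    "WeightDelta",
    "RankShiftReport",
    "weight_deltas",
    "rank_shifts",
    "cluster_profiles",
    "compare_regions",
]


@dataclass(frozen=True)
class WeightDelta:
    """Per-indicator weight change, late period minus early period."""

    region: str
    period_early: str
    period_late: str
    indicator_ids: tuple[str, ...]
    deltas: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.deltas, index=list(self.indicator_ids))


@dataclass(frozen=True)
class RankShiftReport:
    """Improved / stable / declined classification between two rankings."""

    countries: tuple[str, ...]
    rank_early: np.ndarray
    rank_late: np.ndarray
    direction: tuple[str, ...]
    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def m(self) -> int:
        return len(self.countries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": list(self.countries),
                "rank_early": self.rank_early,
                "rank_late": self.rank_late,
                "direction": list(self.direction),
            }
        )


def weight_deltas(w_early: WeightVector, w_late: WeightVector) -> WeightDelta:
    """Element-wise weight difference, late minus early.

    A positive delta means the indicator gained prioritisation over time.
    Both vectors must cover the same indicators; deltas over a full
    weight vector sum to zero by construction.
    """
    if tuple(w_early.indicator_ids) != tuple(w_late.indicator_ids):
        raise AlignmentError(
            f"indicator lists differ: {list(w_early.indicator_ids)} vs "
            f"{list(w_late.indicator_ids)}"
        )
    return WeightDelta(
        region=w_late.region or w_early.region,
        period_early=w_early.period,
        period_late=w_late.period,
        indicator_ids=tuple(w_early.indicator_ids),
        deltas=w_late.weights - w_early.weights,
    )


def rank_shifts(
    r_early: Mapping[str, int] | CoCoSoResult,
    r_late: Mapping[str, int] | CoCoSoResult,
) -> RankShiftReport:
    """Classify each country's rank change between two periods.

    ``improved`` means the rank number strictly decreased (moved toward
    1), ``declined`` strictly increased, ``stable`` unchanged.
    Percentages are 100 * count / m at full precision; round for display.
    """
    early = _rank_mapping(r_early)
    late = _rank_mapping(r_late)
    if set(early) != set(late):
        raise AlignmentError(
            f"country sets differ: {sorted(set(early) ^ set(late))}"
        )
    for name, ranks in (("early", early), ("late", late)):
        if sorted(ranks.values()) != list(range(1, len(ranks) + 1)):
            raise ValueError(f"{name} ranking is not a permutation of 1..m")
    countries = tuple(early)
    direction = []
    for c in countries:
        if late[c] < early[c]:
            direction.append("improved")
        elif late[c] > early[c]:
            direction.append("declined")
        else:
            direction.append("stable")
    m = len(countries)
    counts = {d: direction.count(d) for d in ("improved", "stable", "declined")}
    percentages = {d: 100.0 * n / m for d, n in counts.items()}
    return RankShiftReport(
        countries=countries,
        rank_early=np.array([early[c] for c in countries]),
        rank_late=np.array([late[c] for c in countries]),
        direction=tuple(direction),
        counts=counts,
        percentages=percentages,
    )


def _rank_mapping(r: Mapping[str, int] | CoCoSoResult) -> dict[str, int]:
    if isinstance(r, CoCoSoResult):
        return {c: int(rank) for c, rank in zip(r.countries, r.rank)}
    return {str(c): int(v) for c, v in r.items()}


def cluster_profiles(
    panel: SubIndicatorPanel, assignment: TierAssignment
) -> pd.DataFrame:
    """Unweighted mean sub-indicator score per tier.

    Returns a DataFrame indexed by level (1..K) with one column per
    sub-indicator; chart-ready for tier-profile comparisons.  Every
    country in the assignment must appear in the panel.
    """
    if assignment.countries is None:
        raise ValueError("assignment carries no country names")
    panel_index = {c: i for i, c in enumerate(panel.countries)}
    missing = [c for c in assignment.countries if c not in panel_index]
    if missing:
        raise AlignmentError(f"countries absent from panel: {missing}")
    levels = assignment.levels
    rows = {}
    for level in sorted(set(int(v) for v in levels)):
        members = [c for c, lv in zip(assignment.countries, levels) if lv == level]
        idx = [panel_index[c] for c in members]
        rows[level] = panel.scores[idx].mean(axis=0)
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(panel.sub_indicators))
    frame.index.name = "level"
    return frame


def compare_regions(
    weight_vectors: Sequence[WeightVector],
    delta_periods: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Tidy long-format weight comparison across regions and periods.

    One row per (region, period, indicator) with the weight; when
    ``delta_periods=(early, late)`` is given and both periods exist for a
    region, a ``delta`` column carries the late-minus-early change
    (repeated on both period rows of that region, NaN elsewhere).
    """
    if not weight_vectors:
        raise ValueError("need at least one weight vector")
    ids = tuple(weight_vectors[0].indicator_ids)
    for wv in weight_vectors:
        if tuple(wv.indicator_ids) != ids:
            raise AlignmentError(
                f"inconsistent indicator lists: {list(ids)} vs "
                f"{list(wv.indicator_ids)}"
            )
    records = []
    by_region: dict[str, dict[str, WeightVector]] = {}
    for wv in weight_vectors:
        by_region.setdefault(wv.region, {})[wv.period] = wv
    for wv in weight_vectors:
        delta = None
        if delta_periods is not None:
            early, late = delta_periods
            pair = by_region.get(wv.region, {})
            if early in pair and late in pair and wv.period in (early, late):
                delta = pair[late].weights - pair[early].weights
        for j, ind in enumerate(ids):
            records.append(
                {
                    "region": wv.region,
                    "period": wv.period,
                    "indicator": ind,
                    "weight": float(wv.weights[j]),
                    "delta": float(delta[j]) if delta is not None else np.nan,
                }
            )
    return pd.DataFrame.from_records(records)
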