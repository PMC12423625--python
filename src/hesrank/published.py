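"""Published results of a cross-national health-security assessment.

A 2025 cross-national study scored 27 non-EU European countries on the
six Global Health Security Index domains for 2019, 2021 and the
aggregated 2017-2021 window, weighted the domains by Shannon entropy
(also for the African and Eastern Mediterranean regions), ranked the
countries with CoCoSo and grouped them into five performance tiers.
This module bundles the study's *printed* result tables — entropy
weights per region and period, composite scores C_i with rank and tier
per country, and the printed 2019→2021 weight changes — as plain data.

They serve two purposes: worked-example inputs for the comparison
analytics (weight deltas, rank shifts, tiering of published composite
scores), and regression anchors for the test suite.  Values are exactly
as printed, i.e. rounded to three decimals; weight rows may sum to
0.999-1.001.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .entropy import WeightVector

__all__ = [
    "INDICATORS",
    "REGIONS",
    "PERIODS",
    "published_weights",
    "published_weight_vectors",
    "published_weight_changes",
    "published_scores",
    "published_composites",
    "published_ranks",
    "published_levels",
]

#: the six GHSI domains, all benefit criteria
INDICATORS = (
    "prevention",
    "detection",
    "rapid_response",
    "health_system",
    "compliance",
    "risk_environment",
)

REGIONS = ("non_eu", "africa", "emr")
PERIODS = ("2019", "2021", "2017-2021")

# Entropy weights per (region, period), printed to 3 d.p.
_WEIGHTS: dict[tuple[str, str], tuple[float, ...]] = {
    ("non_eu", "2019"): (0.204, 0.399, 0.104, 0.135, 0.091, 0.066),
    ("non_eu", "2021"): (0.218, 0.372, 0.098, 0.126, 0.123, 0.064),
    ("non_eu", "2017-2021"): (0.214, 0.388, 0.097, 0.130, 0.104, 0.067),
    ("africa", "2019"): (0.330, 0.326, 0.060, 0.172, 0.057, 0.055),
    ("africa", "2021"): (0.352, 0.294, 0.072, 0.169, 0.051, 0.063),
    ("africa", "2017-2021"): (0.325, 0.322, 0.061, 0.175, 0.056, 0.061),
    ("emr", "2019"): (0.209, 0.217, 0.098, 0.322, 0.060, 0.095),
    ("emr", "2021"): (0.259, 0.221, 0.096, 0.261, 0.063, 0.099),
    ("emr", "2017-2021"): (0.228, 0.220, 0.092, 0.298, 0.063, 0.099),
}

# Printed 2019 -> 2021 weight changes per region (for cross-checking
# deltas recomputed from the weight table above).
_WEIGHT_CHANGES: dict[str, tuple[float, ...]] = {
    "non_eu": (0.014, -0.027, -0.006, -0.010, 0.031, -0.001),
    "africa": (0.023, -0.032, 0.011, -0.004, -0.006, 0.008),
    "emr": (0.051, 0.004, -0.003, -0.060, 0.004, 0.004),
}

# Per-country composite score C, rank R and tier level S for each of the
# three assessment periods: (C19, R19, S19, C21, R21, S21, Cw, Rw, Sw).
_SCORES: dict[str, tuple[float, int, int, float, int, int, float, int, int]] = {
    "Albania": (3.088, 8, 2, 2.231, 10, 2, 2.464, 9, 2),
    "Andorra": (1.162, 27, 5, 1.216, 27, 5, 1.148, 27, 5),
    "Armenia": (4.388, 2, 1, 3.066, 2, 1, 3.439, 2, 1),
    "Azerbaijan": (2.039, 23, 4, 1.681, 21, 4, 1.747, 22, 4),
    "Belarus": (2.572, 14, 3, 2.135, 13, 3, 2.214, 13, 3),
    "Bosnia & Herzegovina": (2.093, 21, 4, 1.652, 22, 4, 1.754, 21, 4),
    "Georgia": (3.247, 6, 2, 2.692, 4, 1, 2.803, 5, 2),
    "Iceland": (2.893, 10, 2, 2.265, 9, 2, 2.417, 10, 2),
    "Israel": (3.285, 5, 2, 2.327, 8, 2, 2.598, 7, 2),
    "Kazakhstan": (2.680, 12, 3, 2.192, 11, 2, 2.291, 12, 3),
    "Kyrgyz Republic": (2.570, 15, 3, 1.993, 18, 3, 2.130, 18, 3),
    "Liechtenstein": (2.518, 17, 3, 2.037, 16, 3, 2.136, 16, 3),
    "Moldova": (2.673, 13, 3, 2.032, 17, 3, 2.190, 14, 3),
    "Monaco": (1.712, 24, 4, 1.350, 26, 5, 1.436, 24, 5),
    "Montenegro": (2.372, 18, 3, 2.116, 14, 3, 2.134, 17, 3),
    "North Macedonia": (2.540, 16, 3, 2.088, 15, 3, 2.176, 15, 3),
    "Norway": (3.890, 3, 1, 2.751, 3, 1, 3.066, 3, 1),
    "Russia": (3.030, 9, 2, 2.404, 7, 2, 2.545, 8, 2),
    "San Marino": (1.413, 25, 5, 1.373, 24, 5, 1.397, 25, 5),
    "Serbia": (2.794, 11, 3, 2.137, 12, 3, 2.297, 11, 3),
    "Switzerland": (3.665, 4, 2, 2.678, 5, 1, 2.947, 4, 2),
    "Tajikistan": (1.386, 26, 5, 1.363, 25, 5, 1.373, 26, 5),
    "Turkey": (3.151, 7, 2, 2.424, 6, 2, 2.601, 6, 2),
    "Turkmenistan": (2.081, 22, 4, 1.441, 23, 5, 1.550, 23, 4),
    "Ukraine": (2.243, 19, 4, 1.753, 20, 4, 1.804, 20, 4),
    "United Kingdom": (4.467, 1, 1, 3.208, 1, 1, 3.557, 1, 1),
    "Uzbekistan": (2.217, 20, 4, 1.835, 19, 4, 1.902, 19, 4),
}

_PERIOD_OFFSET = {"2019": 0, "2021": 3, "2017-2021": 6}


def published_weights(region: str, period: str) -> np.ndarray:
    """Printed entropy weights for one (region, period), 3 d.p."""
    key = (region, period)
    if key not in _WEIGHTS:
        raise KeyError(
            f"no published weights for region={region!r}, period={period!r}; "
            f"regions {REGIONS}, periods {PERIODS}"
        )
    return np.array(_WEIGHTS[key])


def published_weight_vectors(region: str | None = None) -> list[WeightVector]:
    """Printed weights wrapped as :class:`WeightVector` objects.

    Entropy and divergence are not printed in the source tables and are
    filled with NaN; only the weights themselves are data.
    """
    out = []
    for (reg, period), w in _WEIGHTS.items():
        if region is not None and reg != region:
            continue
        w = np.array(w)
        nan = np.full(w.size, np.nan)
        out.append(
            WeightVector(
                indicator_ids=INDICATORS,
                entropy=nan,
                divergence=nan,
                weights=w,
                region=reg,
                period=period,
            )
        )
    return out


def published_weight_changes(region: str) -> np.ndarray:
    """Printed 2019 -> 2021 per-indicator weight changes for a region."""
    return np.array(_WEIGHT_CHANGES[region])


def published_scores() -> pd.DataFrame:
    """All printed per-country results as one DataFrame.

    Columns ``C_<period>``, ``rank_<period>``, ``level_<period>`` for the
    three periods, indexed by country.
    """
    cols = {}
    for period in PERIODS:
        o = _PERIOD_OFFSET[period]
        cols[f"C_{period}"] = {c: v[o] for c, v in _SCORES.items()}
        cols[f"rank_{period}"] = {c: v[o + 1] for c, v in _SCORES.items()}
        cols[f"level_{period}"] = {c: v[o + 2] for c, v in _SCORES.items()}
    frame = pd.DataFrame(cols)
    frame.index.name = "country"
    return frame


def published_composites(period: str) -> pd.Series:
    """Printed composite scores C_i for one period, indexed by country."""
    o = _PERIOD_OFFSET[period]
    return pd.Series({c: v[o] for c, v in _SCORES.items()}, name=f"C_{period}")


def published_ranks(period: str) -> dict[str, int]:
    """Printed rank positions (1 = best) for one period."""
    o = _PERIOD_OFFSET[period]
    return {c: v[o + 1] for c, v in _SCORES.items()}


def published_levels(period: str) -> dict[str, int]:
    """Printed five-tier levels (1 High .. 5 Dangerous) for one period."""
    o = _PERIOD_OFFSET[period]
    return {c: v[o + 2] for c, v in _SCORES.items()}
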