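"""Synthetic decision matrices with controllable statistical structure.

The generator emulates the shape of a GHSI-style assessment — by default
27 countries scored on 6 benefit indicators in [0, 100], with an
optional 34-column sub-indicator panel — while exposing the two knobs
the downstream analysis responds to:

* per-indicator *dispersion*: entropy weighting rewards columns whose
  scores are more spread out, so the generator draws each column from a
  bounded beta distribution whose concentration is the inverse of the
  requested dispersion;
* an optional planted *tier structure*: countries fall into K groups
  with strictly decreasing mean performance, which the ranking and
  clustering stages should recover when the between-tier gaps dominate
  the within-tier spread.

All draws are reproducible under a fixed seed; ground-truth tier labels
are returned alongside the data, never embedded in it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import DecisionMatrix, Indicator, SubIndicatorPanel

__all__ = [
    "GeneratorSpec",
    "TierStructure",
    "generate_matrix",
    "generate_tiered_matrix",
    "generate_subindicator_panel",
]


@dataclass(frozen=True)
class TierStructure:
    """Planted K-tier layout: strictly decreasing means, common spread."""

    means: tuple[float, ...]
    sigma: float
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", tuple(float(v) for v in self.means))
        object.__setattr__(self, "sizes", tuple(int(v) for v in self.sizes))
        if len(self.means) != len(self.sizes):
            raise ValueError("means and sizes must have equal length")
        if any(m2 >= m1 for m1, m2 in zip(self.means, self.means[1:])):
            raise ValueError("tier means must be strictly decreasing")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(s < 1 for s in self.sizes):
            raise ValueError("every tier needs at least one member")

    @property
    def K(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic assessment dataset.

    ``dispersion`` holds one positive spread parameter per indicator;
    column j is drawn from a beta distribution (rescaled to ``bounds``)
    with concentration ``1 / dispersion[j]``, so larger dispersion gives
    a wider column and, downstream, a larger entropy weight.
    """

    m: int = 27
    n: int = 6
    bounds: tuple[float, float] = (0.0, 100.0)
    dispersion: tuple[float, ...] | None = None
    mean: float = 0.55
    tiers: TierStructure | None = None
    sub_indicators: int = 34
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 1:
            raise ValueError("need m >= 2 countries and n >= 1 indicators")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must satisfy lo < hi")
        if not 0.0 < self.mean < 1.0:
            raise ValueError("mean is on the unit scale, strictly inside (0, 1)")
        if self.dispersion is not None:
            disp = tuple(float(d) for d in self.dispersion)
            if len(disp) != self.n:
                raise ValueError(f"need {self.n} dispersion values, got {len(disp)}")
            if any(d <= 0 for d in disp):
                raise ValueError("dispersion values must be positive")
            object.__setattr__(self, "dispersion", disp)
        if self.tiers is not None and sum(self.tiers.sizes) != self.m:
            raise ValueError(
                f"tier sizes sum to {sum(self.tiers.sizes)}, expected m={self.m}"
            )
        if self.sub_indicators < 1:
            raise ValueError("sub_indicators must be >= 1")


def _indicators(n: int) -> tuple[Indicator, ...]:
    return tuple(
        Indicator(id=f"ind{j + 1}", name=f"Indicator {j + 1}", direction="benefit")
        for j in range(n)
    )


def _countries(m: int) -> tuple[str, ...]:
    return tuple(f"Country {i + 1:02d}" for i in range(m))


def generate_matrix(spec: GeneratorSpec) -> DecisionMatrix:
    """Draw an m x n decision matrix with per-column dispersion control.

    Column j is ``lo + (hi - lo) * Beta(mu * kappa_j, (1 - mu) * kappa_j)``
    with ``kappa_j = 1 / dispersion[j]``; the default dispersion is 0.2
    for every column.  Bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    disp = spec.dispersion or (0.2,) * spec.n
    lo, hi = spec.bounds
    cols = []
    for d in disp:
        kappa = 1.0 / d
        a = spec.mean * kappa
        b = (1.0 - spec.mean) * kappa
        cols.append(lo + (hi - lo) * rng.beta(a, b, size=spec.m))
    return DecisionMatrix(
        countries=_countries(spec.m),
        indicators=_indicators(spec.n),
        scores=np.column_stack(cols),
        region="synthetic",
        period=str(spec.seed),
        ghsi_scaled=(lo, hi) == (0.0, 100.0),
    )


def generate_tiered_matrix(
    spec: GeneratorSpec,
) -> tuple[DecisionMatrix, np.ndarray]:
    """Draw a matrix with planted performance tiers; return truth labels.

    Country i in tier k scores ``Normal(means[k], sigma)`` on every
    indicator, truncated (clipped) to the bounds.  Returns the matrix and
    the ground-truth tier label (1..K, 1 = best) per country.  A warning
    is raised when ``sigma`` exceeds half the smallest gap between
    adjacent tier means, since tiers may then overlap and recovery is no
    longer guaranteed.
    """
    if spec.tiers is None:
        raise ValueError("spec.tiers must be set for tiered generation")
    tiers = spec.tiers
    if tiers.K > 1:
        min_gap = min(m1 - m2 for m1, m2 in zip(tiers.means, tiers.means[1:]))
        if tiers.sigma > min_gap / 2:
            warnings.warn(
                f"sigma={tiers.sigma} exceeds half the minimum tier gap "
                f"({min_gap / 2}); tiers may overlap",
                stacklevel=2,
            )
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.bounds
    labels = np.repeat(np.arange(1, tiers.K + 1), tiers.sizes)
    means = np.asarray(tiers.means)[labels - 1]
    scores = rng.normal(means[:, None], tiers.sigma, size=(spec.m, spec.n))
    scores = np.clip(scores, lo, hi)
    matrix = DecisionMatrix(
        countries=_countries(spec.m),
        indicators=_indicators(spec.n),
        scores=scores,
        region="synthetic-tiered",
        period=str(spec.seed),
        ghsi_scaled=(lo, hi) == (0.0, 100.0),
    )
    return matrix, labels


def generate_subindicator_panel(
    matrix: DecisionMatrix,
    count: int = 34,
    noise: float = 5.0,
    seed: int = 0,
    bounds: tuple[float, float] = (0.0, 100.0),
) -> SubIndicatorPanel:
    """Expand a matrix into a correlated sub-indicator panel.

    Sub-indicator s is attached to parent indicator ``s mod n`` and
    equals the country's parent score plus uniform noise in
    ``[-noise, +noise]``, clipped to ``bounds``; ``noise=0`` reproduces
    the parent scores exactly.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    n = matrix.n
    parents = np.arange(count) % n
    base = matrix.scores[:, parents]
    jitter = rng.uniform(-noise, noise, size=base.shape) if noise > 0 else 0.0
    scores = np.clip(base + jitter, *bounds)
    names = tuple(
        f"sub{s + 1:02d}_{matrix.indicator_ids[parents[s]]}" for s in range(count)
    )
    return SubIndicatorPanel(
        countries=matrix.countries,
        sub_indicators=names,
        scores=scores,
    )
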