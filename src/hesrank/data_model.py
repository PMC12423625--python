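"""Domain types for decision matrices and their tabular I/O.

The central object is the :class:`DecisionMatrix`: an m x n table of
performance scores g_ij, with m alternatives (countries) on the rows and
n criteria (health-security indicators) on the columns.  Scores on the
Global Health Security Index scale are bounded in [0, 100]; the engine
itself is generic and only enforces the bound when a matrix is declared
GHSI-scaled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Indicator",
    "DecisionMatrix",
    "SubIndicatorPanel",
    "MatrixParseError",
    "AlignmentError",
    "read_decision_matrix",
    "write_decision_matrix",
    "read_indicator_metadata",
    "read_subindicator_panel",
    "write_subindicator_panel",
    "aggregate_periods",
    "read_workbook_matrix",
]

COUNTRY_COLUMN = "country"


class MatrixParseError(ValueError):
    """Raised when a decision-matrix file cannot be parsed or validated."""


class AlignmentError(ValueError):
    """Raised when matrices to be combined do not share countries/indicators."""


@dataclass(frozen=True)
class Indicator:
    """A single assessment criterion.

    Parameters
    ----------
    id : str
        Short unique key (e.g. ``"detection"``).
    name : str
        Display name (e.g. ``"Detection and reporting"``).
    direction : {"benefit", "cost"}
        Whether larger scores are better (benefit) or worse (cost).
        All six GHSI domains are benefit criteria.
    """

    id: str
    name: str
    direction: Literal["benefit", "cost"] = "benefit"

    def __post_init__(self) -> None:
        if self.direction not in ("benefit", "cost"):
            raise ValueError(
                f"indicator {self.id!r}: direction must be 'benefit' or 'cost', "
                f"got {self.direction!r}"
            )


@dataclass(frozen=True)
class DecisionMatrix:
    """An m x n decision matrix of alternatives by criteria.

    ``scores[i, j]`` is the performance score of ``countries[i]`` on
    ``indicators[j]``.  Row and column order is meaningful and preserved
    through I/O.
    """

    countries: tuple[str, ...]
    indicators: tuple[Indicator, ...]
    scores: np.ndarray
    region: str = ""
    period: str = ""
    ghsi_scaled: bool = False

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "countries", tuple(self.countries))
        object.__setattr__(self, "indicators", tuple(self.indicators))
        m, n = self.m, self.n
        if m < 2:
            raise ValueError(f"need at least 2 countries, got {m}")
        if n < 1:
            raise ValueError("need at least 1 indicator")
        if scores.shape != (m, n):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"{m} countries x {n} indicators"
            )
        if len(set(self.countries)) != m:
            dupes = sorted({c for c in self.countries if self.countries.count(c) > 1})
            raise ValueError(f"duplicate country names: {dupes}")
        ids = [ind.id for ind in self.indicators]
        if len(set(ids)) != n:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate indicator ids: {dupes}")
        if not np.all(np.isfinite(scores)):
            i, j = np.argwhere(~np.isfinite(scores))[0]
            raise ValueError(
                f"non-finite score at country {self.countries[i]!r}, "
                f"indicator {ids[j]!r}"
            )
        if self.ghsi_scaled and (scores.min() < 0 or scores.max() > 100):
            raise ValueError("GHSI-scaled scores must lie in [0, 100]")

    @property
    def m(self) -> int:
        return len(self.countries)

    @property
    def n(self) -> int:
        return len(self.indicators)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.indicators)

    def to_frame(self) -> pd.DataFrame:
        """Scores as a DataFrame indexed by country, columns = indicator ids."""
        return pd.DataFrame(
            self.scores, index=list(self.countries), columns=list(self.indicator_ids)
        )

    def rename_countries(self, aliases: Mapping[str, str]) -> "DecisionMatrix":
        """Return a copy with country names mapped through ``aliases``."""
        renamed = tuple(aliases.get(c, c) for c in self.countries)
        return replace(self, countries=renamed)


@dataclass(frozen=True)
class SubIndicatorPanel:
    """Country x sub-indicator score panel (34 sub-indicators for GHSI)."""

    countries: tuple[str, ...]
    sub_indicators: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "countries", tuple(self.countries))
        object.__setattr__(self, "sub_indicators", tuple(self.sub_indicators))
        if scores.shape != (len(self.countries), len(self.sub_indicators)):
            raise ValueError(
                f"panel shape {scores.shape} does not match "
                f"{len(self.countries)} countries x "
                f"{len(self.sub_indicators)} sub-indicators"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError("panel contains non-finite scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=list(self.countries),
            columns=list(self.sub_indicators),
        )


def _default_indicators(names: Sequence[str]) -> tuple[Indicator, ...]:
    return tuple(Indicator(id=str(n), name=str(n), direction="benefit") for n in names)


def read_decision_matrix(
    path: str | Path | io.TextIOBase,
    region: str = "",
    period: str = "",
    indicators: Sequence[Indicator] | None = None,
    ghsi_scaled: bool = False,
) -> DecisionMatrix:
    """Read a decision matrix from CSV.

    Expected layout: UTF-8, comma-separated, ``.`` decimal point; header
    row ``country,<indicator id>,...``; one row per country with numeric
    scores.  Row and column order is preserved.

    Raises
    ------
    MatrixParseError
        On missing/duplicate country names, non-numeric or blank cells,
        or ragged rows; the message names the offending row/column.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"malformed CSV: {exc}") from exc
    if frame.shape[1] < 2:
        raise MatrixParseError(
            "expected a country column plus at least one indicator column"
        )
    first = frame.columns[0]
    if first.strip().lower() != COUNTRY_COLUMN:
        raise MatrixParseError(
            f"first column header must be {COUNTRY_COLUMN!r}, got {first!r}"
        )
    countries = [c.strip() for c in frame.iloc[:, 0]]
    for row, c in enumerate(countries, start=2):
        if not c:
            raise MatrixParseError(f"blank country name at line {row}")
    names = [str(c).strip() for c in frame.columns[1:]]
    body = frame.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            text = str(cell).strip()
            if not text:
                raise MatrixParseError(
                    f"blank score for country {countries[i]!r}, column {names[j]!r}"
                )
            try:
                values[i, j] = float(text)
            except ValueError:
                raise MatrixParseError(
                    f"non-numeric score {text!r} for country {countries[i]!r}, "
                    f"column {names[j]!r}"
                ) from None
    if indicators is None:
        indicators = _default_indicators(names)
    else:
        ids = [ind.id for ind in indicators]
        if ids != names:
            raise MatrixParseError(
                f"indicator metadata ids {ids} do not match file columns {names}"
            )
    try:
        return DecisionMatrix(
            countries=tuple(countries),
            indicators=tuple(indicators),
            scores=values,
            region=region,
            period=period,
            ghsi_scaled=ghsi_scaled,
        )
    except ValueError as exc:
        raise MatrixParseError(str(exc)) from exc


def write_decision_matrix(matrix: DecisionMatrix, path: str | Path) -> Path:
    """Write a decision matrix to CSV with full-precision decimal rendering.

    Round-trips exactly: ``read_decision_matrix(write_decision_matrix(m))``
    reproduces ``m``'s countries, indicator ids and scores bit for bit
    (``repr``-precision floats survive the text round trip).
    """
    path = Path(path)
    lines = [",".join([COUNTRY_COLUMN, *matrix.indicator_ids])]
    for country, row in zip(matrix.countries, matrix.scores):
        lines.append(",".join([country, *(repr(float(v)) for v in row)]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_indicator_metadata(path: str | Path) -> tuple[Indicator, ...]:
    """Read indicator metadata CSV with columns ``id,name,direction``."""
    frame = pd.read_csv(path, dtype=str)
    required = {"id", "name", "direction"}
    if not required.issubset(frame.columns):
        raise MatrixParseError(
            f"indicator metadata needs columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    return tuple(
        Indicator(id=r["id"].strip(), name=r["name"].strip(),
                  direction=r["direction"].strip())
        for _, r in frame.iterrows()
    )


def read_subindicator_panel(path: str | Path) -> SubIndicatorPanel:
    """Read a country x sub-indicator panel CSV (same layout as matrices)."""
    frame = pd.read_csv(path)
    if frame.columns[0].strip().lower() != COUNTRY_COLUMN:
        raise MatrixParseError(
            f"first column header must be {COUNTRY_COLUMN!r}"
        )
    return SubIndicatorPanel(
        countries=tuple(str(c).strip() for c in frame.iloc[:, 0]),
        sub_indicators=tuple(str(c) for c in frame.columns[1:]),
        scores=frame.iloc[:, 1:].to_numpy(dtype=float),
    )


def write_subindicator_panel(panel: SubIndicatorPanel, path: str | Path) -> Path:
    path = Path(path)
    lines = [",".join([COUNTRY_COLUMN, *panel.sub_indicators])]
    for country, row in zip(panel.countries, panel.scores):
        lines.append(",".join([country, *(repr(float(v)) for v in row)]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def aggregate_periods(
    matrices: Sequence[DecisionMatrix],
    method: str = "mean",
    period_label: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> DecisionMatrix:
    """Combine per-edition matrices into one multi-year matrix.

    The default (and only) method is the unweighted cell-wise arithmetic
    mean of the input matrices; a pre-aggregated matrix supplied upstream
    simply bypasses this step.  All matrices must share identical country
    and indicator lists, optionally after mapping country names through
    ``aliases`` (sources disagree on e.g. "Kyrgyz Republic" vs
    "Kyrgyzstan").

    ``period_label`` defaults to "<first>-<last>" of the input periods.
    """
    if not matrices:
        raise ValueError("need at least one matrix to aggregate")
    if method != "mean":
        raise ValueError(f"unsupported aggregation method {method!r}")
    if aliases:
        matrices = [mx.rename_countries(aliases) for mx in matrices]
    ref = matrices[0]
    for other in matrices[1:]:
        if other.countries != ref.countries:
            missing = sorted(set(ref.countries) ^ set(other.countries))
            raise AlignmentError(
                f"country lists differ between periods {ref.period!r} and "
                f"{other.period!r}: symmetric difference {missing or 'order mismatch'}"
            )
        if other.indicator_ids != ref.indicator_ids:
            raise AlignmentError(
                f"indicator lists differ: {list(ref.indicator_ids)} vs "
                f"{list(other.indicator_ids)}"
            )
    stacked = np.stack([mx.scores for mx in matrices])
    if period_label is None:
        periods = [mx.period for mx in matrices if mx.period]
        period_label = f"{periods[0]}-{periods[-1]}" if len(periods) > 1 else (
            periods[0] if periods else ""
        )
    return DecisionMatrix(
        countries=ref.countries,
        indicators=ref.indicators,
        scores=stacked.mean(axis=0),
        region=ref.region,
        period=period_label,
        ghsi_scaled=all(mx.ghsi_scaled for mx in matrices),
    )


def read_workbook_matrix(
    path: str | Path,
    sheet: str | int,
    region: str = "",
    period: str = "",
    country_column: int = 0,
    header_row: int = 0,
    indicators: Sequence[Indicator] | None = None,
) -> DecisionMatrix:
    """Import a decision matrix from an Excel workbook data sheet.

    Optional path for reproducing a run from a published supplementary
    workbook rather than CSV.  The sheet must contain a country column
    followed by one numeric column per indicator.
    """
    frame = pd.read_excel(path, sheet_name=sheet, header=header_row)
    frame = frame.dropna(how="all").dropna(axis=1, how="all")
    countries = tuple(str(c).strip() for c in frame.iloc[:, country_column])
    body = frame.drop(columns=[frame.columns[country_column]])
    names = [str(c).strip() for c in body.columns]
    if indicators is None:
        indicators = _default_indicators(names)
    return DecisionMatrix(
        countries=countries,
        indicators=tuple(indicators),
        scores=body.to_numpy(dtype=float),
        region=region,
        period=period,
    )
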